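"""Resonant inductive-power-transfer circuit model.

A driven transmitter coil couples magnetically (coupling coefficient k,
mutual inductance M = k√(L1·L2)) to a receiver coil on the spinning disc.
Together with the capacitance of the receiver structures,

    C = C_electrode + C_coil + C_add,

the receiver forms an LC tank resonating at f = 1/(2π√(LC)); driving the
transmitter near that frequency boosts the electrode voltage well above the
source amplitude.  The frequency-domain response is obtained from the
standard two-mesh coupled-inductor equations

    (R_s + R_1 + jωL_1) I_1 + jωM I_2 = V_s
    jωM I_1 + (R_2 + jωL_2 + 1/(jωC)) I_2 = 0

with the receiver voltage taken across the tank capacitance (the electrodes
are modelled as a purely capacitive load).  All quantities are SI; reported
voltages follow the peak-to-peak convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InfeasibleDesignError, InvalidGeometryError
from .materials import FR4, DielectricMaterial

__all__ = [
    "PlanarCoil",
    "InterdigitatedElectrodeArray",
    "ReceiverTank",
    "TransmitterDrive",
    "CouplingSpec",
    "FrequencySweepResult",
    "CouplingFit",
    "electrode_capacitance",
    "coil_plane_capacitance",
    "total_capacitance",
    "resonance_frequency",
    "capacitance_from_resonance",
    "mutual_inductance",
    "quality_factor",
    "link_efficiency",
    "induced_voltage_amplitude",
    "sweep_receiver_voltage",
    "required_added_capacitance",
    "fit_coupling_and_loss",
]


@dataclass(frozen=True)
class PlanarCoil:
    """A spiral PCB coil: geometry plus measured electrical parameters.

    The inductance is user-supplied (measured); no inductance-from-geometry
    prediction is attempted because planar-spiral formulas need the exact
    layer-by-layer turn distribution, which is a fabrication detail.
    """

    n_turns: int
    r_outer: float
    r_inner: float
    trace_width: float
    turn_spacing: float
    inductance: float
    series_resistance: float
    n_layers: int = 2

    def __post_init__(self) -> None:
        if not (self.r_outer > self.r_inner > 0.0):
            raise InvalidGeometryError(
                f"need r_outer > r_inner > 0, got {self.r_outer}, {self.r_inner}"
            )
        if self.n_turns < 1:
            raise InvalidGeometryError(f"need n_turns >= 1, got {self.n_turns}")
        if self.inductance <= 0.0:
            raise InvalidGeometryError(f"inductance must be > 0, got {self.inductance}")
        if self.series_resistance < 0.0:
            raise InvalidGeometryError("series resistance must be >= 0")


@dataclass(frozen=True)
class InterdigitatedElectrodeArray:
    """Comb electrodes on the receiver disc; a distributed parallel-plate capacitor.

    ``cover_medium`` supplies the permittivity of whatever sits on top of the
    fingers (the aqueous sample for an uncovered array).
    """

    n_fingers: int
    finger_length: float
    finger_width: float
    gap: float
    copper_height: float = 35e-6  # 1 oz copper
    cover_medium: DielectricMaterial = field(
        default_factory=lambda: DielectricMaterial(epsilon_r=80.0, sigma=0.0, name="water cover")
    )

    def __post_init__(self) -> None:
        if self.n_fingers < 2:
            raise InvalidGeometryError(f"need n_fingers >= 2, got {self.n_fingers}")
        for name in ("finger_length", "finger_width", "gap"):
            if getattr(self, name) <= 0.0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.copper_height < 0.0:
            raise InvalidGeometryError("copper_height must be >= 0")


@dataclass(frozen=True)
class ReceiverTank:
    """Receiver coil + electrodes + optional discrete capacitor: the LC tank.

    ``c_parasitic_override``, if given, replaces the geometric
    C_electrode + C_coil estimate with a measured/inferred parasitic value
    (the route taken when a resonance curve is available).
    """

    coil: PlanarCoil
    electrodes: InterdigitatedElectrodeArray
    c_added: float = 0.0
    coil_plane_gap: float = 1.0e-3  # 1 mm board thickness
    substrate: DielectricMaterial = field(default_factory=lambda: FR4)
    coil_plane_r_outer: Optional[float] = None
    coil_plane_r_inner: Optional[float] = None
    c_parasitic_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c_added < 0.0:
            raise InvalidGeometryError("c_added must be >= 0")
        if self.coil_plane_gap <= 0.0:
            raise InvalidGeometryError("coil_plane_gap must be > 0")
        if self.c_parasitic_override is not None and self.c_parasitic_override < 0.0:
            raise InvalidGeometryError("c_parasitic_override must be >= 0")

    @property
    def plane_r_outer(self) -> float:
        return self.coil_plane_r_outer if self.coil_plane_r_outer is not None else self.coil.r_outer

    @property
    def plane_r_inner(self) -> float:
        return self.coil_plane_r_inner if self.coil_plane_r_inner is not None else self.coil.r_inner


@dataclass(frozen=True)
class TransmitterDrive:
    """The AC source: peak-to-peak voltage, frequency, and output resistance."""

    v_pp: float
    frequency: float
    source_resistance: float = 50.0

    def __post_init__(self) -> None:
        if self.v_pp <= 0.0:
            raise InvalidGeometryError("v_pp must be > 0")
        if self.frequency <= 0.0:
            raise InvalidGeometryError("frequency must be > 0")
        if self.source_resistance < 0.0:
            raise InvalidGeometryError("source_resistance must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Magnetic coupling between the coils, 0 ≤ k ≤ 1."""

    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.k <= 1.0):
            raise DomainError(f"coupling coefficient must be in [0, 1], got {self.k}")


@dataclass(frozen=True)
class FrequencySweepResult:
    """Transmitter/receiver peak-to-peak voltages over a frequency sweep."""

    frequencies: np.ndarray
    v_tx_pp: np.ndarray
    v_rx_pp: np.ndarray
    resonance_peak: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "v_tx_pp": self.v_tx_pp,
                "v_rx_pp": self.v_rx_pp,
            }
        )


# --- capacitance estimates -------------------------------------------------


def electrode_capacitance(array: InterdigitatedElectrodeArray) -> float:
    """Parallel-plate estimate of the interdigitated array: C = n·2εhl/d."""
    eps = array.cover_medium.epsilon
    return array.n_fingers * 2.0 * eps * array.copper_height * array.finger_length / array.gap


def coil_plane_capacitance(tank: ReceiverTank) -> float:
    """Annular plate capacitance between the coil's two copper layers:
    C = ε·π(r_outer² − r_inner²)/d_coil, with ε of the board substrate."""
    ro, ri = tank.plane_r_outer, tank.plane_r_inner
    if ro < ri:
        raise InvalidGeometryError(f"need coil-plane r_outer >= r_inner, got {ro} < {ri}")
    return tank.substrate.epsilon * math.pi * (ro**2 - ri**2) / tank.coil_plane_gap


def total_capacitance(tank: ReceiverTank) -> float:
    """Total tank capacitance C = C_electrode + C_coil + C_add.

    If the tank carries a parasitic override (a measured value inferred from a
    resonance curve), it stands in for the two geometric terms.
    """
    if tank.c_parasitic_override is not None:
        return tank.c_parasitic_override + tank.c_added
    return electrode_capacitance(tank.electrodes) + coil_plane_capacitance(tank) + tank.c_added


# --- lumped-element formulas ----------------------------------------------


def resonance_frequency(inductance: float, capacitance: float) -> float:
    """LC resonance f = 1/(2π√(LC))."""
    if inductance <= 0.0 or capacitance <= 0.0:
        raise DomainError("L and C must both be > 0")
    return 1.0 / (2.0 * math.pi * math.sqrt(inductance * capacitance))


def capacitance_from_resonance(inductance: float, frequency: float) -> float:
    """Invert the resonance formula: C = 1/((2πf)²·L)."""
    if inductance <= 0.0 or frequency <= 0.0:
        raise DomainError("L and f must both be > 0")
    return 1.0 / ((2.0 * math.pi * frequency) ** 2 * inductance)


def mutual_inductance(l1: float, l2: float, k: float) -> float:
    """M = k·√(L1·L2)."""
    if l1 <= 0.0 or l2 <= 0.0:
        raise DomainError("inductances must be > 0")
    if not (0.0 <= k <= 1.0):
        raise DomainError(f"coupling coefficient must be in [0, 1], got {k}")
    return k * math.sqrt(l1 * l2)


def quality_factor(frequency: float, inductance: float, resistance: float) -> float:
    """Q = 2πfL/R."""
    if resistance <= 0.0:
        raise DomainError("resistance must be > 0 (infinite Q not represented)")
    return 2.0 * math.pi * frequency * inductance / resistance


def link_efficiency(k: float, q1: float, q2: float) -> float:
    """IPT link efficiency η = k²Q1Q2/(1 + k²Q1Q2) ∈ [0, 1)."""
    if not (0.0 <= k <= 1.0):
        raise DomainError(f"coupling coefficient must be in [0, 1], got {k}")
    if q1 < 0.0 or q2 < 0.0:
        raise DomainError("quality factors must be >= 0")
    x = k * k * q1 * q2
    return x / (1.0 + x)


def induced_voltage_amplitude(n_turns: int, flux_amplitude: float, frequency: float) -> float:
    """Peak of the Faraday EMF V = −N·dΦ/dt for Φ(t) = Φ₀ sin(2πft): N·2πf·Φ₀."""
    if n_turns < 0 or flux_amplitude < 0.0 or frequency < 0.0:
        raise DomainError("all arguments must be >= 0")
    return n_turns * 2.0 * math.pi * frequency * flux_amplitude


def required_added_capacitance(
    inductance: float, c_parasitic: float, f_target: float
) -> float:
    """Discrete capacitor needed to bring the tank resonance down to f_target.

    C_add = 1/((2π f_target)² L) − c_parasitic.  Raises if f_target lies
    above the bare-tank resonance (capacitance can only be added, never
    removed).
    """
    if inductance <= 0.0 or f_target <= 0.0 or c_parasitic < 0.0:
        raise DomainError("need L > 0, f_target > 0, c_parasitic >= 0")
    c_needed = capacitance_from_resonance(inductance, f_target)
    c_add = c_needed - c_parasitic
    if -1e-9 * c_needed <= c_add < 0.0:  # f_target == bare resonance up to rounding
        return 0.0
    if c_add < 0.0:
        raise InfeasibleDesignError(
            f"target {f_target:g} Hz is above the bare-tank resonance; "
            "cannot reach it by adding capacitance"
        )
    return c_add


# --- coupled two-mesh frequency sweep --------------------------------------


def _two_mesh_response(
    freqs: np.ndarray,
    r_source: float,
    r_tx: float,
    l_tx: float,
    r_rx: float,
    l_rx: float,
    c_total: float,
    k: float,
    v_source_amplitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex (V_tx, V_rx) amplitudes of the coupled circuit at each frequency."""
    w = 2.0 * np.pi * freqs
    m = mutual_inductance(l_tx, l_rx, k) if k > 0.0 else 0.0
    z11 = r_source + r_tx + 1j * w * l_tx
    z22 = r_rx + 1j * w * l_rx + 1.0 / (1j * w * c_total)
    zm = 1j * w * m
    det = z11 * z22 - zm * zm
    if np.any(det == 0.0):
        raise DomainError("singular mesh system (all impedances zero at some frequency)")
    i1 = v_source_amplitude * z22 / det
    i2 = -v_source_amplitude * zm / det
    v_tx = (r_tx + 1j * w * l_tx) * i1 + zm * i2  # across the transmitter coil
    v_rx = i2 / (1j * w * c_total)  # across the tank capacitance / electrodes
    return v_tx, v_rx


def sweep_receiver_voltage(
    tx_coil: PlanarCoil,
    rx_tank: ReceiverTank,
    coupling: CouplingSpec,
    drive: TransmitterDrive,
    f_min: float,
    f_max: float,
    n_points: int = 400,
) -> FrequencySweepResult:
    """Sweep the drive frequency and record transmitter/receiver Vpp.

    Solves the two coupled mesh equations per frequency; the receiver voltage
    is taken across the total tank capacitance.  The reported
    ``resonance_peak`` is the frequency of the receiver-voltage maximum.
    """
    if not (0.0 < f_min < f_max):
        raise DomainError("need 0 < f_min < f_max")
    if n_points < 2:
        raise DomainError("need n_points >= 2")
    freqs = np.linspace(f_min, f_max, n_points)
    c_total = total_capacitance(rx_tank)
    if c_total <= 0.0:
        raise DomainError("total tank capacitance must be > 0 for a sweep")
    v_src = drive.v_pp / 2.0  # amplitude of the sinusoidal source
    v_tx, v_rx = _two_mesh_response(
        freqs,
        drive.source_resistance,
        tx_coil.series_resistance,
        tx_coil.inductance,
        rx_tank.coil.series_resistance,
        rx_tank.coil.inductance,
        c_total,
        coupling.k,
        v_src,
    )
    v_tx_pp = 2.0 * np.abs(v_tx)
    v_rx_pp = 2.0 * np.abs(v_rx)
    peak = float(freqs[int(np.argmax(v_rx_pp))])
    return FrequencySweepResult(
        frequencies=freqs, v_tx_pp=v_tx_pp, v_rx_pp=v_rx_pp, resonance_peak=peak
    )


@dataclass(frozen=True)
class CouplingFit:
    """Result of calibrating (k, R_rx) against a measured receiver curve."""

    k: float
    r_rx: float
    residual_norm: float


def fit_coupling_and_loss(
    sweep: FrequencySweepResult,
    tx_coil: PlanarCoil,
    rx_tank: ReceiverTank,
    drive: TransmitterDrive,
    k_init: float = 0.3,
    r_init: float = 5.0,
) -> CouplingFit:
    """Least-squares fit of coupling coefficient and receiver coil resistance.

    The device's k and coil losses are rarely known a priori; this calibrates
    them against a measured receiver-voltage curve using the forward two-mesh
    model.  Requires at least 5 points with an interior, nonzero peak.
    """
    freqs = np.asarray(sweep.frequencies, dtype=float)
    v_obs = np.asarray(sweep.v_rx_pp, dtype=float)
    if freqs.size < 5:
        raise FitError("need at least 5 sweep points")
    i_max = int(np.argmax(v_obs))
    if v_obs[i_max] <= 0.0:
        raise FitError("receiver curve is identically zero; nothing to fit")
    if i_max == 0 or i_max == freqs.size - 1:
        raise FitError("no interior peak in the swept range; widen the sweep")

    c_total = total_capacitance(rx_tank)
    v_src = drive.v_pp / 2.0

    def residuals(params: np.ndarray) -> np.ndarray:
        k, r_rx = params
        _, v_rx = _two_mesh_response(
            freqs,
            drive.source_resistance,
            tx_coil.series_resistance,
            tx_coil.inductance,
            r_rx,
            rx_tank.coil.inductance,
            c_total,
            k,
            v_src,
        )
        return 2.0 * np.abs(v_rx) - v_obs

    result = least_squares(
        residuals,
        x0=[k_init, r_init],
        bounds=([0.0, 1e-6], [1.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not result.success:
        raise FitError(f"fit did not converge: {result.message}")
    k_hat, r_hat = result.x
    return CouplingFit(k=float(k_hat), r_rx=float(r_hat), residual_norm=float(np.linalg.norm(result.fun)))
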