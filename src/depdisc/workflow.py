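"""The end-to-end design workflow.

Runs, in order: tank capacitance estimate → resonance prediction →
recommended added capacitance for the drive frequency → coupled-circuit
frequency sweep → Clausius–Mossotti factor at the drive frequency → electrode
unit-cell field solve → trap-versus-wash check at the stated spin speed.  The
result is a :class:`DesignReport` carrying every intermediate quantity plus a
provenance block (config hash, seed, version).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any, Optional

from . import __version__
from .circuit import (
    coil_plane_capacitance,
    electrode_capacitance,
    required_added_capacitance,
    resonance_frequency,
    sweep_receiver_voltage,
    total_capacitance,
)
from .config import DesignCase, config_hash
from .dep import clausius_mossotti, crossover_frequency
from .errors import DepDiscError, InfeasibleDesignError
from .field import solve_unit_cell
from .trajectory import trapping_map

__all__ = ["DesignReport", "StageError", "run_design"]

log = logging.getLogger("depdisc.workflow")


class StageError(DepDiscError, RuntimeError):
    """A workflow stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, partial: dict[str, Any]):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


@dataclass(frozen=True)
class DesignReport:
    """All quantities the workflow computes for one design case."""

    name: str
    c_electrode_f: Optional[float]
    c_coil_f: Optional[float]
    c_parasitic_f: float
    c_total_f: float
    resonance_hz: float
    c_add_recommended_f: Optional[float]
    sweep_peak_hz: float
    v_rx_pp_at_drive: float
    v_rx_pp_peak: float
    cm_at_drive: complex
    crossover_hz: Optional[float]
    trap_outcome_fraction: float
    trap_outcomes: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "c_electrode_f": self.c_electrode_f,
            "c_coil_f": self.c_coil_f,
            "c_parasitic_f": self.c_parasitic_f,
            "c_total_f": self.c_total_f,
            "resonance_peak_hz": self.resonance_hz,
            "recommended_c_add_f": self.c_add_recommended_f,
            "sweep_peak_hz": self.sweep_peak_hz,
            "v_rx_pp_at_drive": self.v_rx_pp_at_drive,
            "v_rx_pp_peak": self.v_rx_pp_peak,
            "cm_at_drive_re": self.cm_at_drive.real,
            "cm_at_drive_im": self.cm_at_drive.imag,
            "crossover_hz": self.crossover_hz,
            "trapped_fraction": self.trap_outcome_fraction,
            "trap_outcomes": self.trap_outcomes,
            "provenance": self.provenance,
        }


def run_design(
    case: DesignCase,
    seed: int = 0,
    resolution: int = 64,
    n_starts: int = 9,
    sweep_points: int = 400,
) -> DesignReport:
    """Execute the full workflow for one case.

    ``seed`` only feeds the provenance block today (the pipeline itself is
    deterministic) but is threaded through so stochastic extensions stay
    reproducible.  Any stage failure raises :class:`StageError` carrying the
    partial results accumulated so far.
    """
    partial: dict[str, Any] = {}
    stage = "capacitance"
    t0 = time.perf_counter()
    try:
        tank = case.tank
        if tank.c_parasitic_override is not None:
            c_el = c_coil = None
            c_par = tank.c_parasitic_override
        else:
            c_el = electrode_capacitance(tank.electrodes)
            c_coil = coil_plane_capacitance(tank)
            c_par = c_el + c_coil
        c_total = total_capacitance(tank)
        partial.update(c_electrode_f=c_el, c_coil_f=c_coil, c_parasitic_f=c_par, c_total_f=c_total)
        _log_stage(stage, t0)

        stage = "resonance"
        t0 = time.perf_counter()
        f_res = resonance_frequency(tank.coil.inductance, c_total)
        partial["resonance_hz"] = f_res
        _log_stage(stage, t0)

        stage = "recommend_c_add"
        t0 = time.perf_counter()
        try:
            c_add_rec = required_added_capacitance(
                tank.coil.inductance, c_par, case.drive.frequency
            )
        except InfeasibleDesignError:
            c_add_rec = None  # drive already above the bare-tank resonance
        partial["c_add_recommended_f"] = c_add_rec
        _log_stage(stage, t0)

        stage = "sweep"
        t0 = time.perf_counter()
        f_lo, f_hi = 0.3 * f_res, 2.0 * f_res
        sweep = sweep_receiver_voltage(
            case.tx_coil, tank, case.coupling, case.drive, f_lo, f_hi, sweep_points
        )
        import numpy as np

        v_at_drive = float(
            np.interp(case.drive.frequency, sweep.frequencies, sweep.v_rx_pp, left=0.0, right=0.0)
        )
        partial.update(
            sweep_peak_hz=sweep.resonance_peak,
            v_rx_pp_at_drive=v_at_drive,
            v_rx_pp_peak=float(sweep.v_rx_pp.max()),
        )
        _log_stage(stage, t0)

        stage = "cm_factor"
        t0 = time.perf_counter()
        cm = clausius_mossotti(case.suspension.particle, case.suspension.medium, case.drive.frequency)
        fx = crossover_frequency(case.suspension.particle, case.suspension.medium)
        partial.update(cm_at_drive=cm, crossover_hz=fx)
        _log_stage(stage, t0)

        stage = "field_solve"
        t0 = time.perf_counter()
        # the workflow drives the electrodes with the voltage the link delivers;
        # solve at a 1 V reference and rescale (|E|² scales as V²)
        from .field import UnitCellGeometry

        geom_ref = UnitCellGeometry(
            electrode_width=case.unit_cell.electrode_width,
            gap=case.unit_cell.gap,
            channel_height=case.unit_cell.channel_height,
            applied_v_pp=1.0,
            copper_height=case.unit_cell.copper_height,
        )
        fmap = solve_unit_cell(geom_ref, resolution=resolution).scaled(max(v_at_drive, 1e-30))
        _log_stage(stage, t0)

        stage = "trap_check"
        t0 = time.perf_counter()
        tmap = trapping_map(case.suspension, case.drive.frequency, fmap, case.spin, n_starts)
        partial.update(trapped_fraction=tmap.fraction_trapped, trap_outcomes=tmap.outcomes)
        _log_stage(stage, t0)
    except Exception as exc:  # noqa: BLE001 - every stage failure carries its context
        raise StageError(stage, exc, partial) from exc

    return DesignReport(
        name=case.name,
        c_electrode_f=c_el,
        c_coil_f=c_coil,
        c_parasitic_f=c_par,
        c_total_f=c_total,
        resonance_hz=f_res,
        c_add_recommended_f=c_add_rec,
        sweep_peak_hz=sweep.resonance_peak,
        v_rx_pp_at_drive=v_at_drive,
        v_rx_pp_peak=float(sweep.v_rx_pp.max()),
        cm_at_drive=cm,
        crossover_hz=fx,
        trap_outcome_fraction=tmap.fraction_trapped,
        trap_outcomes=tmap.outcomes,
        provenance={
            "config_hash": config_hash(case),
            "seed": seed,
            "version": __version__,
            "resolution": resolution,
            "n_starts": n_starts,
        },
    )


def _log_stage(stage: str, t0: float) -> None:
    log.info("stage %-16s %.3f s", stage, time.perf_counter() - t0)
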