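"""TOML configuration for complete design cases.

A design case bundles everything needed to run the full workflow: the two
coils, the electrode array, the tank capacitances, the drive signal, the
coupling, the suspension, the spin condition and the field-solve unit cell.
Keys carry their SI unit as a suffix (``gap_m``, ``inductance_h``,
``sigma_s_per_m``); unknown keys are rejected and validation errors name the
offending dotted path.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .circuit import (
    CouplingSpec,
    InterdigitatedElectrodeArray,
    PlanarCoil,
    ReceiverTank,
    TransmitterDrive,
)
from .errors import ConfigError
from .field import UnitCellGeometry
from .materials import DielectricMaterial, SphericalParticle, Suspension
from .trajectory import SpinCondition

__all__ = ["DesignCase", "load_case", "case_to_dict", "dump_case", "config_hash"]


# key -> (constraint, required, default). Constraints: pos, nonneg, frac (0..1),
# int_pos, ge1_warn (handled by DielectricMaterial itself), any.
_SCHEMA: dict[str, dict[str, tuple[str, bool, Any]]] = {
    "case": {"name": ("str", False, "unnamed")},
    "tx_coil": {
        "n_turns": ("int_pos", True, None),
        "r_outer_m": ("pos", True, None),
        "r_inner_m": ("pos", True, None),
        "trace_width_m": ("pos", True, None),
        "turn_spacing_m": ("pos", True, None),
        "n_layers": ("int_pos", False, 2),
        "inductance_h": ("pos", True, None),
        "series_resistance_ohm": ("nonneg", True, None),
    },
    "rx_coil": {
        "n_turns": ("int_pos", True, None),
        "r_outer_m": ("pos", True, None),
        "r_inner_m": ("pos", True, None),
        "trace_width_m": ("pos", True, None),
        "turn_spacing_m": ("pos", True, None),
        "n_layers": ("int_pos", False, 2),
        "inductance_h": ("pos", True, None),
        "series_resistance_ohm": ("nonneg", True, None),
    },
    "electrodes": {
        "n_fingers": ("int_pos", True, None),
        "finger_length_m": ("pos", True, None),
        "finger_width_m": ("pos", True, None),
        "gap_m": ("pos", True, None),
        "copper_height_m": ("nonneg", False, 35e-6),
        "cover_epsilon_r": ("pos", False, 80.0),
        "cover_sigma_s_per_m": ("nonneg", False, 0.0),
    },
    "tank": {
        "c_added_f": ("nonneg", False, 0.0),
        "coil_plane_gap_m": ("pos", False, 1.0e-3),
        "substrate_epsilon_r": ("pos", False, 4.5),
        "coil_plane_r_outer_m": ("pos", False, None),
        "coil_plane_r_inner_m": ("pos", False, None),
        "c_parasitic_override_f": ("nonneg", False, None),
    },
    "drive": {
        "v_pp": ("pos", True, None),
        "frequency_hz": ("pos", True, None),
        "source_resistance_ohm": ("nonneg", False, 50.0),
    },
    "coupling": {"k": ("frac", True, None)},
    "particle": {
        "epsilon_r": ("pos", True, None),
        "sigma_s_per_m": ("nonneg", True, None),
        "radius_m": ("pos", True, None),
        "density_kg_per_m3": ("pos", False, 1050.0),
    },
    "medium": {
        "epsilon_r": ("pos", True, None),
        "sigma_s_per_m": ("nonneg", True, None),
        "viscosity_pa_s": ("pos", False, 1.0e-3),
        "density_kg_per_m3": ("pos", False, 1000.0),
    },
    "spin": {
        "rpm": ("nonneg", True, None),
        "radial_position_m": ("pos", False, 25e-3),
    },
    "unit_cell": {
        "electrode_width_m": ("pos", True, None),
        "gap_m": ("pos", True, None),
        "channel_height_m": ("pos", False, 100e-6),
        "applied_v_pp": ("nonneg", True, None),
    },
}


@dataclass(frozen=True)
class DesignCase:
    """A fully validated design case, ready for the workflow."""

    name: str
    tx_coil: PlanarCoil
    tank: ReceiverTank
    drive: TransmitterDrive
    coupling: CouplingSpec
    suspension: Suspension
    spin: SpinCondition
    unit_cell: UnitCellGeometry


def _check(section: str, key: str, kind: str, value: Any) -> Any:
    path = f"{section}.{key}"
    if kind == "str":
        if not isinstance(value, str):
            raise ConfigError("expected a string", field=path)
        return value
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError("expected a number", field=path)
    v = float(value)
    if kind == "int_pos":
        if value != int(value) or value < 1:
            raise ConfigError("expected a positive integer", field=path)
        return int(value)
    if kind == "pos" and v <= 0.0:
        raise ConfigError(f"must be > 0, got {value}", field=path)
    if kind == "nonneg" and v < 0.0:
        raise ConfigError(f"must be >= 0, got {value}", field=path)
    if kind == "frac" and not (0.0 <= v <= 1.0):
        raise ConfigError(f"must be in [0, 1], got {value}", field=path)
    return v


def validate_config(raw: dict[str, Any]) -> dict[str, Any]:
    """Validate a parsed TOML mapping against the schema; fill defaults."""
    out: dict[str, Any] = {}
    for section in raw:
        if section not in _SCHEMA:
            raise ConfigError("unknown section", field=section)
        if not isinstance(raw[section], dict):
            raise ConfigError("expected a table", field=section)
    for section, keys in _SCHEMA.items():
        given = raw.get(section, {})
        for key in given:
            if key not in keys:
                raise ConfigError("unknown key", field=f"{section}.{key}")
        sec_out: dict[str, Any] = {}
        for key, (kind, required, default) in keys.items():
            if key in given:
                sec_out[key] = _check(section, key, kind, given[key])
            elif required:
                raise ConfigError("missing required key", field=f"{section}.{key}")
            elif default is not None:
                sec_out[key] = default
        out[section] = sec_out
    # cross-field checks that the dataclasses would only report without a path
    for coil in ("tx_coil", "rx_coil"):
        if out[coil]["r_outer_m"] <= out[coil]["r_inner_m"]:
            raise ConfigError("r_outer_m must exceed r_inner_m", field=f"{coil}.r_outer_m")
    if out["electrodes"]["n_fingers"] < 2:
        raise ConfigError("need at least 2 fingers", field="electrodes.n_fingers")
    return out


def _coil_from(sec: dict[str, Any]) -> PlanarCoil:
    return PlanarCoil(
        n_turns=sec["n_turns"],
        r_outer=sec["r_outer_m"],
        r_inner=sec["r_inner_m"],
        trace_width=sec["trace_width_m"],
        turn_spacing=sec["turn_spacing_m"],
        n_layers=sec["n_layers"],
        inductance=sec["inductance_h"],
        series_resistance=sec["series_resistance_ohm"],
    )


def case_from_dict(raw: dict[str, Any]) -> DesignCase:
    """Build a validated :class:`DesignCase` from a parsed TOML mapping."""
    cfg = validate_config(raw)
    electrodes = InterdigitatedElectrodeArray(
        n_fingers=cfg["electrodes"]["n_fingers"],
        finger_length=cfg["electrodes"]["finger_length_m"],
        finger_width=cfg["electrodes"]["finger_width_m"],
        gap=cfg["electrodes"]["gap_m"],
        copper_height=cfg["electrodes"]["copper_height_m"],
        cover_medium=DielectricMaterial(
            epsilon_r=cfg["electrodes"]["cover_epsilon_r"],
            sigma=cfg["electrodes"]["cover_sigma_s_per_m"],
        ),
    )
    tank = ReceiverTank(
        coil=_coil_from(cfg["rx_coil"]),
        electrodes=electrodes,
        c_added=cfg["tank"]["c_added_f"],
        coil_plane_gap=cfg["tank"]["coil_plane_gap_m"],
        substrate=DielectricMaterial(epsilon_r=cfg["tank"]["substrate_epsilon_r"], sigma=0.0),
        coil_plane_r_outer=cfg["tank"].get("coil_plane_r_outer_m"),
        coil_plane_r_inner=cfg["tank"].get("coil_plane_r_inner_m"),
        c_parasitic_override=cfg["tank"].get("c_parasitic_override_f"),
    )
    suspension = Suspension(
        particle=SphericalParticle(
            radius=cfg["particle"]["radius_m"],
            material=DielectricMaterial(
                epsilon_r=cfg["particle"]["epsilon_r"], sigma=cfg["particle"]["sigma_s_per_m"]
            ),
        ),
        medium=DielectricMaterial(
            epsilon_r=cfg["medium"]["epsilon_r"], sigma=cfg["medium"]["sigma_s_per_m"]
        ),
        viscosity=cfg["medium"]["viscosity_pa_s"],
        density_particle=cfg["particle"]["density_kg_per_m3"],
        density_medium=cfg["medium"]["density_kg_per_m3"],
    )
    return DesignCase(
        name=cfg["case"]["name"],
        tx_coil=_coil_from(cfg["tx_coil"]),
        tank=tank,
        drive=TransmitterDrive(
            v_pp=cfg["drive"]["v_pp"],
            frequency=cfg["drive"]["frequency_hz"],
            source_resistance=cfg["drive"]["source_resistance_ohm"],
        ),
        coupling=CouplingSpec(k=cfg["coupling"]["k"]),
        suspension=suspension,
        spin=SpinCondition(
            rpm=cfg["spin"]["rpm"], radial_position=cfg["spin"]["radial_position_m"]
        ),
        unit_cell=UnitCellGeometry(
            electrode_width=cfg["unit_cell"]["electrode_width_m"],
            gap=cfg["unit_cell"]["gap_m"],
            channel_height=cfg["unit_cell"]["channel_height_m"],
            applied_v_pp=cfg["unit_cell"]["applied_v_pp"],
        ),
    )


def load_case(path: str | Path) -> DesignCase:
    """Load and validate a design case from a TOML file."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"no such config file: {path}")
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"TOML parse error in {path}: {exc}")
    return case_from_dict(raw)


def case_to_dict(case: DesignCase) -> dict[str, Any]:
    """Serialize a DesignCase back to the TOML schema (inverse of load)."""

    def coil_sec(c: PlanarCoil) -> dict[str, Any]:
        return {
            "n_turns": c.n_turns,
            "r_outer_m": c.r_outer,
            "r_inner_m": c.r_inner,
            "trace_width_m": c.trace_width,
            "turn_spacing_m": c.turn_spacing,
            "n_layers": c.n_layers,
            "inductance_h": c.inductance,
            "series_resistance_ohm": c.series_resistance,
        }

    t, e, s = case.tank, case.tank.electrodes, case.suspension
    out: dict[str, Any] = {
        "case": {"name": case.name},
        "tx_coil": coil_sec(case.tx_coil),
        "rx_coil": coil_sec(t.coil),
        "electrodes": {
            "n_fingers": e.n_fingers,
            "finger_length_m": e.finger_length,
            "finger_width_m": e.finger_width,
            "gap_m": e.gap,
            "copper_height_m": e.copper_height,
            "cover_epsilon_r": e.cover_medium.epsilon_r,
            "cover_sigma_s_per_m": e.cover_medium.sigma,
        },
        "tank": {
            "c_added_f": t.c_added,
            "coil_plane_gap_m": t.coil_plane_gap,
            "substrate_epsilon_r": t.substrate.epsilon_r,
        },
        "drive": {
            "v_pp": case.drive.v_pp,
            "frequency_hz": case.drive.frequency,
            "source_resistance_ohm": case.drive.source_resistance,
        },
        "coupling": {"k": case.coupling.k},
        "particle": {
            "epsilon_r": s.particle.material.epsilon_r,
            "sigma_s_per_m": s.particle.material.sigma,
            "radius_m": s.particle.radius,
            "density_kg_per_m3": s.density_particle,
        },
        "medium": {
            "epsilon_r": s.medium.epsilon_r,
            "sigma_s_per_m": s.medium.sigma,
            "viscosity_pa_s": s.viscosity,
            "density_kg_per_m3": s.density_medium,
        },
        "spin": {"rpm": case.spin.rpm, "radial_position_m": case.spin.radial_position},
        "unit_cell": {
            "electrode_width_m": case.unit_cell.electrode_width,
            "gap_m": case.unit_cell.gap,
            "channel_height_m": case.unit_cell.channel_height,
            "applied_v_pp": case.unit_cell.applied_v_pp,
        },
    }
    if t.coil_plane_r_outer is not None:
        out["tank"]["coil_plane_r_outer_m"] = t.coil_plane_r_outer
    if t.coil_plane_r_inner is not None:
        out["tank"]["coil_plane_r_inner_m"] = t.coil_plane_r_inner
    if t.c_parasitic_override is not None:
        out["tank"]["c_parasitic_override_f"] = t.c_parasitic_override
    return out


def _toml_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_config(cfg: dict[str, Any]) -> str:
    """Serialize a section/scalar mapping to TOML text (sorted, stable)."""
    lines: list[str] = []
    for section in cfg:
        lines.append(f"[{section}]")
        for key, value in cfg[section].items():
            lines.append(f"{key} = {_toml_scalar(value)}")
        lines.append("")
    return "\n".join(lines)


def dump_case(case: DesignCase, path: str | Path) -> None:
    """Write a DesignCase to a TOML file; ``load_case`` round-trips it."""
    Path(path).write_text(dumps_config(case_to_dict(case)))


def config_hash(case: DesignCase) -> str:
    """Stable SHA-256 of the case's canonical TOML serialization."""
    return hashlib.sha256(dumps_config(case_to_dict(case)).encode()).hexdigest()[:16]
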