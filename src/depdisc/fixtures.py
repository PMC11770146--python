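"""Named design-case presets and a seeded random-case generator.

The named presets encode the reference device: a 13-turn receiver coil
(22 mm outer / 10 mm inner diameter, 1.8 mm trace, 0.2 mm spacing) on a 1 mm
FR4 disc, interdigitated electrodes with ~75 µm traces and ~125 µm gaps, a
4.6 µH measured coil inductance, a 35 pF parasitic tank capacitance inferred
from the bare resonance curve, and a 450 pF discrete capacitor that shifts
the resonance from ~12.5 MHz down to ~3.5 MHz.  Quantities the device
characterisation leaves open (coupling coefficient, coil resistance,
particle/medium dielectric parameters, disc radial position, channel height)
carry documented defaults — see docs/methods.md.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np

from .config import DesignCase, case_from_dict, dumps_config
from .errors import ConfigError

__all__ = ["FIXTURE_NAMES", "fixture_config", "make_fixture", "make_random_config", "write_fixture"]

# Receiver/transmitter coil of the reference device. Inductance stored as
# 4.6 µH: the value consistent with the observed 12.5 MHz / 35 pF resonance.
_COIL = {
    "n_turns": 13,
    "r_outer_m": 11e-3,
    "r_inner_m": 5e-3,
    "trace_width_m": 1.8e-3,
    "turn_spacing_m": 0.2e-3,
    "n_layers": 2,
    "inductance_h": 4.6e-6,
    "series_resistance_ohm": 5.0,
}

_ELECTRODES = {
    "n_fingers": 10,
    "finger_length_m": 5e-3,
    "finger_width_m": 75e-6,
    "gap_m": 125e-6,
    "copper_height_m": 35e-6,
    "cover_epsilon_r": 80.0,
    "cover_sigma_s_per_m": 2.0e-4,
}

_UNIT_CELL = {
    "electrode_width_m": 75e-6,
    "gap_m": 125e-6,
    "channel_height_m": 100e-6,
}

# Effective dielectric parameters; see docs/methods.md for provenance.
_POLYSTYRENE = {
    "epsilon_r": 2.55,
    "sigma_s_per_m": 0.1,
    "radius_m": 2.5e-6,
    "density_kg_per_m3": 1050.0,
}
_YEAST = {
    "epsilon_r": 60.0,
    "sigma_s_per_m": 0.25,
    "radius_m": 3.0e-6,
    "density_kg_per_m3": 1100.0,
}
_DI_WATER = {
    "epsilon_r": 80.0,
    "sigma_s_per_m": 2.0e-4,
    "viscosity_pa_s": 1.0e-3,
    "density_kg_per_m3": 1000.0,
}


def _base(name: str) -> dict[str, Any]:
    return {
        "case": {"name": name},
        "tx_coil": dict(_COIL),
        "rx_coil": dict(_COIL),
        "electrodes": dict(_ELECTRODES),
        "tank": {
            "c_added_f": 0.0,
            "coil_plane_gap_m": 1.0e-3,
            "substrate_epsilon_r": 4.5,
            "c_parasitic_override_f": 35e-12,
        },
        "drive": {"v_pp": 18.0, "frequency_hz": 3.5e6, "source_resistance_ohm": 50.0},
        "coupling": {"k": 0.2},
        "particle": dict(_POLYSTYRENE),
        "medium": dict(_DI_WATER),
        "spin": {"rpm": 1000.0, "radial_position_m": 25e-3},
        "unit_cell": dict(_UNIT_CELL),
    }


def _depdisc_paper() -> dict[str, Any]:
    """Resonant reference case: 450 pF added, drive at the shifted resonance."""
    cfg = _base("depdisc_paper")
    cfg["tank"]["c_added_f"] = 450e-12
    cfg["unit_cell"]["applied_v_pp"] = 55.0  # measured electrode signal at resonance
    return cfg


def _depdisc_yeast() -> dict[str, Any]:
    """Yeast manipulation at 3.5 MHz with the resonance-boosted 55 Vpp."""
    cfg = _base("depdisc_yeast")
    cfg["tank"]["c_added_f"] = 450e-12
    cfg["particle"] = dict(_YEAST)
    cfg["spin"]["rpm"] = 0.0  # stationary observation under a coverslip
    cfg["unit_cell"]["applied_v_pp"] = 55.0
    return cfg


def _polystyrene_beads() -> dict[str, Any]:
    """Non-resonant bead validation: 7 MHz, 20 Vpp applied, disc at 1000 RPM."""
    cfg = _base("polystyrene_beads")
    cfg["drive"] = {"v_pp": 20.0, "frequency_hz": 7.0e6, "source_resistance_ohm": 50.0}
    cfg["unit_cell"]["applied_v_pp"] = 20.0
    return cfg


_PRESETS = {
    "depdisc_paper": _depdisc_paper,
    "depdisc_yeast": _depdisc_yeast,
    "polystyrene_beads": _polystyrene_beads,
}

FIXTURE_NAMES = tuple(sorted(_PRESETS))


def fixture_config(name: str) -> dict[str, Any]:
    """The raw config mapping for a named preset."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    return _PRESETS[name]()


def make_fixture(name: str) -> DesignCase:
    """A validated :class:`DesignCase` for a named preset."""
    return case_from_dict(fixture_config(name))


def make_random_config(seed: int) -> dict[str, Any]:
    """A randomized but valid case, for property tests.

    Geometry and material values are drawn from plausible PCB/colloid ranges;
    the same seed always yields the same mapping.
    """
    rng = np.random.default_rng(seed)
    cfg = _base(f"random_{seed}")
    cfg["rx_coil"]["inductance_h"] = float(rng.uniform(1e-6, 20e-6))
    cfg["tx_coil"]["inductance_h"] = float(rng.uniform(1e-6, 20e-6))
    cfg["rx_coil"]["series_resistance_ohm"] = float(rng.uniform(0.5, 20.0))
    cfg["tx_coil"]["series_resistance_ohm"] = float(rng.uniform(0.5, 20.0))
    cfg["tank"]["c_parasitic_override_f"] = float(rng.uniform(5e-12, 100e-12))
    cfg["tank"]["c_added_f"] = float(rng.choice([0.0, 1.0, 1.0]) * rng.uniform(50e-12, 1e-9))
    cfg["coupling"]["k"] = float(rng.uniform(0.05, 0.6))
    cfg["drive"]["v_pp"] = float(rng.uniform(5.0, 30.0))
    cfg["drive"]["frequency_hz"] = float(rng.uniform(1e6, 10e6))
    w = float(rng.uniform(60e-6, 150e-6))
    g = float(rng.uniform(100e-6, 200e-6))
    cfg["electrodes"]["finger_width_m"] = w
    cfg["electrodes"]["gap_m"] = g
    cfg["unit_cell"].update(electrode_width_m=w, gap_m=g, applied_v_pp=float(rng.uniform(5, 60)))
    cfg["particle"]["epsilon_r"] = float(rng.uniform(2.0, 80.0))
    cfg["particle"]["sigma_s_per_m"] = float(rng.uniform(0.0, 1.0))
    cfg["particle"]["radius_m"] = float(rng.uniform(0.5e-6, 10e-6))
    cfg["medium"]["sigma_s_per_m"] = float(rng.uniform(1e-5, 1e-2))
    cfg["spin"]["rpm"] = float(rng.uniform(0.0, 3000.0))
    return cfg


def write_fixture(name_or_seed: str | int, path: str | Path) -> Path:
    """Write a preset (by name) or randomized (by integer seed) case to TOML."""
    if isinstance(name_or_seed, int) or (
        isinstance(name_or_seed, str) and name_or_seed.lstrip("-").isdigit()
    ):
        cfg = make_random_config(int(name_or_seed))
    else:
        cfg = fixture_config(str(name_or_seed))
    path = Path(path)
    path.write_text(dumps_config(cfg))
    return path
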