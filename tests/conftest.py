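import pytest

from depdisc.field import solve_unit_cell
from depdisc.fixtures import make_fixture


@pytest.fixture(scope="session")
def beads_case():
    """Non-resonant bead validation case: 7 MHz, 20 Vpp, 1000 RPM."""
    return make_fixture("polystyrene_beads")


@pytest.fixture(scope="session")
def paper_case():
    """Resonant reference case: 450 pF added, drive at the shifted resonance."""
    return make_fixture("depdisc_paper")


@pytest.fixture(scope="session")
def yeast_case():
    return make_fixture("depdisc_yeast")


@pytest.fixture(scope="session")
def bead_field(beads_case):
    """Unit-cell field of the bead case at 20 Vpp, 64 nodes/period (shared)."""
    return solve_unit_cell(beads_case.unit_cell, resolution=64)
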