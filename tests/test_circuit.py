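"""Lumped-element formulas, the coupled two-mesh sweep, and the (k, R) fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depdisc.circuit import (
    CouplingSpec,
    InterdigitatedElectrodeArray,
    PlanarCoil,
    ReceiverTank,
    TransmitterDrive,
    capacitance_from_resonance,
    coil_plane_capacitance,
    electrode_capacitance,
    fit_coupling_and_loss,
    induced_voltage_amplitude,
    link_efficiency,
    mutual_inductance,
    quality_factor,
    required_added_capacitance,
    resonance_frequency,
    sweep_receiver_voltage,
    total_capacitance,
)
from depdisc.errors import DomainError, FitError, InfeasibleDesignError, InvalidGeometryError
from depdisc.materials import DielectricMaterial

WATER = DielectricMaterial(epsilon_r=80.0, sigma=0.0)


def _array(n=10, h=35e-6, length=5e-3, gap=125e-6, cover=WATER):
    return InterdigitatedElectrodeArray(
        n_fingers=n, finger_length=length, finger_width=75e-6, gap=gap,
        copper_height=h, cover_medium=cover,
    )


def _coil(inductance=4.6e-6, resistance=5.0):
    return PlanarCoil(
        n_turns=13, r_outer=11e-3, r_inner=5e-3, trace_width=1.8e-3,
        turn_spacing=0.2e-3, inductance=inductance, series_resistance=resistance,
    )


def _tank(c_added=0.0, override=None, resistance=5.0):
    return ReceiverTank(
        coil=_coil(resistance=resistance), electrodes=_array(),
        c_added=c_added, c_parasitic_override=override,
        substrate=DielectricMaterial(epsilon_r=4.5, sigma=0.0),
    )


class TestCapacitances:
    def test_electrode_capacitance_worked_example(self):
        # n=10, ε_r=80, h=35 µm, l=5 mm, d=125 µm
        assert electrode_capacitance(_array()) == pytest.approx(19.8e-12, rel=2e-3)

    def test_electrode_capacitance_zero_height(self):
        assert electrode_capacitance(_array(h=0.0)) == 0.0

    def test_electrode_capacitance_linear_in_fingers(self):
        assert electrode_capacitance(_array(n=20)) == pytest.approx(
            2.0 * electrode_capacitance(_array(n=10)), rel=1e-12
        )

    def test_electrode_capacitance_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            _array(gap=-1e-6)

    def test_coil_plane_capacitance_worked_example(self):
        # ε_r=4.5, r_outer=11 mm, r_inner=5 mm, d_coil=1 mm
        assert coil_plane_capacitance(_tank()) == pytest.approx(12.0e-12, rel=5e-3)

    def test_coil_plane_capacitance_zero_annulus(self):
        t = ReceiverTank(
            coil=_coil(), electrodes=_array(),
            coil_plane_r_outer=8e-3, coil_plane_r_inner=8e-3,
        )
        assert coil_plane_capacitance(t) == 0.0

    def test_coil_plane_capacitance_inverse_in_gap(self):
        t1 = _tank()
        t2 = ReceiverTank(coil=_coil(), electrodes=_array(), coil_plane_gap=0.5e-3,
                          substrate=DielectricMaterial(4.5, 0.0))
        assert coil_plane_capacitance(t2) == pytest.approx(2 * coil_plane_capacitance(t1), rel=1e-12)

    def test_total_capacitance_is_sum_of_terms(self):
        t = _tank()
        expected = electrode_capacitance(t.electrodes) + coil_plane_capacitance(t)
        assert total_capacitance(t) == pytest.approx(expected, rel=1e-12)
        assert total_capacitance(t) == pytest.approx(31.8e-12, rel=5e-3)

    def test_total_capacitance_parasitic_override(self):
        # measured 35 pF parasitic plus the 450 pF discrete capacitor
        t = _tank(c_added=450e-12, override=35e-12)
        assert total_capacitance(t) == pytest.approx(485e-12, rel=1e-12)

    def test_total_capacitance_all_zero(self):
        t = ReceiverTank(coil=_coil(), electrodes=_array(h=0.0),
                         coil_plane_r_outer=8e-3, coil_plane_r_inner=8e-3)
        assert total_capacitance(t) == 0.0


class TestResonance:
    def test_bare_tank_resonance(self):
        # L=4.6 µH with the inferred 35 pF parasitic → ~12.5 MHz
        assert resonance_frequency(4.6e-6, 35e-12) == pytest.approx(12.54e6, rel=1e-3)

    def test_unit_case(self):
        assert resonance_frequency(1.0, 1.0) == pytest.approx(1.0 / (2 * math.pi), rel=1e-12)

    def test_shifted_resonance(self):
        assert resonance_frequency(4.6e-6, 485e-12) == pytest.approx(3.37e6, rel=1e-3)

    @pytest.mark.parametrize("l,c", [(0.0, 1e-12), (1e-6, 0.0), (-1e-6, 1e-12)])
    def test_domain_errors(self, l, c):
        with pytest.raises(DomainError):
            resonance_frequency(l, c)

    def test_capacitance_inference(self):
        assert capacitance_from_resonance(4.6e-6, 12.5e6) == pytest.approx(35.2e-12, rel=2e-3)
        assert capacitance_from_resonance(1.0, 1.0 / (2 * math.pi)) == pytest.approx(1.0, rel=1e-12)

    @given(
        l=st.floats(1e-9, 1e-2), c=st.floats(1e-15, 1e-6),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, l, c):
        assert capacitance_from_resonance(l, resonance_frequency(l, c)) == pytest.approx(
            c, rel=1e-12
        )

    @given(
        l=st.floats(1e-9, 1e-2), c=st.floats(1e-15, 1e-6),
        scale=st.floats(1.001, 100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_resonance_strictly_decreasing_in_l_and_c(self, l, c, scale):
        f0 = resonance_frequency(l, c)
        assert resonance_frequency(l * scale, c) < f0
        assert resonance_frequency(l, c * scale) < f0

    def test_required_added_capacitance_design_move(self):
        # lowering the bare 12.5 MHz resonance to 3.37 MHz takes ~450 pF
        assert required_added_capacitance(4.6e-6, 35e-12, 3.37e6) == pytest.approx(
            450e-12, rel=2e-3
        )

    def test_required_added_capacitance_at_bare_resonance_is_zero(self):
        f0 = resonance_frequency(4.6e-6, 35e-12)
        assert required_added_capacitance(4.6e-6, 35e-12, f0) == pytest.approx(0.0, abs=1e-16)

    def test_required_added_capacitance_unit_case(self):
        assert required_added_capacitance(1.0, 0.0, 1.0 / (2 * math.pi)) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_required_added_capacitance_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            required_added_capacitance(4.6e-6, 35e-12, 20e6)


class TestLinkFormulas:
    def test_mutual_inductance(self):
        assert mutual_inductance(4.6e-6, 4.6e-6, 1.0) == pytest.approx(4.6e-6, rel=1e-12)
        assert mutual_inductance(4.6e-6, 4.6e-6, 0.0) == 0.0
        assert mutual_inductance(4.6e-6, 4.6e-6, 0.2) == pytest.approx(0.92e-6, rel=1e-12)
        with pytest.raises(DomainError):
            mutual_inductance(4.6e-6, 4.6e-6, 1.5)

    def test_quality_factor(self):
        assert quality_factor(3.5e6, 4.6e-6, 5.0) == pytest.approx(20.2, rel=2e-3)
        assert quality_factor(0.0, 4.6e-6, 5.0) == 0.0
        assert quality_factor(7e6, 4.6e-6, 5.0) == pytest.approx(
            2 * quality_factor(3.5e6, 4.6e-6, 5.0), rel=1e-12
        )
        with pytest.raises(DomainError):
            quality_factor(3.5e6, 4.6e-6, 0.0)

    def test_link_efficiency_examples(self):
        assert link_efficiency(0.0, 20.0, 20.0) == 0.0
        # symmetry point: k²Q1Q2 = 1 → η = 1/2
        assert link_efficiency(0.5, 2.0, 2.0) == pytest.approx(0.5, rel=1e-12)
        assert link_efficiency(0.3, 20.0, 20.0) == pytest.approx(0.973, abs=5e-4)

    @given(
        k=st.floats(0.0, 1.0), q1=st.floats(0.0, 1e4), q2=st.floats(0.0, 1e4),
        dk=st.floats(0.0, 0.5), dq=st.floats(0.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_link_efficiency_bounds_and_monotonicity(self, k, q1, q2, dk, dq):
        eta = link_efficiency(k, q1, q2)
        assert 0.0 <= eta < 1.0
        assert link_efficiency(min(k + dk, 1.0), q1, q2) >= eta
        assert link_efficiency(k, q1 + dq, q2) >= eta
        assert link_efficiency(k, q1, q2 + dq) >= eta

    def test_induced_voltage(self):
        assert induced_voltage_amplitude(13, 0.0, 3.5e6) == 0.0
        assert induced_voltage_amplitude(1, 1.0, 1.0 / (2 * math.pi)) == pytest.approx(1.0, rel=1e-12)
        assert induced_voltage_amplitude(13, 1e-9, 3.5e6) == pytest.approx(0.286, rel=2e-3)


class TestSweep:
    DRIVE = TransmitterDrive(v_pp=20.0, frequency=7e6, source_resistance=50.0)

    def test_zero_coupling_gives_zero_receiver_voltage(self):
        sw = sweep_receiver_voltage(
            _coil(), _tank(override=35e-12), CouplingSpec(0.0), self.DRIVE, 1e6, 20e6, 100
        )
        assert np.all(sw.v_rx_pp == 0.0)

    def test_low_loss_peak_matches_closed_form(self):
        # weak coupling too: the reflected impedance detunes the peak by ~k²/2
        tank = _tank(override=35e-12, resistance=0.01)
        f0 = resonance_frequency(4.6e-6, 35e-12)
        sw = sweep_receiver_voltage(
            _coil(resistance=0.01), tank, CouplingSpec(0.01), self.DRIVE,
            0.8 * f0, 1.2 * f0, 2000,
        )
        grid_step = sw.frequencies[1] - sw.frequencies[0]
        assert abs(sw.resonance_peak - f0) <= grid_step

    def test_added_capacitor_shifts_peak_near_3p4_mhz(self):
        tank = _tank(c_added=450e-12, override=35e-12, resistance=1.0)
        sw = sweep_receiver_voltage(
            _coil(resistance=1.0), tank, CouplingSpec(0.2), self.DRIVE, 1e6, 6e6, 1000
        )
        assert sw.resonance_peak == pytest.approx(3.4e6, rel=0.03)

    def test_peak_frequency_monotone_decreasing_in_added_capacitance(self):
        peaks = []
        for c_add in (0.0, 100e-12, 450e-12, 1000e-12):
            tank = _tank(c_added=c_add, override=35e-12)
            sw = sweep_receiver_voltage(
                _coil(), tank, CouplingSpec(0.2), self.DRIVE, 0.5e6, 20e6, 2000
            )
            peaks.append(sw.resonance_peak)
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_resonance_peak_within_swept_range(self):
        sw = sweep_receiver_voltage(
            _coil(), _tank(override=35e-12), CouplingSpec(0.2), self.DRIVE, 1e6, 20e6, 500
        )
        assert 1e6 <= sw.resonance_peak <= 20e6
        assert len(sw.frequencies) == len(sw.v_rx_pp) == len(sw.v_tx_pp)


class TestCouplingFit:
    DRIVE = TransmitterDrive(v_pp=20.0, frequency=7e6, source_resistance=50.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_parameter_recovery_on_synthetic_sweeps(self, seed):
        rng = np.random.default_rng(seed)
        k_true = float(rng.uniform(0.05, 0.6))
        r_true = float(rng.uniform(1.0, 15.0))
        tank = _tank(override=float(rng.uniform(10e-12, 80e-12)), resistance=r_true)
        f0 = resonance_frequency(tank.coil.inductance, total_capacitance(tank))
        sw = sweep_receiver_voltage(
            _coil(), tank, CouplingSpec(k_true), self.DRIVE, 0.3 * f0, 2.5 * f0, 250
        )
        fit = fit_coupling_and_loss(sw, _coil(), tank, self.DRIVE)
        assert fit.k == pytest.approx(k_true, rel=0.01)
        assert fit.r_rx == pytest.approx(r_true, rel=0.01)
        # noise-free synthetic data → essentially zero residual
        assert fit.residual_norm < 1e-6 * np.max(sw.v_rx_pp) * len(sw.frequencies)

    def test_flat_zero_curve_raises(self):
        tank = _tank(override=35e-12)
        sw = sweep_receiver_voltage(
            _coil(), tank, CouplingSpec(0.0), self.DRIVE, 1e6, 20e6, 100
        )
        with pytest.raises(FitError):
            fit_coupling_and_loss(sw, _coil(), tank, self.DRIVE)

    def test_too_few_points_raises(self):
        tank = _tank(override=35e-12)
        sw = sweep_receiver_voltage(_coil(), tank, CouplingSpec(0.2), self.DRIVE, 1e6, 20e6, 4)
        with pytest.raises(FitError):
            fit_coupling_and_loss(sw, _coil(), tank, self.DRIVE)
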