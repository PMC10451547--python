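import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinpot.constants import FARADAY, R_GAS
from kinpot.electrochem import (
    ElectrodeModel,
    FerroFerriCell,
    alpha_from_potentials,
    concentration_noise_sd,
    exp_delta_e,
    expected_potential_shift,
    potential_from_radicals,
    residual_concentration,
)
from kinpot.exceptions import DomainError, InputError, MediatorCapacityError
from kinpot.kinetics import Trajectory
from kinpot.trace import PotentialTrace


def _flat_trajectory(x_value: float, n: int = 100) -> Trajectory:
    t = np.arange(float(n))
    z = np.zeros(n)
    return Trajectory(
        t=t, initiator=np.full(n, 0.1), radical=np.full(n, x_value),
        inhibitors={}, cum_generated=z, cum_recombined=z, cum_scavenged=z,
        t_add=10.0,
    )


class TestElectrodeLaw:
    def test_reference_concentration_gives_reference_potential(self):
        el = ElectrodeModel(e_ref=0.25, c_ref=1e-6)
        trace = potential_from_radicals(_flat_trajectory(1e-6), el)
        assert np.allclose(trace.e, 0.25)

    def test_decade_step_is_nernstian(self):
        # RT/F * ln 10 at 310.15 K = 61.5 mV per decade
        el = ElectrodeModel()
        e1 = potential_from_radicals(_flat_trajectory(1e-7), el).e[0]
        e2 = potential_from_radicals(_flat_trajectory(1e-6), el).e[0]
        expected = 2.302585 * R_GAS * 310.15 / FARADAY
        assert e2 - e1 == pytest.approx(expected, rel=1e-6)
        assert e2 - e1 == pytest.approx(0.06153, rel=1e-3)

    def test_radical_floor_keeps_potential_finite(self):
        trace = potential_from_radicals(_flat_trajectory(0.0))
        assert np.all(np.isfinite(trace.e))

    def test_empty_trajectory_rejected(self):
        traj = _flat_trajectory(1e-6)
        traj.t = np.array([])
        with pytest.raises(InputError):
            potential_from_radicals(traj)


class TestExpDeltaE:
    def test_flat_trace_is_unity(self):
        t = np.arange(200.0)
        trace = PotentialTrace(t, np.full(200, 0.3), t_add=100.0)
        series = exp_delta_e(trace)
        assert np.allclose(series.values, 1.0)

    def test_known_drop(self):
        # dE = -0.1 V at E_s = 1 V: exp(-0.1) = 0.905
        t = np.arange(200.0)
        e = np.full(200, 0.3)
        e[t > 100] = 0.2
        trace = PotentialTrace(t, e, t_add=100.0)
        v = exp_delta_e(trace).values
        assert v[150] == pytest.approx(math.exp(-0.1), rel=1e-12)

    def test_nernst_scale_recovers_radical_ratio(self, fast_trace_075):
        """With E_s = RT/F the series is exactly a radical-concentration ratio."""
        el = ElectrodeModel()
        series = exp_delta_e(fast_trace_075, electrode=ElectrodeModel(exp_scale=el.nernst_slope))
        # reconstruct the ratio from the same trace: x ∝ exp(E/slope)
        x = np.exp(fast_trace_075.e / el.nernst_slope)
        mask = (fast_trace_075.t >= 270.0) & (fast_trace_075.t <= 300.0)
        x_base = np.exp(fast_trace_075.e[mask].mean() / el.nernst_slope)
        assert np.allclose(series.values, x / x_base, rtol=1e-10)

    @given(offset=st.floats(-1.0, 1.0))
    def test_invariant_to_reference_offset(self, offset):
        t = np.arange(200.0)
        e = 0.3 + 0.05 * np.sin(t / 30.0)
        base = exp_delta_e(PotentialTrace(t, e, t_add=100.0)).values
        shifted = exp_delta_e(PotentialTrace(t, e + offset, t_add=100.0)).values
        assert np.allclose(base, shifted, rtol=1e-9)

    def test_t_add_outside_trace_rejected(self):
        t = np.arange(200.0)
        trace = PotentialTrace(t, np.zeros(200), t_add=100.0)
        with pytest.raises(DomainError):
            exp_delta_e(trace, t_add=500.0)


class TestMediatorCell:
    cell = FerroFerriCell()  # 1 mM / 0.01 mM, 25 degC

    def test_alpha_at_equal_potentials_is_initial_ratio(self):
        assert alpha_from_potentials(0.3, 0.3, self.cell) == pytest.approx(100.0)

    def test_alpha_decade_arithmetic(self):
        de = -self.cell.slope_decade
        assert alpha_from_potentials(0.3, 0.3 + de, self.cell) == pytest.approx(
            10.0, rel=1e-9
        )

    def test_zero_shift_zero_concentration(self):
        res = residual_concentration(0.3, 0.3, self.cell)
        assert res.c_ao == pytest.approx(0.0, abs=1e-18)

    def test_spike_recovery_against_stoichiometric_oracle(self):
        """Forward Ox->Ox-x, Red->Red+x Nernst model, then inversion."""
        c_added = 5e-4
        alpha_prime = (self.cell.c_ox - c_added) / (self.cell.c_red + c_added)
        de_oracle = self.cell.slope_decade * math.log10(alpha_prime / 100.0)
        de = expected_potential_shift(c_added, self.cell)
        assert de == pytest.approx(de_oracle, rel=1e-12)
        res = residual_concentration(0.3, 0.3 + de, self.cell)
        assert res.c_ao == pytest.approx(c_added, abs=1e-12)

    def test_dilution_scales_concentration(self):
        c10 = FerroFerriCell(dilution_n=10.0)
        r1 = residual_concentration(0.30, 0.28, self.cell)
        r10 = residual_concentration(0.30, 0.28, c10)
        assert r10.c_ao == pytest.approx(10.0 * r1.c_ao, rel=1e-12)

    def test_monotone_decreasing_in_e2(self):
        import warnings

        e2s = np.linspace(0.29, 0.31, 21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamps above e1 are expected here
            cs = [residual_concentration(0.30, e2, self.cell).c_ao for e2 in e2s]
        assert all(a >= b for a, b in zip(cs, cs[1:]))

    def test_apparent_negative_concentration_flagged(self):
        with pytest.warns(UserWarning, match="negative concentration"):
            res = residual_concentration(0.30, 0.31, self.cell)
        assert res.negative_flagged and res.c_ao == 0.0

    @given(c=st.floats(1e-8, 0.9e-3))
    def test_round_trip_identity(self, c):
        """expected_potential_shift then residual_concentration recovers c."""
        de = expected_potential_shift(c, self.cell)
        rec = residual_concentration(0.3, 0.3 + de, self.cell).c_ao
        assert rec == pytest.approx(c, rel=1e-10)

    def test_round_trip_with_dilution(self):
        cell = FerroFerriCell(dilution_n=5.0)
        rng = np.random.default_rng(42)
        for c in rng.uniform(1e-6, 4e-3, 100):
            de = expected_potential_shift(c, cell)
            assert residual_concentration(0.3, 0.3 + de, cell).c_ao == pytest.approx(
                c, rel=1e-10
            )

    def test_zero_spike_zero_shift(self):
        assert expected_potential_shift(0.0, self.cell) == 0.0

    def test_shift_monotone_and_capacity_error(self):
        cs = np.linspace(0.0, 0.9e-3, 10)
        des = [expected_potential_shift(c, self.cell) for c in cs]
        assert all(a > b for a, b in zip(des, des[1:]))
        with pytest.raises(MediatorCapacityError):
            expected_potential_shift(1.1e-3, self.cell)

    def test_noise_propagation_matches_monte_carlo(self):
        """Delta-method SD within 10% of brute-force noise simulation."""
        c, sigma_e = 1e-4, 5e-4
        de = expected_potential_shift(c, self.cell)
        rng = np.random.default_rng(3)
        sims = [
            residual_concentration(
                0.3 + rng.normal(0, sigma_e), 0.3 + de + rng.normal(0, sigma_e), self.cell
            ).c_ao
            for _ in range(4000)
        ]
        assert concentration_noise_sd(c, self.cell, sigma_e) == pytest.approx(
            np.std(sims), rel=0.10
        )

    def test_cell_validation(self):
        with pytest.raises(InputError):
            FerroFerriCell(c_ox=0.0)
        with pytest.raises(InputError):
            FerroFerriCell(dilution_n=0.5)
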