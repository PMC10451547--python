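import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from kinpot.exceptions import (
    DomainError,
    InputError,
    QSSAValidityError,
)
from kinpot.kinetics import (
    AntioxidantSpec,
    RateParameters,
    initiation_rate,
    simulate,
    steady_state_radical,
)


class TestInitiationRate:
    @pytest.mark.parametrize(
        "ki,c0,t,expected",
        [
            (1e-6, 0.1, 0.0, 2e-7),
            (1e-6, 0.05, 0.0, 1e-7),  # linear in initiator load
            (1e-6, 0.1, 3600.0, 2e-7 * np.exp(-3.6e-3)),
        ],
    )
    def test_first_order_generation(self, ki, c0, t, expected):
        p = RateParameters(ki=ki, initiator_c0=c0)
        assert initiation_rate(p, t) == pytest.approx(expected, rel=1e-12)

    def test_no_initiator_no_radicals(self):
        p = RateParameters(initiator_c0=0.0)
        assert initiation_rate(p, 0.0) == 0.0
        assert np.all(initiation_rate(p, np.linspace(0, 1e4, 5)) == 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            initiation_rate(RateParameters(), -1.0)

    def test_parameter_validation(self):
        with pytest.raises(InputError):
            RateParameters(ki=-1e-6)
        with pytest.raises(InputError):
            RateParameters(temperature=400.0)
        with pytest.raises(InputError):
            AntioxidantSpec("x", -1e-5, 1e3)
        with pytest.raises(InputError):
            AntioxidantSpec("x", 1e-5, 1e3, q=0.0)


class TestSteadyStateRadical:
    def test_recombination_only_closed_form(self):
        # sqrt(wi/two_k2): the classical no-inhibitor steady state
        assert steady_state_radical(2e-7, 5e4, 0.0) == pytest.approx(2e-6, rel=1e-12)

    def test_zero_generation(self):
        assert steady_state_radical(0.0, 5e4, 0.3) == 0.0

    def test_scavenging_dominated_limit(self):
        # 0.05 mM antioxidant with kinh = 3.95e3: load 0.1975 1/s
        x = steady_state_radical(2e-7, 5e4, 0.1975)
        assert x == pytest.approx(2e-7 / 0.1975, rel=0.25)
        # independent bisection oracle on the defining quadratic
        root = brentq(lambda y: 5e4 * y * y + 0.1975 * y - 2e-7, 0.0, 1e-3)
        assert x == pytest.approx(root, rel=1e-10)

    @given(
        wi=st.floats(1e-9, 1e-5),
        two_k2=st.floats(1e3, 1e6),
        load=st.floats(0.0, 10.0),
    )
    def test_is_nonnegative_root_of_balance(self, wi, two_k2, load):
        x = steady_state_radical(wi, two_k2, load)
        assert x >= 0.0
        assert two_k2 * x * x + load * x - wi == pytest.approx(0.0, abs=1e-12 * wi + 1e-300)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            steady_state_radical(-1e-7, 5e4, 0.0)
        with pytest.raises(DomainError):
            steady_state_radical(1e-7, 0.0, 0.0)


class TestSimulateFull:
    def test_uninhibited_radical_reaches_steady_state(self, params):
        t = np.arange(0.0, 301.0, 1.0)
        traj = simulate(params, [], t)
        x_inf = steady_state_radical(params.wi0, params.two_k2)
        assert traj.radical[-1] == pytest.approx(x_inf, rel=0.01)
        # monotone rise, allowing the ~1e-12 M/s decline from initiator depletion
        assert np.all(np.diff(traj.radical) >= -1e-11)

    def test_depletion_time_matches_quadrature_oracle(self, params):
        """Time to 90% consumption agrees with the independent QSSA integral."""
        kinh, q, c0 = 3.95e3, 2.0, 1e-4
        t = np.arange(0.0, 1500.0, 1.0)
        traj = simulate(params, [AntioxidantSpec("a", c0, kinh, q)], t)
        c = traj.inhibitors["a"]
        t90 = t[np.nonzero(c <= 0.1 * c0)[0][0]]

        def rate(cc):  # dc/dt magnitude under the steady radical balance
            x = steady_state_radical(params.wi0, params.two_k2, q * kinh * cc)
            return kinh * x * cc

        oracle, _ = quad(lambda cc: 1.0 / rate(cc), 0.1 * c0, c0, limit=200)
        assert t90 == pytest.approx(oracle, rel=0.02)
        # loose capacity bookkeeping: q c0 / Wi, biased long by recombination share
        assert q * c0 / params.wi0 <= t90 <= 1.2 * q * c0 / params.wi0

    @pytest.mark.parametrize("kinh", [4e2, 3.95e3, 1e4])
    @pytest.mark.parametrize("c0", [5e-5, 2e-4])
    def test_mass_balance(self, params, kinh, c0):
        t = np.linspace(0.0, 2.5 * 2 * c0 / params.wi0, 200)
        traj = simulate(params, [AntioxidantSpec("a", c0, kinh, 2.0)], t)
        assert traj.max_mass_balance_error() <= 1e-3
        assert np.all(np.diff(traj.inhibitors["a"]) <= 1e-18)
        assert np.all(np.diff(traj.initiator) < 0)
        assert np.all(traj.radical >= 0)

    def test_two_antioxidants_scavenged_equals_capacity(self, params):
        aos = [
            AntioxidantSpec("f", 1e-4, 3.95e3, 2.0),
            AntioxidantSpec("s", 1e-4, 7.5e2, 3.0),
        ]
        t = np.arange(0.0, 6001.0, 10.0)
        traj = simulate(params, aos, t)
        capacity = sum(a.q * a.c0 for a in aos)
        assert traj.cum_scavenged[-1] == pytest.approx(capacity, rel=0.02)

    def test_addition_time_splits_phases(self, params):
        t = np.arange(0.0, 901.0, 1.0)
        traj = simulate(
            params, [AntioxidantSpec("a", 1e-4, 3.95e3, 2.0)], t, t_add=300.0
        )
        c = traj.inhibitors["a"]
        assert np.all(c[t <= 300.0] == 1e-4)  # inert before addition
        assert c[-1] < 1e-4
        # radical drops across the addition
        assert traj.radical[299] > 5 * traj.radical[320]

    def test_side_reaction_lowers_radical(self, params):
        t = np.arange(0.0, 301.0, 1.0)
        base = simulate(params, [], t)
        side = simulate(
            params, [], t, ferrocyanide_side_reaction=True,
            side_reaction_k=1e4, ferrocyanide_c=1e-5,
        )
        assert side.radical[-1] < base.radical[-1]

    def test_grid_validation(self, params):
        with pytest.raises(InputError):
            simulate(params, [], np.array([1.0, 2.0]))  # must start at 0
        with pytest.raises(InputError):
            simulate(params, [], np.array([0.0, 2.0, 2.0]))
        with pytest.raises(InputError):
            simulate(
                params,
                [AntioxidantSpec("a", 1e-5, 1e3), AntioxidantSpec("a", 1e-5, 2e3)],
                np.array([0.0, 1.0]),
            )


class TestQSSA:
    @pytest.mark.parametrize("kinh,c0", [(3.95e3, 1e-4), (9.25e3, 5e-5), (4e2, 1e-4)])
    def test_agreement_with_full_ode(self, params, kinh, c0):
        """QSSA and full-ODE inhibitor curves agree to 1% of c0."""
        grid = np.arange(0.0, 2.2 * 2 * c0 / params.wi0, 60.0)
        ao = [AntioxidantSpec("a", c0, kinh, 2.0)]
        full = simulate(params, ao, grid, mode="full")
        qssa = simulate(params, ao, grid, mode="qssa")
        dev = np.abs(qssa.inhibitors["a"] - full.inhibitors["a"]) / c0
        assert dev.max() <= 0.01

    def test_validity_check_rejects_fine_grid(self, params):
        with pytest.raises(QSSAValidityError):
            simulate(
                params,
                [AntioxidantSpec("a", 1e-4, 3.95e3, 2.0)],
                np.arange(0.0, 100.0, 1.0),
                mode="qssa",
            )

    def test_qssa_radical_equals_algebraic_root(self, params):
        grid = np.arange(0.0, 1201.0, 60.0)
        ao = AntioxidantSpec("a", 1e-4, 3.95e3, 2.0)
        traj = simulate(params, [ao], grid, mode="qssa")
        c = traj.inhibitors["a"]
        for i in (1, 10, -1):
            wi = initiation_rate(params, traj.t[i])
            expect = steady_state_radical(wi, params.two_k2, 2.0 * 3.95e3 * c[i])
            assert traj.radical[i] == pytest.approx(expect, rel=1e-9)
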