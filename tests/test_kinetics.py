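"""Network construction, mass-action RHS evaluation and steady states."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mirloop as ml
from mirloop.kinetics import (
    RateParameters,
    SteadyStateError,
    ValidationError,
    evaluate_rhs,
)

from conftest import hand_rhs


ZERO = {f: 0.0 for f in RateParameters().as_dict()}


def params_with(**kw):
    d = dict(ZERO, d_P=1.0)
    d.update(kw)
    return RateParameters(**d)


class TestValidation:
    def test_negative_rate_rejected_with_field_name(self):
        with pytest.raises(ValidationError, match="k_rep"):
            RateParameters(k_rep=-1.0)

    def test_eta_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError, match="eta"):
            RateParameters(eta=1.5)

    def test_zero_receptor_decay_rejected(self):
        with pytest.raises(ValidationError, match="d_P"):
            RateParameters(d_P=0.0)

    def test_unknown_parameter_name_rejected(self):
        with pytest.raises(ValidationError, match="nonsense"):
            RateParameters.from_dict({"nonsense": 1.0})

    def test_default_network_satisfies_invariants(self, default_network):
        # construction itself runs the invariant checks; spot-check contents
        assert default_network.species == ml.SPECIES
        names = {r.name for r in default_network.reactions}
        assert "M_mirtron_production" in names
        pnames = set(default_network.parameters.as_dict())
        for rx in default_network.reactions:
            assert set(rx.rate_constants) <= pnames

    def test_state_length_mismatch_raises(self, default_network):
        with pytest.raises(ValidationError, match="shape"):
            evaluate_rhs(default_network, np.zeros(5))

    def test_negative_abundance_raises(self, default_network):
        y = np.zeros(8)
        y[0] = -1.0
        with pytest.raises(ValidationError, match="negative"):
            evaluate_rhs(default_network, y)


class TestRhs:
    def test_pure_decay_network(self):
        net = ml.build_default_network(params_with(d_R=0.7))
        y = np.array([2.0, 0, 0, 0, 0, 0, 0, 0])
        dy = evaluate_rhs(net, y, stimulus=1.0)
        assert dy[0] == pytest.approx(-0.7 * 2.0, abs=1e-15)
        assert np.all(dy[1:] == 0)

    def test_single_production_from_zero_state(self):
        net = ml.build_default_network(params_with(k_R=1.0))
        dy = evaluate_rhs(net, np.zeros(8), stimulus=1.0)
        expected = np.zeros(8)
        expected[0] = 1.0
        np.testing.assert_array_equal(dy, expected)

    def test_severed_mirtron_production_decays_m(self):
        p = RateParameters(eta=0.0)
        net = ml.build_default_network(p)
        y = np.array([0, 0, 0, 0.8, 0, 0, 0, 3.0])
        dy = evaluate_rhs(net, y, stimulus=0.0)
        assert dy[ml.SPECIES.index("M")] == pytest.approx(-p.d_M * 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_rhs_matches_hand_assembled_equations(self, seed):
        """Mass-action assembly must agree term-by-term with the literal
        eight-equation oracle at random states and parameters."""
        rng = np.random.default_rng(seed)
        draws = {f: float(rng.uniform(0.1, 3.0)) for f in ZERO}
        draws["eta"] = float(rng.uniform(0, 1))
        p = RateParameters(**draws)
        net = ml.build_default_network(p)
        y = rng.uniform(0.0, 2.0, size=8)
        y[3] = rng.uniform(0, 1)  # phospho-fraction
        u = float(rng.uniform(0, 2))
        got = evaluate_rhs(net, y, stimulus=u)
        np.testing.assert_allclose(got, hand_rhs(p, y, u), rtol=0, atol=1e-12)

    def test_extra_depolarization_enters_v_only(self, default_network):
        g = ml.GenotypePerturbation("nachbac", extra_depolarization=0.5)
        net = ml.apply_perturbation(default_network, g)
        base = evaluate_rhs(default_network, np.zeros(8), stimulus=0.0)
        boosted = evaluate_rhs(net, np.zeros(8), stimulus=0.0)
        diff = boosted - base
        assert diff[ml.SPECIES.index("V")] == pytest.approx(0.5)
        assert np.all(np.delete(diff, ml.SPECIES.index("V")) == 0)


class TestSteadyState:
    def test_linear_closed_form(self):
        # decoupled dR/dt = k - d*R with k=2, d=0.5 -> R* = 4
        net = ml.build_default_network(params_with(k_R=2.0, d_R=0.5))
        ss = ml.steady_state(net, stimulus_amplitude=0.0)
        assert ss.converged
        assert ss.state[0] == pytest.approx(4.0, rel=1e-9)

    def test_mirtron_null_has_zero_mirna(self):
        net = ml.build_default_network(RateParameters(eta=0.0))
        ss = ml.steady_state(net, stimulus_amplitude=1.0)
        assert ss.state[ml.SPECIES.index("M")] == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_long_integration_oracle(self, default_network):
        """The located fixed point must agree with an independent dense
        5000-lifetime integration at strict tolerances."""
        ss = ml.steady_state(default_network, stimulus_amplitude=1.0)
        f = default_network.rate_function(lambda t: 1.0)
        y0 = ml.resting_state(default_network)
        sol = solve_ivp(f, (0, 5000.0), y0, method="LSODA",
                        rtol=1e-12, atol=1e-14)
        assert sol.success
        np.testing.assert_allclose(ss.state, sol.y[:, -1], rtol=1e-6)

    def test_residual_below_tolerance(self, default_network):
        ss = ml.steady_state(default_network, stimulus_amplitude=1.0)
        assert ss.residual < 1e-9

    def test_runaway_drive_raises(self):
        # all tempering removed, strong positive feedback: no fixed point
        p = RateParameters(k_leak=0.1, g_K=0.0, eta=0.0, k_rep=0.0, a_R=2.0)
        net = ml.build_default_network(p)
        with pytest.raises(SteadyStateError):
            ml.steady_state(net, stimulus_amplitude=1.0)

    def test_coupling_invariant_m_equals_eta_as_a_over_dm(self, default_network):
        """Substitution identity M* = eta*a_S*A*/d_M at any converged
        steady state (the mirtron is spliced from the host transcript)."""
        p = default_network.parameters
        for u in (0.0, 0.5, 1.0, 2.0):
            ss = ml.steady_state(default_network, stimulus_amplitude=u)
            A = ss.state[ml.SPECIES.index("A")]
            M = ss.state[ml.SPECIES.index("M")]
            assert M == pytest.approx(p.eta * p.a_S * A / p.d_M, rel=1e-8, abs=1e-12)

    def test_monotone_repression(self, default_network):
        """Steady-state receptor mRNA never increases with repression rate."""
        k_grid = np.linspace(0.5, 20.0, 10)
        r_vals = []
        for k in k_grid:
            net = ml.build_default_network(
                default_network.parameters.replace(k_rep=float(k)))
            r_vals.append(ml.steady_state(net, 1.0).state[0])
        assert np.all(np.diff(r_vals) <= 1e-12)


class TestClosedFormRelaxation:
    def test_zeroth_order_production_first_order_decay(self):
        """A species with only production k and decay d relaxes to k/d
        with time constant 1/d; compare the full trajectory analytically."""
        k, d = 2.0, 0.5
        net = ml.build_default_network(params_with(k_R=k, d_R=d))
        f = net.rate_function(lambda t: 0.0)
        y0 = np.zeros(8)
        t_eval = np.linspace(0, 20, 200)
        sol = solve_ivp(f, (0, 20), y0, method="LSODA", t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        analytic = (k / d) * (1 - np.exp(-d * t_eval))
        np.testing.assert_allclose(sol.y[0], analytic, rtol=1e-6, atol=1e-9)


class TestNonNegativity:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_trajectories_stay_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        draws = {f: float(rng.uniform(0.1, 3.0)) for f in ZERO}
        draws["eta"] = float(rng.uniform(0, 1))
        net = ml.build_default_network(RateParameters(**draws))
        tc = ml.simulate_timecourse(net, horizon=20.0)
        assert tc.states.min() >= -1e-8
        assert tc.species("A").max() <= 1 + 1e-8
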