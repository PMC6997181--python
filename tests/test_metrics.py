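"""Return-time metrics, switch classification and fold-change tables."""

import numpy as np
import pytest

import mirloop as ml
from mirloop.metrics import (
    ConfigurationError,
    SUSTAINED,
    classify_switch,
    compute_delta_t,
)
from mirloop.simulate import NormalizedResponse


def toy_response(times, v, name="toy"):
    return NormalizedResponse(genotype=name, times=np.asarray(times, float),
                              v_norm=np.asarray(v, float), reference_peak=1.0)


def brute_force_t_return(times, v, threshold):
    """Exhaustive scan: first time at/after the argmax from which every
    later sample is below threshold."""
    ipk = int(np.argmax(v))
    for i in range(ipk, len(times)):
        if all(x < threshold for x in v[i:]):
            return times[i]
    return None


class TestDeltaT:
    def test_identical_to_wildtype_gives_zero_delay(self, default_responses):
        wt = default_responses["wild-type"]
        m = compute_delta_t(wt, wt)
        assert m.delta_t == 0.0
        assert m.classification == "homeostatic"

    def test_never_stimulated_curve_returns_at_its_peak(self, default_responses):
        wt = default_responses["wild-type"]
        flat = toy_response(wt.times, np.zeros_like(wt.times), "flat")
        m = compute_delta_t(flat, wt)
        assert m.t_return == m.time_of_peak
        assert m.classification == "homeostatic"

    def test_piecewise_linear_crossing_matches_brute_force(self, default_responses):
        """A toy curve crossing 0.2 at t = 3.7 then staying below: t_return
        is the first grid time satisfying the stays-below scan."""
        wt = default_responses["wild-type"]
        t = wt.times
        # peak 1.0 at t=1, linear decay crossing 0.2 at t=3.7, flat after
        v = np.interp(t, [0, 1.0, 3.7, 50.0], [0, 1.0, 0.2, 0.0])
        resp = toy_response(t, v)
        m = compute_delta_t(resp, wt)
        assert m.t_return == brute_force_t_return(t, v, 0.2)
        assert m.t_return >= 3.7

    def test_sustained_when_never_below(self, default_responses):
        wt = default_responses["wild-type"]
        high = toy_response(wt.times, np.full_like(wt.times, 0.5), "high")
        m = compute_delta_t(high, wt)
        assert m.t_return is None and m.delta_t is None
        assert m.classification == SUSTAINED

    def test_wildtype_never_returning_is_configuration_error(self, default_responses):
        wt = default_responses["wild-type"]
        high = toy_response(wt.times, np.full_like(wt.times, 0.5), "fake-wt")
        with pytest.raises(ConfigurationError):
            compute_delta_t(wt, high)

    def test_threshold_monotonicity(self, default_responses):
        """Raising the threshold can only shorten (or keep) the return."""
        wt = default_responses["wild-type"]
        resp = default_responses["SKIP-MiMIC"]
        t_prev = np.inf
        for thr in (0.18, 0.2, 0.4, 0.6):
            m = compute_delta_t(resp, wt, threshold=thr)
            assert m.t_return is not None and m.t_return <= t_prev
            t_prev = m.t_return

    def test_fig_style_ordering_under_defaults(self, default_metrics):
        """Qualitative content of the simulated genotype panel: complete
        miRNA loss stays high; SKIP loss and half miRNA dosage are delayed."""
        dm = default_metrics
        assert dm.loc["miR-1010-null", "terminal_level"] > \
            dm.loc["SKIP-MiMIC", "terminal_level"]
        assert dm.loc["SKIP-MiMIC", "delta_t"] > 0
        assert dm.loc["miR-1010-het", "delta_t"] > 0


class TestSwitch:
    def test_grid_too_small_rejected(self):
        with pytest.raises(Exception):
            classify_switch({0.1 * i: None for i in range(5)})

    def test_scan_endpoints_and_brute_force_eta_star(self, default_network):
        """Zero yield is sustained, full yield homeostatic, and the
        reported eta* equals the exhaustive smallest returning grid point."""
        grid = np.linspace(0, 1, 21)
        summary = ml.switch_scan(default_network, eta_grid=grid, horizon=50.0)
        assert summary.classifications[0] == SUSTAINED
        assert summary.classifications[-1] != SUSTAINED
        returning = [e for e, c in zip(summary.eta_grid, summary.classifications)
                     if c != SUSTAINED]
        assert summary.eta_star == min(returning)
        assert summary.monotone


class TestFoldChanges:
    @pytest.fixture(scope="class")
    def table(self, default_network):
        fc = ml.steady_state_fold_changes(default_network)
        return fc.set_index(["condition", "observable"])["fold_change"]

    def test_wildtype_rows_exactly_one(self, table):
        assert (table.loc["wild-type"] == 1.0).all()

    def test_mirna_null_overexpresses_targets(self, table):
        assert table.loc[("miR-1010-null", "nAcRb2_mRNA")] > 1
        assert table.loc[("miR-1010-null", "SKIP_transcript")] > 1
        assert table.loc[("miR-1010-null", "Shal")] > 1
        assert table.loc[("miR-1010-null", "miR-1010")] == 0

    def test_binding_site_mutant_raises_mirna(self, table):
        assert table.loc[("nAcRb2-delta1010", "miR-1010")] > 1

    def test_activity_perturbation_directions(self, table):
        # boosted firing represses the receptor; silencing raises it modestly
        assert table.loc[("NaChBac", "nAcRb2_mRNA")] < 1
        assert table.loc[("Kir2.1", "nAcRb2_mRNA")] > 1
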