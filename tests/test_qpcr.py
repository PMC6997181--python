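"""Relative quantification arithmetic and the variance-decision test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mirloop as ml
from mirloop.qpcr import (
    DegenerateInputError,
    InsufficientReplicationError,
    delta_delta_ct,
    expression_filter,
    significance_stars,
    validate_ct_table,
    variance_decision_test,
)


def group_frame(target_cts, ref_cts, group="control", gene="tgt"):
    n = len(target_cts)
    return pd.DataFrame({
        "sample_id": [f"{group}-{i}" for i in range(n)],
        "group": group,
        "target_gene": gene,
        "target_ct": target_cts,
        "reference_gene": "Rpl32",
        "reference_ct": ref_cts,
        "replicate_index": range(1, n + 1),
    })


class TestExpressionFilter:
    @pytest.mark.parametrize("mean_ct,expressed", [
        (30.0, True), (33.0, False), (32.999, True), (34.0, False)])
    def test_strict_threshold(self, mean_ct, expressed):
        assert expression_filter([mean_ct] * 3) is expressed

    def test_empty_vector_rejected(self):
        with pytest.raises(Exception):
            expression_filter([])


class TestDeltaDeltaCt:
    def test_unit_delta_gives_twofold(self):
        ctrl = group_frame([20.0, 20.0], [15.0, 15.0])
        cond = group_frame([19.0, 19.0], [15.0, 15.0], group="condition")
        res = delta_delta_ct(ctrl, cond)
        assert res.fold_change == pytest.approx(2.0, abs=1e-12)

    def test_triplicate_hand_arithmetic_oracle(self):
        """Frozen hand computation: control dCt {5.1, 5.0, 4.9} (mean 5.0),
        condition dCt {3.4, 3.5, 3.6} (mean 3.5); ddCt = -1.5;
        fold change = 2^1.5 = 2.8284271247461903."""
        ctrl = group_frame([20.1, 20.0, 19.9], [15.0] * 3)
        cond = group_frame([18.4, 18.5, 18.6], [15.0] * 3, group="condition")
        res = delta_delta_ct(ctrl, cond)
        assert res.fold_change == pytest.approx(2.8284271247461903, abs=1e-12)
        assert res.log2_fold_change == pytest.approx(1.5, abs=1e-12)
        assert res.dct_control_mean == pytest.approx(5.0)
        assert res.dct_condition_mean == pytest.approx(3.5)

    def test_identical_groups_fold_one_p_near_one(self):
        vals = [20.1, 19.9, 20.0]
        ctrl = group_frame(vals, [15.0] * 3)
        cond = group_frame(vals, [15.0] * 3, group="condition")
        res = delta_delta_ct(ctrl, cond)
        assert res.fold_change == pytest.approx(1.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_single_replicate_rejected(self):
        ctrl = group_frame([20.0], [15.0])
        cond = group_frame([19.0, 19.1], [15.0, 15.0], group="condition")
        with pytest.raises(InsufficientReplicationError):
            delta_delta_ct(ctrl, cond)

    def test_fold_change_consistency_invariant(self):
        rng = np.random.default_rng(5)
        ctrl = group_frame(rng.normal(24, 0.2, 9), rng.normal(15, 0.2, 9))
        cond = group_frame(rng.normal(23, 0.2, 9), rng.normal(15, 0.2, 9),
                           group="condition")
        res = delta_delta_ct(ctrl, cond)
        assert res.fold_change == pytest.approx(
            2 ** res.log2_fold_change, abs=1e-12)

    @given(shift=st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, shift):
        """Adding a constant to every Ct (target and reference, both
        groups) leaves the fold change unchanged."""
        ctrl = group_frame([20.1, 20.0, 19.9], [15.0, 15.1, 14.9])
        cond = group_frame([18.4, 18.5, 18.6], [15.0, 14.8, 15.2],
                           group="condition")
        base = delta_delta_ct(ctrl, cond).fold_change
        ctrl2 = ctrl.assign(target_ct=ctrl.target_ct + shift,
                            reference_ct=ctrl.reference_ct + shift)
        cond2 = cond.assign(target_ct=cond.target_ct + shift,
                            reference_ct=cond.reference_ct + shift)
        shifted = delta_delta_ct(ctrl2, cond2).fold_change
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_swap_symmetry(self):
        """Swapping control/condition inverts the fold change exactly."""
        ctrl = group_frame([20.1, 20.0, 19.9], [15.0] * 3)
        cond = group_frame([18.4, 18.5, 18.6], [15.0] * 3, group="condition")
        fwd = delta_delta_ct(ctrl, cond).fold_change
        rev = delta_delta_ct(cond, ctrl).fold_change
        assert fwd * rev == pytest.approx(1.0, abs=1e-12)


class TestVarianceDecision:
    def test_equal_variance_draws_use_student(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        assert variance_decision_test(a, b).test_used == "student"

    def test_hundredfold_variance_uses_welch(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 9)
        b = rng.normal(0.5, 1.0, 9)
        assert variance_decision_test(a, b).test_used == "welch"

    def test_textbook_formula_oracle(self):
        """Both branches recomputed from the textbook t statistic and df
        (pooled for Student, Satterthwaite for Welch)."""
        a = np.array([4.8, 5.1, 5.0, 4.9, 5.2])
        b = np.array([3.1, 3.9, 3.3, 3.7, 3.5, 3.6])
        dec = variance_decision_test(a, b)
        na, nb = len(a), len(b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        # pooled Student
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_s = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_s = 2 * stats.t.sf(abs(t_s), na + nb - 2)
        # Welch with Satterthwaite df
        t_w = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
        df_w = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p_w = 2 * stats.t.sf(abs(t_w), df_w)
        assert dec.p_student == pytest.approx(p_s, abs=1e-12)
        assert dec.p_welch == pytest.approx(p_w, abs=1e-12)
        if dec.test_used == "student":
            assert dec.t_statistic == pytest.approx(t_s, abs=1e-12)
            assert dec.df == na + nb - 2
        else:
            assert dec.t_statistic == pytest.approx(t_w, abs=1e-12)
            assert dec.df == pytest.approx(df_w, abs=1e-12)

    def test_branches_agree_asymptotically_for_equal_variances(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 1, 30)
        dec = variance_decision_test(a, b)
        assert abs(dec.p_student - dec.p_welch) < 0.02

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(DegenerateInputError):
            variance_decision_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            variance_decision_test([1.0], [2.0, 3.0])


class TestTableValidation:
    def test_out_of_range_ct_rejected(self):
        df = group_frame([20.0, 45.0], [15.0, 15.0])
        with pytest.raises(Exception, match="Ct"):
            validate_ct_table(df)

    def test_inconsistent_reference_gene_rejected(self):
        df = group_frame([20.0, 20.1], [15.0, 15.0])
        df.loc[1, "reference_gene"] = "U27"
        with pytest.raises(Exception, match="reference"):
            validate_ct_table(df)

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == "ns"
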