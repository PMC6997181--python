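"""Relative quantification (2^-ddCt) and the variance-decision test.

Quantification follows the standard endogenous-control route: per
replicate, dCt = target Ct - reference Ct (Rpl32 for mRNA, U27 for
miRNA); ddCt = mean dCt(condition) - mean dCt(control); fold change =
2^(-ddCt).  Significance follows the published procedure: a Bartlett test
of variance homogeneity first, then a pooled-variance Student t test if
variances are homogeneous, otherwise Welch's t test; both two-sided, on
the dCt scale.  A target is considered expressed at meaningful levels iff
its mean control Ct is strictly below 33 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import ValidationError

__all__ = [
    "CT_COLUMNS",
    "QuantificationResult",
    "VarianceDecision",
    "expression_filter",
    "variance_decision_test",
    "delta_delta_ct",
    "quantify_table",
    "significance_stars",
    "validate_ct_table",
    "InsufficientReplicationError",
    "DegenerateInputError",
]

CT_COLUMNS = ("sample_id", "group", "target_gene", "target_ct",
              "reference_gene", "reference_ct", "replicate_index")

CONTROL, CONDITION = "control", "condition"


class InsufficientReplicationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns {sorted(missing)}")
    bad = df[(df.target_ct <= 0) | (df.target_ct > 40) |
             (df.reference_ct <= 0) | (df.reference_ct > 40)]
    if len(bad):
        raise ValidationError(
            f"Ct values must lie in (0, 40]; {len(bad)} offending row(s)")
    groups = set(df.group.unique())
    if not groups <= {CONTROL, CONDITION}:
        raise ValidationError(
            f"group must be '{CONTROL}' or '{CONDITION}', got {sorted(groups)}")
    for tgt, sub in df.groupby("target_gene"):
        if sub.reference_gene.nunique() != 1:
            raise ValidationError(
                f"reference gene must be consistent within an experiment "
                f"(target {tgt!r} uses {sorted(sub.reference_gene.unique())})")
    return df


def expression_filter(ct_values, threshold: float = 33.0) -> bool:
    """Expressed at meaningful levels iff mean Ct < threshold (strict)."""
    ct = np.asarray(ct_values, dtype=float)
    if ct.size == 0:
        raise ValidationError("empty Ct vector")
    return bool(ct.mean() < threshold)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class VarianceDecision:
    test_used: str        # "student" | "welch"
    p_value: float        # p of the chosen t test (two-sided)
    bartlett_p: float
    t_statistic: float
    df: float
    p_student: float
    p_welch: float


def variance_decision_test(group_a, group_b, alpha: float = 0.05) -> VarianceDecision:
    """Bartlett-gated two-sample t test.

    Bartlett p >= alpha -> Student's pooled-variance t; otherwise Welch's
    t with Satterthwaite df.  Both branch p-values are reported so the
    decision is auditable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise DegenerateInputError(
                "zero variance in both groups with equal means: t test undefined")
        bartlett_p = 1.0
    else:
        bartlett_p = float(stats.bartlett(a, b).pvalue)
    t_s, p_s = stats.ttest_ind(a, b, equal_var=True)
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
    if bartlett_p >= alpha:
        used, t, p = "student", float(t_s), float(p_s)
        df = len(a) + len(b) - 2
    else:
        used, t, p = "welch", float(t_w), float(p_w)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return VarianceDecision(test_used=used, p_value=p, bartlett_p=bartlett_p,
                            t_statistic=t, df=float(df),
                            p_student=float(p_s), p_welch=float(p_w))


@dataclass(frozen=True)
class QuantificationResult:
    target_gene: str
    fold_change: float
    log2_fold_change: float
    dct_control_mean: float
    dct_control_sd: float
    dct_condition_mean: float
    dct_condition_sd: float
    n_control: int
    n_condition: int
    expressed: bool
    test_used: str
    p_value: float
    stars: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def delta_delta_ct(
    control: pd.DataFrame,
    condition: pd.DataFrame,
    alpha: float = 0.05,
    ct_threshold: float = 33.0,
) -> QuantificationResult:
    """Relative quantification of one target from two replicate groups.

    Each input frame holds one group's wells (columns ``target_ct`` and
    ``reference_ct``; one row per replicate).  The expression filter is
    applied to the control-group target Ct.
    """
    for name, grp in (("control", control), ("condition", condition)):
        if len(grp) < 2:
            raise InsufficientReplicationError(
                f"{name} group has {len(grp)} replicate(s); need >= 2")
    dct_c = (control["target_ct"] - control["reference_ct"]).to_numpy(float)
    dct_x = (condition["target_ct"] - condition["reference_ct"]).to_numpy(float)
    ddct = dct_x.mean() - dct_c.mean()
    fc = float(2.0 ** (-ddct))
    try:
        dec = variance_decision_test(dct_c, dct_x, alpha=alpha)
        test_used, p = dec.test_used, dec.p_value
    except DegenerateInputError:
        # identical constant groups: no evidence of change
        test_used, p = "student", 1.0
    target = control["target_gene"].iloc[0] if "target_gene" in control else ""
    return QuantificationResult(
        target_gene=str(target),
        fold_change=fc,
        log2_fold_change=float(-ddct),
        dct_control_mean=float(dct_c.mean()),
        dct_control_sd=float(dct_c.std(ddof=1)),
        dct_condition_mean=float(dct_x.mean()),
        dct_condition_sd=float(dct_x.std(ddof=1)),
        n_control=len(dct_c),
        n_condition=len(dct_x),
        expressed=expression_filter(control["target_ct"], ct_threshold),
        test_used=test_used,
        p_value=float(p),
        stars=significance_stars(float(p)),
    )


def quantify_table(df: pd.DataFrame, alpha: float = 0.05,
                   ct_threshold: float = 33.0) -> pd.DataFrame:
    """Run relative quantification per target gene on a well-level table."""
    validate_ct_table(df)
    rows = []
    for tgt, sub in df.groupby("target_gene", sort=False):
        res = delta_delta_ct(sub[sub.group == CONTROL], sub[sub.group == CONDITION],
                             alpha=alpha, ct_threshold=ct_threshold)
        d = res.as_dict()
        d["target_gene"] = tgt
        rows.append(d)
    return pd.DataFrame(rows)
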