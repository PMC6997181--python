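"""Seeded synthetic RT-qPCR data with published fold changes as truth.

The generator emulates well-level Ct measurements with the structure the
quantification stage assumes: a control and a condition group, a target
gene and an endogenous control gene (Rpl32 for mRNA targets, U27 for the
miRNA), independent Gaussian cycle noise of equal SD on every well, and
the condition group's target Ct shifted down by log2(true fold change).
Presets carry the published fold-change values so every downstream stage
is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .kinetics import ValidationError
from .observations import FoldChangeObservation
from .qpcr import CONDITION, CONTROL

__all__ = [
    "QpcrPreset",
    "builtin_presets",
    "get_preset",
    "generate_ct_data",
    "generate_foldchange_table",
]

_MIRNA_OBSERVABLES = {"miR-1010"}


@dataclass(frozen=True)
class QpcrPreset:
    """Ground truth and noise structure for one synthetic experiment.

    Defaults: baseline target Ct 24 cycles, reference Ct 15 cycles,
    technical noise 0.2 cycles SD, 9 replicates per group.
    """

    name: str
    observable: str
    condition: str
    true_fold_change: float
    baseline_target_ct: float = 24.0
    reference_ct: float = 15.0
    ct_sd: float = 0.2
    replicates_per_group: int = 9
    source: str = ""

    def __post_init__(self) -> None:
        if not self.true_fold_change > 0:
            raise ValidationError("true_fold_change must be > 0")
        if self.ct_sd < 0:
            raise ValidationError("ct_sd must be >= 0")
        if self.replicates_per_group < 2:
            raise ValidationError("replicates_per_group must be >= 2")

    @property
    def reference_gene(self) -> str:
        return "U27" if self.observable in _MIRNA_OBSERVABLES else "Rpl32"

    def replace(self, **changes) -> "QpcrPreset":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "QpcrPreset":
        return cls(**d)


def builtin_presets() -> list[QpcrPreset]:
    """One preset per published fold-change observation."""
    P = QpcrPreset
    return [
        P("nicotine-nAcRb2", "nAcRb2_mRNA", "nicotine-low", 2.0,
          source="nAcRb2 increased to 2-fold of control under 0.1 mg/ml nicotine"),
        P("nicotine-miR1010", "miR-1010", "nicotine-low", 10.0,
          source="~10-fold increase in miR-1010 under 0.1 mg/ml nicotine"),
        P("nicotine-high-miR1010", "miR-1010", "nicotine-high", 10.0,
          source="~10-fold increase in miR-1010 under 0.5 mg/ml nicotine"),
        P("miR1010-null-SKIP", "SKIP_transcript", "miR-1010-null", 3.0,
          source="SKIP mRNA ~3-fold increase vs control in miR-1010 nulls"),
        P("miR1010-null-Shal", "Shal", "miR-1010-null", 3.0,
          source="Shal mRNA ~3-fold increase vs control in miR-1010 nulls"),
        P("miR1010-null-4EBP", "4E-BP", "miR-1010-null", 10.0,
          source="4E-BP shows a 10-fold increase at the onset of larval life"),
        P("Kir21-nAcRb2", "nAcRb2_mRNA", "Kir2.1", 1.24,
          source="modest 1.24-fold increase of nAcRb2 under Kir2.1"),
        P("delta1010-miR1010", "miR-1010", "nAcRb2-delta1010", 5.0,
          source="miR-1010 peaking at 5-fold of wild-type in the binding-site mutant"),
        P("rescue-SKIP", "SKIP_transcript", "rescue-line", 10.0,
          source="SKIP mRNA ~10-fold higher in the pan-neural rescue line"),
    ]


def get_preset(name: str) -> QpcrPreset:
    presets = {p.name: p for p in builtin_presets()}
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None


def generate_ct_data(preset: QpcrPreset, seed: int) -> pd.DataFrame:
    """Draw one well-level Ct dataset for ``preset``.

    Control target Ct ~ N(baseline, sd); condition target Ct ~
    N(baseline - log2(true fold change), sd); reference Ct ~ N(ref, sd)
    in both groups.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = preset.replicates_per_group
    shift = float(np.log2(preset.true_fold_change))
    rows = []
    for group, target_mu in ((CONTROL, preset.baseline_target_ct),
                             (CONDITION, preset.baseline_target_ct - shift)):
        t_ct = rng.normal(target_mu, preset.ct_sd, size=n)
        r_ct = rng.normal(preset.reference_ct, preset.ct_sd, size=n)
        for i in range(n):
            rows.append({
                "sample_id": f"{preset.name}-{group}-{i + 1}",
                "group": group,
                "target_gene": preset.observable,
                "target_ct": float(t_ct[i]),
                "reference_gene": preset.reference_gene,
                "reference_ct": float(r_ct[i]),
                "replicate_index": i + 1,
            })
    return pd.DataFrame(rows)


def generate_foldchange_table(
    presets: list[QpcrPreset],
    relative_sd: float = 0.0,
    seed: int = 0,
) -> list[FoldChangeObservation]:
    """Noisy fold-change observations: value = truth * exp(N(0, relative_sd))."""
    if relative_sd < 0:
        raise ValidationError("relative_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for p in presets:
        value = p.true_fold_change * float(np.exp(rng.normal(0.0, relative_sd))) \
            if relative_sd > 0 else p.true_fold_change
        out.append(FoldChangeObservation(
            observable=p.observable, condition=p.condition,
            value=value, weight=1.0, source=p.source,
        ))
    return out
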