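"""Printed RT-qPCR fold-change observations used for calibration.

Each row is one published fold change relative to the control condition,
with a citation tag, used both as a calibration target and as ground truth
for the synthetic-data generators.  Conditions with model counterparts
must resolve in the genotype registry; a small set of qPCR-only tags
(``rescue-line``; observable ``4E-BP``) have no dynamical counterpart and
are excluded from calibration by construction (weight 0) or by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .genotypes import genotype_registry
from .kinetics import ValidationError

__all__ = [
    "FoldChangeObservation",
    "QPCR_ONLY_CONDITIONS",
    "builtin_observation_table",
    "observations_to_frame",
    "observations_from_frame",
    "read_observations_csv",
    "write_observations_csv",
]

#: conditions that exist only as qPCR experiments, never as model variants
QPCR_ONLY_CONDITIONS = frozenset({"rescue-line"})


@dataclass(frozen=True)
class FoldChangeObservation:
    observable: str
    condition: str
    value: float          # fold change relative to control, > 0
    weight: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(
                f"fold change must be > 0, got {self.value!r} for "
                f"({self.observable}, {self.condition})"
            )
        if self.weight < 0:
            raise ValidationError("observation weight must be >= 0")


def builtin_observation_table() -> list[FoldChangeObservation]:
    """The published fold changes, each with its citation tag.

    The rescue-line SKIP row ships with weight 0: the measurement is
    reported as surprising and unexplained, so it is carried for
    completeness but excluded from the default fit.
    """
    O = FoldChangeObservation
    return [
        O("SKIP_transcript", "miR-1010-null", 3.0, 1.0,
          "SKIP and Shal mRNA show a ~3-fold increase vs control in miR-1010 nulls"),
        O("Shal", "miR-1010-null", 3.0, 1.0,
          "SKIP and Shal mRNA show a ~3-fold increase vs control in miR-1010 nulls"),
        O("nAcRb2_mRNA", "nicotine-low", 2.0, 1.0,
          "nAcRb2 increased to 2-fold of control under 0.1 mg/ml nicotine"),
        O("miR-1010", "nicotine-low", 10.0, 1.0,
          "~10-fold increase in miR-1010 under nicotine exposure"),
        O("nAcRb2_mRNA", "Kir2.1", 1.24, 1.0,
          "modest 1.24-fold increase of nAcRb2 under Kir2.1 overexpression"),
        O("miR-1010", "nAcRb2-delta1010", 5.0, 1.0,
          "miR-1010 peaks at 5-fold of wild-type in the binding-site mutant"),
        O("SKIP_transcript", "rescue-line", 10.0, 0.0,
          "SKIP mRNA ~10-fold higher in the pan-neural rescue line "
          "(reported as surprising; excluded from fitting)"),
    ]


def validate_observations(obs: list[FoldChangeObservation]) -> None:
    reg = genotype_registry()
    for o in obs:
        if o.weight > 0 and o.condition not in reg and o.condition not in QPCR_ONLY_CONDITIONS:
            raise ValidationError(
                f"observation condition {o.condition!r} is not a registered "
                f"genotype (registered: {sorted(reg)})"
            )


_COLUMNS = [f.name for f in fields(FoldChangeObservation)]


def observations_to_frame(obs: list[FoldChangeObservation]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(o, c) for c in _COLUMNS} for o in obs],
                        columns=_COLUMNS)


def observations_from_frame(df: pd.DataFrame) -> list[FoldChangeObservation]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"observations table missing columns {sorted(missing)}")
    return [
        FoldChangeObservation(
            observable=str(r.observable), condition=str(r.condition),
            value=float(r.value), weight=float(r.weight),
            source="" if pd.isna(r.source) else str(r.source),
        )
        for r in df.itertuples()
    ]


def write_observations_csv(obs: list[FoldChangeObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_observations_csv(path) -> list[FoldChangeObservation]:
    return observations_from_frame(pd.read_csv(path, keep_default_na=False,
                                               na_values=[]))
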