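"""Genotype concordance between a sequencing pipeline and an orthogonal assay.

Calls from both methods are crossed into a 4x4 confusion table over
{AA, AB, BB, NN} (NN = failed genotype).  The summary reports:

* success rate — fraction of loci where both methods agree exactly
  (diagonal AA/AB/BB over all compared loci);
* true negatives — reference homozygous (AA) by both methods;
* true positives — variant (AB or BB) by both methods;
* specificity = TN / (TN + FP), sensitivity = TP / (TP + FN).

Two readings of "true positive" are supported: the default detection-level
definition counts a locus as TP whenever both methods call it variant,
regardless of AB/BB agreement; the strict genotype-level definition requires
the identical variant genotype and books AB/BB disagreements as false
negatives.  Cells involving NN are excluded from the TP/TN/FP/FN partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB", "NN")
_INDEX = {g: i for i, g in enumerate(GENOTYPES)}


@dataclass(frozen=True)
class ConfusionTable:
    """4x4 counts: rows = pipeline call, columns = assay call."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (4, 4) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 4x4 matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, pipeline: str, assay: str) -> int:
        return int(self.counts[_INDEX[pipeline], _INDEX[assay]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(GENOTYPES), columns=list(GENOTYPES))


@dataclass(frozen=True)
class ConcordanceSummary:
    n_total: int
    n_concordant: int
    success_rate: float
    true_negative: int
    true_positive: int
    false_positive: int
    false_negative: int
    specificity: float | None  # None when the denominator is zero
    sensitivity: float | None


def build_confusion(pipeline_calls, assay_calls) -> ConfusionTable:
    """Cross-tabulate two equal-length genotype call vectors."""
    pipeline_calls = list(pipeline_calls)
    assay_calls = list(assay_calls)
    if len(pipeline_calls) != len(assay_calls):
        raise ValueError("call vectors differ in length")
    counts = np.zeros((4, 4), dtype=int)
    for locus, (a, b) in enumerate(zip(pipeline_calls, assay_calls)):
        try:
            i, j = _INDEX[str(a).upper()], _INDEX[str(b).upper()]
        except KeyError:
            raise ValueError(
                f"unknown genotype symbol at locus {locus}: ({a!r}, {b!r})"
            ) from None
        counts[i, j] += 1
    return ConfusionTable(counts)


def summarize(
    table: ConfusionTable, positive_definition: str = "detection"
) -> ConcordanceSummary:
    """Concordance statistics from a confusion table.

    ``positive_definition``: ``"detection"`` (both methods variant, default)
    or ``"strict"`` (identical variant genotype required for TP).
    """
    c = table.counts
    if table.total == 0:
        raise ValueError("empty confusion table")
    var = [_INDEX["AB"], _INDEX["BB"]]
    aa = _INDEX["AA"]
    n_concordant = int(c[aa, aa] + c[_INDEX["AB"], _INDEX["AB"]] + c[_INDEX["BB"], _INDEX["BB"]])
    tn = int(c[aa, aa])
    fp = int(c[var, aa].sum())  # pipeline variant, assay reference
    fn = int(c[aa, var].sum())  # pipeline reference, assay variant
    if positive_definition == "detection":
        tp = int(c[np.ix_(var, var)].sum())
    elif positive_definition == "strict":
        tp = int(c[_INDEX["AB"], _INDEX["AB"]] + c[_INDEX["BB"], _INDEX["BB"]])
        fn += int(c[_INDEX["AB"], _INDEX["BB"]] + c[_INDEX["BB"], _INDEX["AB"]])
    else:
        raise ValueError(f"unknown positive_definition {positive_definition!r}")
    return ConcordanceSummary(
        n_total=table.total,
        n_concordant=n_concordant,
        success_rate=n_concordant / table.total,
        true_negative=tn,
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else None,
        sensitivity=tp / (tp + fn) if (tp + fn) > 0 else None,
    )


def load_validation_table() -> ConfusionTable:
    """Bundled pipeline-vs-MassARRAY validation counts (50 loci x 30 fish).

    The published 4x4 genotype count table from a MassARRAY validation of
    GBS-derived SNP calls in large yellow croaker; used as the worked input
    for the concordance statistics.
    """
    path = resources.files("gbskit.data").joinpath("massarray_validation.tsv")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(GENOTYPES), list(GENOTYPES)]
    return ConfusionTable(df.to_numpy())
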