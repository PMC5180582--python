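"""Composite SNP marker filter: per-call depth, site quality, population call rate.

A marker survives when its site quality reaches ``min_qual`` (default 100)
and, after masking genotype calls supported by fewer than ``min_depth``
reads (default 5), at least ``min_callrate`` of samples (default 80%) still
carry a call.  All thresholds are inclusive.  Removed sites are partitioned
by the first failing rule (quality before call rate) in the rejection log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import NN, GenotypeMatrix


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the composite filter (all comparisons inclusive)."""

    min_depth: int = 5
    min_qual: float = 100.0
    min_callrate: float = 0.8
    mask_below_depth: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.min_callrate <= 1:
            raise ValueError("min_callrate must be in (0, 1]")


@dataclass
class FilterReport:
    """Per-rule rejection accounting for one filter run."""

    n_input: int
    n_retained: int
    n_fail_quality: int
    n_fail_callrate: int
    site_fate: pd.DataFrame  # chrom, pos, fate in {retained, quality, callrate}


def apply_filter(
    gm: GenotypeMatrix, policy: FilterPolicy
) -> tuple[GenotypeMatrix, FilterReport]:
    """Filter a genotype matrix; returns (retained matrix, rejection report).

    Calls with depth below ``min_depth`` are masked to missing first (when
    ``mask_below_depth``), then sites failing quality or call-rate are
    removed.  Requires per-call DP and per-site QUAL.
    """
    if gm.depth is None:
        raise ValueError("genotype matrix lacks per-call depth (FORMAT DP)")
    if gm.qual is None:
        raise ValueError("genotype matrix lacks site quality (QUAL)")
    calls = gm.calls.copy()
    if policy.mask_below_depth:
        calls[gm.depth < policy.min_depth] = NN

    n_called = (calls != NN).sum(axis=0)
    need = math.ceil(policy.min_callrate * gm.n_samples)
    ok_qual = gm.qual >= policy.min_qual
    ok_rate = n_called >= need
    retained_mask = ok_qual & ok_rate

    fate = np.where(retained_mask, "retained", np.where(~ok_qual, "quality", "callrate"))
    site_fate = gm.loci[["chrom", "pos"]].copy()
    site_fate["fate"] = fate

    idx = np.flatnonzero(retained_mask)
    retained = GenotypeMatrix(
        samples=list(gm.samples),
        loci=gm.loci.iloc[idx].reset_index(drop=True),
        calls=calls[:, idx],
        depth=gm.depth[:, idx],
        qual=gm.qual[idx],
    )
    report = FilterReport(
        n_input=gm.n_loci,
        n_retained=int(retained_mask.sum()),
        n_fail_quality=int((~ok_qual).sum()),
        n_fail_callrate=int((ok_qual & ~ok_rate).sum()),
        site_fate=site_fate,
    )
    return retained, report


def shared_count_table(
    gm: GenotypeMatrix,
    depth_grid,
    callrate_grid,
    min_qual: float = 100.0,
) -> pd.DataFrame:
    """Retained-marker counts over a depth-threshold x call-rate grid.

    Cell (t, m) equals the number of sites surviving ``apply_filter`` with
    ``min_depth=t`` and ``min_callrate=m``; counts are non-increasing along
    both axes.
    """
    rows = []
    for t in depth_grid:
        row = []
        for m in callrate_grid:
            policy = FilterPolicy(min_depth=int(t), min_qual=min_qual, min_callrate=m)
            _, report = apply_filter(gm, policy)
            row.append(report.n_retained)
        rows.append(row)
    return pd.DataFrame(
        rows,
        index=pd.Index(list(depth_grid), name="min_depth"),
        columns=pd.Index(list(callrate_grid), name="min_callrate"),
    )


def filter_vcf(
    vcf_in: str, vcf_out: str, policy: FilterPolicy
) -> FilterReport:
    """File-level convenience: read VCF, filter, write retained sites."""
    gm = GenotypeMatrix.from_vcf(vcf_in)
    retained, report = apply_filter(gm, policy)
    retained.to_vcf(vcf_out)
    return report
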