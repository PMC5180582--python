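"""Closed-form expected marker yield and shared-SNP retention models.

A reduced-representation library of ``n_fragments`` fragments of roughly
``fragment_len`` bp, at a SNP density of ``snp_rate`` per bp, is expected to
expose ``n_fragments * fragment_len * snp_rate`` SNPs (the back-of-envelope
that turns ~1.5 M fragments of 200 bp at 1 SNP/kb into ~300 k markers).

Whether a SNP is actually genotyped in a sample depends on sequencing depth
at the locus.  Depth is modelled as Poisson with mean ``lambda``; a locus is
callable in one sample when depth reaches a threshold ``t``, and a marker is
retained population-wide when at least ``m`` of ``n`` samples call it
(samples independent, so the retained count follows a binomial tail).  These
two tails reproduce the characteristic depth/completeness retention surface
and the saturation of discovered markers with sequencing amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class YieldConfig:
    """Study-design parameters for the yield model."""

    n_fragments: float
    fragment_len: float = 200.0  # window lower bound; see docs/methods.md
    snp_rate: float = 0.001
    n_samples: int = 500
    depth_mean: float = 10.0
    depth_threshold: int = 5
    completeness: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.snp_rate < 1:
            raise ValueError("snp_rate must be in (0, 1)")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0 < self.completeness <= 1:
            raise ValueError("completeness must be in (0, 1]")


def expected_snp_yield(
    n_fragments: float, fragment_len: float = 200.0, snp_rate: float = 0.001
) -> float:
    """Expected SNP count in the library: fragments x length x SNP density."""
    if n_fragments <= 0 or fragment_len <= 0 or snp_rate < 0:
        raise ValueError("n_fragments and fragment_len must be positive")
    return n_fragments * fragment_len * snp_rate


def detection_prob(
    depth_mean: float, depth_threshold: int, dispersion: float | None = None
) -> float:
    """P(depth >= t) for one locus in one sample.

    Depth is Poisson(``depth_mean``) by default.  ``dispersion`` switches to
    a negative binomial with the same mean and shape ``dispersion`` (smaller
    shape = more overdispersed), for libraries with uneven coverage.
    """
    if depth_mean < 0:
        raise ValueError("depth_mean must be >= 0")
    t = int(depth_threshold)
    if t < 0:
        raise ValueError("depth_threshold must be >= 0")
    if t == 0:
        return 1.0
    if dispersion is None:
        return float(stats.poisson.sf(t - 1, depth_mean))
    r = float(dispersion)
    return float(stats.nbinom.sf(t - 1, r, r / (r + depth_mean)))


def shared_snp_expectation(
    n_loci: float,
    n_samples: int,
    depth_mean: float,
    depth_threshold: int,
    min_samples: int,
    dispersion: float | None = None,
) -> float:
    """Expected number of loci genotyped in at least ``min_samples`` samples.

    Each of ``n_samples`` samples independently reaches the depth threshold
    with probability ``detection_prob``; a locus is retained when a binomial
    count of successes is >= ``min_samples``.
    """
    if min_samples > n_samples:
        raise ValueError("min_samples cannot exceed n_samples")
    p = detection_prob(depth_mean, depth_threshold, dispersion)
    if min_samples <= 0:
        return float(n_loci)
    return float(n_loci * stats.binom.sf(min_samples - 1, n_samples, p))


def saturation_curve(
    seq_amounts: np.ndarray,
    library_bp: float,
    n_loci: float,
    n_samples: int,
    depth_threshold: int,
    min_samples: int,
) -> np.ndarray:
    """Expected discovered markers as a function of per-sample sequencing amount.

    The per-sample mean depth at sequencing amount ``a`` (bp) over a library
    totalling ``library_bp`` bp is ``a / library_bp``; the curve is the
    shared-SNP expectation at each grid point.  It is non-decreasing and
    plateaus at ``n_loci`` as the amount grows.
    """
    if library_bp <= 0:
        raise ValueError("library_bp must be positive")
    amounts = np.asarray(seq_amounts, dtype=float)
    if np.any(amounts < 0):
        raise ValueError("sequencing amounts must be >= 0")
    return np.array(
        [
            shared_snp_expectation(
                n_loci, n_samples, a / library_bp, depth_threshold, min_samples
            )
            for a in amounts
        ]
    )
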