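"""Population diagnostics and single-marker association with variance partition.

The association workflow mirrors a classic GBS trait-mapping analysis:

* identity-by-state (IBS) pairwise distances and classical MDS for
  population-stratification checks;
* a single-marker scan — ordinary least squares of the trait on additive
  genotype dosage (AA=0, AB=1, BB=2) with a sex covariate, two-sided t-test
  on the genotype coefficient, fixed significance threshold p <= 1e-4
  (no multiple-testing correction, by design);
* a VanRaden genomic relationship matrix (GRM) and restricted maximum
  likelihood (REML) variance components for the mixed model
  y = Xb + u + e,  u ~ N(0, sg2 K),  e ~ N(0, se2 I),
  fitted by profiling the restricted likelihood over the variance ratio on
  K's spectral decomposition (Brent search on log(se2/sg2));
* the variance-explained ratio: sg2 estimated with a GRM built from a
  marker subset (e.g. the significant hits) divided by sg2 with the GRM
  from all markers — the statistic summarising how much of the
  marker-captured genetic variance the hits tag;
* a one-sample Kolmogorov-Smirnov normality check of the trait (estimated
  mean/SD, no small-sample correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

# ------------------------------------------------------------------ distances


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS distance: 1 - shared alleles / (2 x compared loci).

    Genotypes share ``2 - |gi - gj|`` alleles under additive coding; missing
    calls are excluded pair-wise.  A pair with no comparable locus gets NaN
    (flagged with a warning).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.dosage()
    n = gm.n_samples
    dist = np.zeros((n, n))
    flagged = 0
    for i in range(n - 1):
        diff = np.abs(g[i] - g[i + 1 :])  # NaN where either is missing
        comp = np.sum(~np.isnan(diff), axis=1)
        shared = 2 * comp - np.nansum(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1 - shared / (2 * comp)
        flagged += int(np.sum(comp == 0))
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    if flagged:
        warnings.warn(f"{flagged} sample pairs share no comparable loci (NaN distance)")
    return dist


def mds(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-centering + spectral decomposition.

    Negative eigenvalues are truncated; if fewer than ``k`` positive
    eigenvalues exist, the embedding is reduced with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12 * max(eigval.max(), 1.0)
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    return eigvec[:, :k] * np.sqrt(eigval[:k])


# ----------------------------------------------------------------------- GWAS


@dataclass(frozen=True)
class AssocResult:
    """Per-locus OLS association: additive effect, SE, t, p, samples used."""

    locus: int
    beta: float
    se: float
    t: float
    p: float
    n_used: int
    reason: str = ""


def _ols_locus(y: np.ndarray, g: np.ndarray, sex: np.ndarray) -> tuple[float, float, float, float]:
    """OLS y ~ 1 + g + sex via normal equations; returns beta, se, t, p for g."""
    n = len(y)
    X = np.column_stack([np.ones(n), g, sex])
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    beta, se = coef[1], np.sqrt(cov[1, 1])
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta, se, t, p


def gwas_scan(
    gm: GenotypeMatrix, phenotypes: pd.DataFrame, chunk: int = 10_000
) -> pd.DataFrame:
    """Single-marker scan: OLS of trait on genotype dosage with sex covariate.

    ``phenotypes`` needs columns sample/trait/sex; samples are matched by id
    and genotype-only samples dropped.  Missing calls are excluded per
    locus; monomorphic loci and loci with fewer than 4 usable samples
    return NA with a reason.  Complete loci are solved in vectorised blocks
    by residualising trait and dosage on [1, sex] (equivalent to the full
    three-parameter OLS); incomplete loci fall back to per-locus normal
    equations.
    """
    pheno = phenotypes.set_index("sample").loc[
        [s for s in gm.samples if s in set(phenotypes["sample"])]
    ]
    keep = np.array([s in pheno.index for s in gm.samples])
    g_all = gm.dosage()[keep]
    y = pheno["trait"].to_numpy(dtype=float)
    sex = pheno["sex"].to_numpy(dtype=float)
    n, n_loci = g_all.shape

    # residualise on covariates once for the complete-case fast path
    C = np.column_stack([np.ones(n), sex])
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    df = n - 3

    beta = np.full(n_loci, np.nan)
    se = np.full(n_loci, np.nan)
    tstat = np.full(n_loci, np.nan)
    pval = np.full(n_loci, np.nan)
    n_used = np.zeros(n_loci, dtype=int)
    reason = np.full(n_loci, "", dtype=object)

    complete = ~np.isnan(g_all).any(axis=0)
    mono = np.zeros(n_loci, dtype=bool)

    comp_idx = np.flatnonzero(complete)
    for lo in range(0, len(comp_idx), chunk):
        idx = comp_idx[lo : lo + chunk]
        G = g_all[:, idx]
        var = G.var(axis=0)
        ok = var > 0
        mono[idx[~ok]] = True
        idx, G = idx[ok], G[:, ok]
        if idx.size == 0:
            continue
        G_res = G - Q @ (Q.T @ G)
        gg = np.einsum("ij,ij->j", G_res, G_res)
        gy = G_res.T @ y_res
        b = gy / gg
        rss = y_res @ y_res - b * gy
        sigma2 = rss / df
        s = np.sqrt(sigma2 / gg)
        beta[idx], se[idx] = b, s
        with np.errstate(divide="ignore", invalid="ignore"):
            # a perfect fit has zero residual variance; t is +/- inf, p -> 0
            tstat[idx] = b / s
        pval[idx] = 2 * stats.t.sf(np.abs(tstat[idx]), df)
        n_used[idx] = n

    for jdx in np.flatnonzero(~complete):
        gj = g_all[:, jdx]
        use = ~np.isnan(gj)
        m = int(use.sum())
        n_used[jdx] = m
        if m < 4:
            reason[jdx] = "too_few_samples"
            continue
        if gj[use].var() == 0:
            mono[jdx] = True
            continue
        beta[jdx], se[jdx], tstat[jdx], pval[jdx] = _ols_locus(
            y[use], gj[use], sex[use]
        )
        # df differs per locus in the fallback path; recompute p there
    reason[mono] = "monomorphic"
    n_used[complete] = np.where(mono[complete], n, n_used[complete])

    out = gm.loci[["chrom", "pos"]].copy()
    out["beta"], out["se"], out["t"], out["p"] = beta, se, tstat, pval
    out["n_used"], out["reason"] = n_used, reason
    return out


def significant(results: pd.DataFrame, alpha: float = 1e-4) -> pd.DataFrame:
    """Markers with p <= alpha (inclusive), sorted by p."""
    hits = results[results["p"] <= alpha].copy()
    return hits.sort_values("p", kind="stable").reset_index(drop=True)


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-locus (chrom, pos, -log10 p) export for Manhattan plotting."""
    out = results[["chrom", "pos"]].copy()
    out["neg_log10_p"] = -np.log10(results["p"])
    return out


# ------------------------------------------------------------------------ GRM


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix from additive dosages.

    Missing calls are mean-imputed per locus; loci with every call missing
    are excluded with a warning.  K = Z Z' / (2 sum p(1-p)) with Z the
    allele-frequency-centred dosage matrix; K is symmetric PSD with mean
    diagonal near 1 for unrelated samples.
    """
    g = gm.dosage()
    all_missing = np.isnan(g).all(axis=0)
    if all_missing.any():
        warnings.warn(f"excluding {int(all_missing.sum())} all-missing loci from GRM")
        g = g[:, ~all_missing]
    mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    p = mean / 2
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for a GRM")
    z = g[:, poly] - 2 * p[poly]
    denom = 2 * np.sum(p[poly] * (1 - p[poly]))
    return z @ z.T / denom


# ----------------------------------------------------------------------- REML


@dataclass(frozen=True)
class VarCompResult:
    """REML variance components and fit diagnostics."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool
    boundary: bool  # optimum at the edge of the search interval

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


def reml_varcomp(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    log_delta_bounds: tuple[float, float] = (-12.0, 12.0),
    tol: float = 1e-8,
) -> VarCompResult:
    """REML fit of y = Xb + u + e with u ~ N(0, sg2 K), e ~ N(0, se2 I).

    The restricted likelihood is profiled over delta = se2/sg2 on the
    spectral decomposition of K and maximised by bounded Brent search over
    log(delta).  An optimum at either bound is reported as a boundary
    solution (sg2 -> 0 corresponds to the upper bound).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([np.ones(n), covariates])
    p = X.shape[1]
    if n < p + 2:
        raise ValueError("too few observations for the fixed effects")
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be a symmetric n x n matrix")
    s, U = np.linalg.eigh(K)
    if s.max() <= 1e-10:
        raise ValueError("K is (numerically) zero; variance ratio unidentifiable")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (s + delta)
        XtWX = (Xt * w[:, None]).T @ Xt
        XtWy = (Xt * w[:, None]).T @ yt
        coef = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ coef
        rss = float(r @ (w * r))
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * rss / (n - p))
            + (n - p)
            + np.sum(np.log(s + delta))
            + logdet_xwx
            - logdet_xtx
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=log_delta_bounds,
        method="bounded",
        options={"xatol": tol},
    )
    log_delta = float(res.x)
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    XtWX = (Xt * w[:, None]).T @ Xt
    coef = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt)
    r = yt - Xt @ coef
    sigma_g2 = float(r @ (w * r)) / (n - p)
    sigma_e2 = delta * sigma_g2
    span = log_delta_bounds[1] - log_delta_bounds[0]
    boundary = (
        log_delta <= log_delta_bounds[0] + 1e-3 * span
        or log_delta >= log_delta_bounds[1] - 1e-3 * span
    )
    if boundary and log_delta >= log_delta_bounds[1] - 1e-3 * span:
        # delta huge: genetic variance at the zero bound
        sigma_e2 = sigma_g2 * delta
        total = float(np.var(y, ddof=1))
        sigma_g2, sigma_e2 = 0.0, min(sigma_e2, total)
    return VarCompResult(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        loglik=-float(res.fun),
        converged=bool(res.success),
        boundary=boundary,
    )


def variance_explained_ratio(
    y: np.ndarray,
    covariates: np.ndarray | None,
    gm_subset: GenotypeMatrix,
    gm_all: GenotypeMatrix,
) -> tuple[float | None, VarCompResult, VarCompResult]:
    """sg2 from the subset-marker GRM over sg2 from the all-marker GRM.

    Both REML fits use identical covariates.  The ratio is None (flagged)
    when either fit lands on the zero-variance boundary.
    """
    fit_subset = reml_varcomp(y, covariates, grm(gm_subset))
    fit_all = reml_varcomp(y, covariates, grm(gm_all))
    if fit_all.sigma_g2 <= 0 or fit_subset.boundary or fit_all.boundary:
        warnings.warn("variance ratio undefined (boundary or zero genetic variance)")
        return None, fit_subset, fit_all
    return fit_subset.sigma_g2 / fit_all.sigma_g2, fit_subset, fit_all


# ------------------------------------------------------------------ normality


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS test of the trait against N(sample mean, sample SD)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant trait vector")
    stat = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat.statistic), float(stat.pvalue)
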