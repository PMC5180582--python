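import numpy as np
import pandas as pd
import pytest

from gbskit.assoc import (
    grm,
    gwas_scan,
    ibs_distance,
    ks_normality,
    manhattan_table,
    mds,
    reml_varcomp,
    significant,
    variance_explained_ratio,
)
from gbskit.genotypes import GenotypeMatrix
from gbskit.synthetic_data import SimConfig, simulate_phenotype


def _gm(calls, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    loci = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_l,
            "pos": np.arange(n_l) * 10,
            "ref": ["A"] * n_l,
            "alt": ["G"] * n_l,
        }
    )
    return GenotypeMatrix(
        samples=samples or [f"S{i}" for i in range(n_s)], loci=loci, calls=calls
    )


class TestIbsDistance:
    def test_identical_samples_zero(self):
        gm = _gm([[0, 1, 2, 1], [0, 1, 2, 1]])
        assert ibs_distance(gm)[0, 1] == 0.0

    def test_opposite_homozygotes_max_distance(self):
        gm = _gm([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance(gm)[0, 1] == 1.0

    def test_hand_computed_matrix_with_missing(self):
        gm = _gm([[0, 1, 2, 0], [0, 1, 0, 2], [-1, 2, 2, 0]])
        d = ibs_distance(gm)
        assert d[0, 1] == pytest.approx(0.5)       # shared 4 of 8 alleles
        assert d[0, 2] == pytest.approx(1 / 6)     # 3 comparable loci
        assert d[1, 2] == pytest.approx(5 / 6)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_no_comparable_loci_flagged_nan(self):
        gm = _gm([[0, -1], [-1, 0]])
        with pytest.warns(UserWarning, match="no comparable"):
            d = ibs_distance(gm)
        assert np.isnan(d[0, 1])


class TestMds:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = mds(d, k=2)
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-9)

    def test_round_trip_of_planted_coordinates(self, rng):
        pts = rng.standard_normal((12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = mds(d, k=2)
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)

    def test_identical_samples_collapse(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords = mds(d, k=2)
        assert coords.shape[1] == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            mds(d)


def _ols_oracle(y, g, sex):
    """Normal-equations OLS for y ~ 1 + g + sex, written independently."""
    X = np.column_stack([np.ones(len(y)), g, sex])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    df = len(y) - 3
    s2 = resid @ resid / df
    se = np.sqrt(s2 * XtX_inv[1, 1])
    from scipy.stats import t as tdist

    t = beta_hat[1] / se
    p = 2 * tdist.sf(abs(t), df)
    return beta_hat[1], se, t, p


class TestGwasScan:
    def test_matches_normal_equations_oracle(self, rng):
        n = 12
        calls = rng.integers(0, 3, size=(n, 6)).astype(np.int8)
        gm = _gm(calls)
        y = rng.normal(21.5, 4.1, size=n)
        sex = rng.integers(0, 2, size=n)
        pheno = pd.DataFrame({"sample": gm.samples, "trait": y, "sex": sex})
        res = gwas_scan(gm, pheno)
        for j in range(6):
            g = calls[:, j].astype(float)
            if g.var() == 0:
                assert res.loc[j, "reason"] == "monomorphic"
                continue
            beta, se, t, p = _ols_oracle(y, g, sex)
            assert res.loc[j, "beta"] == pytest.approx(beta, abs=1e-10)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-10)
            assert res.loc[j, "p"] == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        n = 40
        calls = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
        gm = _gm(calls)
        y = rng.normal(size=n)
        sex = rng.integers(0, 2, size=n)
        pheno = pd.DataFrame({"sample": gm.samples, "trait": y, "sex": sex})
        res = gwas_scan(gm, pheno)
        for j in range(3):
            X = sm.add_constant(np.column_stack([calls[:, j], sex]))
            fit = sm.OLS(y, X).fit()
            assert res.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_missing_calls_excluded_per_locus(self, rng):
        n = 30
        calls = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        calls[:5, 0] = -1
        gm = _gm(calls)
        y = rng.normal(size=n)
        sex = rng.integers(0, 2, size=n)
        pheno = pd.DataFrame({"sample": gm.samples, "trait": y, "sex": sex})
        res = gwas_scan(gm, pheno)
        assert res.loc[0, "n_used"] == 25
        use = calls[:, 0] >= 0
        beta, se, t, p = _ols_oracle(y[use], calls[use, 0].astype(float), sex[use])
        assert res.loc[0, "beta"] == pytest.approx(beta, abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_noise_free_signal_gives_vanishing_p(self):
        calls = np.tile([0, 1, 2], 8).reshape(-1, 1).astype(np.int8)
        gm = _gm(calls)
        y = 2.0 * calls[:, 0] + 10.0
        sex = np.tile([0, 1], 12)
        pheno = pd.DataFrame({"sample": gm.samples, "trait": y, "sex": sex})
        res = gwas_scan(gm, pheno)
        assert res.loc[0, "beta"] == pytest.approx(2.0)
        assert res.loc[0, "p"] < 1e-30

    def test_too_few_samples_na(self):
        calls = np.array([[0], [1], [2], [-1], [-1]], dtype=np.int8)
        gm = _gm(calls)
        pheno = pd.DataFrame(
            {"sample": gm.samples, "trait": [1.0, 2, 3, 4, 5], "sex": [0, 1, 0, 1, 0]}
        )
        res = gwas_scan(gm, pheno)
        assert res.loc[0, "reason"] == "too_few_samples"
        assert np.isnan(res.loc[0, "p"])


class TestSignificant:
    def test_threshold_inclusive_and_sorted(self):
        res = pd.DataFrame(
            {"chrom": ["c"] * 4, "pos": range(4), "p": [1e-4, 5e-5, 2e-4, np.nan]}
        )
        hits = significant(res, alpha=1e-4)
        assert list(hits["p"]) == [5e-5, 1e-4]

    def test_empty_input(self):
        res = pd.DataFrame({"chrom": [], "pos": [], "p": []})
        assert len(significant(res)) == 0

    def test_manhattan_table_matches_scan(self):
        res = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3], "p": [0.1, 0.01, 1e-5]})
        man = manhattan_table(res)
        assert np.allclose(man["neg_log10_p"], [1, 2, 5])


class TestGrm:
    def test_hand_computed_entries(self, rng):
        calls = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        gm = _gm(calls)
        K = grm(gm)
        # independent VanRaden computation with explicit loops
        g = calls.astype(float)
        p = g.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        denom = 2 * sum(pk * (1 - pk) for pk in p[keep])
        for i in range(4):
            for j in range(4):
                expected = (
                    sum(
                        (g[i, k] - 2 * p[k]) * (g[j, k] - 2 * p[k])
                        for k in range(6)
                        if keep[k]
                    )
                    / denom
                )
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_samples_match_diagonal(self, rng):
        base = rng.integers(0, 3, size=(1, 50))
        other = rng.integers(0, 3, size=(3, 50))
        calls = np.vstack([base, base, other]).astype(np.int8)
        K = grm(_gm(calls))
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_psd_and_unit_diagonal_scale(self, rng):
        # Hardy-Weinberg genotypes: diagonal scales to ~1 for unrelateds
        p = rng.uniform(0.1, 0.5, size=400)
        calls = rng.binomial(2, p, size=(30, 400)).astype(np.int8)
        K = grm(_gm(calls))
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.25)

    def test_all_missing_locus_excluded_with_warning(self, rng):
        calls = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
        calls[:, 2] = -1
        with pytest.warns(UserWarning, match="all-missing"):
            grm(_gm(calls))


class TestReml:
    def test_null_trait_gives_zero_genetic_variance(self, rng):
        n = 120
        Z = rng.standard_normal((n, 400)) / 20
        K = Z @ Z.T
        sg2 = [
            reml_varcomp(rng.standard_normal(n), None, K).sigma_g2 for _ in range(8)
        ]
        assert np.mean(sg2) < 0.1

    def test_parameter_recovery_from_direct_mixed_model_draws(self, rng):
        n, h2_true = 300, 0.5
        estimates = []
        for _ in range(10):
            Z = rng.standard_normal((n, 1000)) / np.sqrt(1000)
            K = Z @ Z.T
            L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
            u = L @ rng.standard_normal(n)
            e = rng.standard_normal(n)
            y = 3.0 + u + e  # sg2 = se2 = 1
            fit = reml_varcomp(y, None, K)
            estimates.append(fit.heritability)
        assert np.mean(estimates) == pytest.approx(h2_true, abs=0.1)

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            reml_varcomp(np.arange(10.0), None, np.zeros((10, 10)))

    def test_covariates_accepted(self, rng):
        n = 80
        Z = rng.standard_normal((n, 200)) / np.sqrt(200)
        K = Z @ Z.T
        y = rng.standard_normal(n) + 2.0 * rng.integers(0, 2, size=n)
        fit = reml_varcomp(y, rng.integers(0, 2, size=n), K)
        assert fit.sigma_e2 > 0


@pytest.fixture(scope="module")
def heritable_study():
    rng = np.random.default_rng(77)
    n, L = 400, 600
    calls = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    gm = _gm(calls)
    config = SimConfig(n_samples=n, n_causal=20, seed=77)
    pheno, effects = simulate_phenotype(gm, config)
    return gm, pheno, effects


class TestVarianceRatio:
    def test_subset_equal_to_all_gives_unit_ratio(self, heritable_study):
        gm, pheno, _ = heritable_study
        ratio, _, _ = variance_explained_ratio(
            pheno["trait"].to_numpy(), pheno["sex"].to_numpy(), gm, gm
        )
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_causal_subset_recovers_target_fraction(self, heritable_study):
        gm, pheno, effects = heritable_study
        causal = np.flatnonzero(effects["is_causal"].to_numpy())
        ratio, _, _ = variance_explained_ratio(
            pheno["trait"].to_numpy(),
            pheno["sex"].to_numpy(),
            gm.subset_loci(causal),
            gm,
        )
        assert ratio == pytest.approx(0.63, abs=0.2)

    def test_null_subset_gives_small_ratio(self, heritable_study):
        gm, pheno, effects = heritable_study
        null_idx = np.flatnonzero(~effects["is_causal"].to_numpy())[:20]
        ratio, fit_sub, fit_all = variance_explained_ratio(
            pheno["trait"].to_numpy(), pheno["sex"].to_numpy(),
            gm.subset_loci(null_idx), gm,
        )
        if ratio is not None:  # boundary fit flags the ratio as undefined
            assert ratio < 0.25


class TestKsNormality:
    def test_hand_computed_statistic(self):
        from scipy.stats import norm

        x = np.array([1.0, 2.0, 2.5, 3.0, 3.2, 4.0, 4.5, 5.0, 6.0, 9.0])
        D, _ = ks_normality(x)
        xs = np.sort(x)
        F = norm.cdf(xs, x.mean(), x.std(ddof=1))
        n = len(x)
        D_manual = max(
            max((i + 1) / n - F[i], F[i] - i / n) for i in range(n)
        )
        assert D == pytest.approx(D_manual, abs=1e-12)

    def test_normal_sample_not_rejected(self, rng):
        x = rng.normal(21.5, 4.1, size=500)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_exponential_sample_rejected(self, rng):
        x = rng.exponential(size=500)
        _, p = ks_normality(x)
        assert p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(10))
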