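"""Kinship, REML polygenic fit, and the single-marker score test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import triadqtl as tq
from triadqtl.mixedmodel import (
    KinshipMatrix,
    _reml_neg_loglik,
    build_design,
    compute_grm,
    fit_polygenic,
    scan_vector,
    score_test,
)
from triadqtl.containers import GenotypeMatrix


def _toy_genotypes(rng, n=40, m=60, dup_first=False):
    p = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if dup_first:
        dos[1] = dos[0]
    snps = [f"s{j}" for j in range(m)]
    return GenotypeMatrix(
        dosages=pd.DataFrame(dos, index=[f"i{i}" for i in range(n)], columns=snps),
        snp_map=pd.DataFrame({"snp": snps, "chrom": 1, "pos": np.arange(1, m + 1) * 1000}),
    )


class TestGrm:
    def test_identical_samples_match_mean_diagonal(self, rng):
        g = _toy_genotypes(rng, dup_first=True)
        K = compute_grm(g)
        diag = np.diag(K.values)
        assert K.values[0, 1] == pytest.approx(diag[:2].mean(), rel=1e-6)

    def test_invariant_under_allele_swap(self, rng):
        g = _toy_genotypes(rng)
        K1 = compute_grm(g).values
        flipped = g.dosages.copy()
        flipped.iloc[:, 0] = 2.0 - flipped.iloc[:, 0]
        g2 = GenotypeMatrix(dosages=flipped, snp_map=g.snp_map)
        np.testing.assert_allclose(K1, compute_grm(g2).values, atol=1e-12)

    def test_all_missing_sample_rejected(self, rng):
        g = _toy_genotypes(rng)
        d = g.dosages.copy()
        d.iloc[0, :] = np.nan
        with pytest.raises(ValueError, match="no genotype"):
            compute_grm(GenotypeMatrix(dosages=d, snp_map=g.snp_map))

    def test_mean_diagonal_near_one(self, small_kinship):
        assert 0.8 < np.diag(small_kinship.values).mean() < 1.5


class TestPolygenicFit:
    def test_identity_kinship_reduces_to_ols(self, rng):
        n = 80
        idx = pd.Index([f"i{i}" for i in range(n)])
        sex = pd.Series(rng.integers(1, 3, n), index=idx)
        batch = pd.Series(rng.integers(1, 4, n), index=idx)
        X = build_design(sex, batch)
        y = pd.Series(rng.normal(size=n), index=idx)
        K = KinshipMatrix(values=np.eye(n), samples=idx)
        _, adj = fit_polygenic(y, X, K)
        Xm = X.to_numpy()
        beta = np.linalg.lstsq(Xm, y.to_numpy(), rcond=None)[0]
        ols_resid = y.to_numpy() - Xm @ beta
        np.testing.assert_allclose(adj.residuals.to_numpy(), ols_resid, atol=1e-8)

    def test_reml_optimum_matches_grid_search(self, small_f2, small_kinship, rng):
        n = small_f2.n_samples
        w, U = np.linalg.eigh(small_kinship.values)
        gpoly = (U * np.sqrt(np.clip(w, 0, None))) @ rng.normal(size=n)
        y = pd.Series(
            gpoly / gpoly.std() + rng.normal(size=n), index=small_f2.samples
        )
        X = build_design(small_f2.sex, small_f2.batch)
        vc, adj = fit_polygenic(y, X, small_kinship)
        d = np.clip(w, 0, None)
        yt = U.T @ y.to_numpy()
        Xt = U.T @ X.to_numpy()
        grid = np.arange(0.0, 0.999, 0.001)
        nlls = [_reml_neg_loglik(h, d, yt, Xt)[0] for h in grid]
        assert vc.loglik >= -min(nlls) - 1e-4

    def test_constant_vector_rejected(self, small_f2, small_kinship):
        y = pd.Series(1.0, index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        with pytest.raises(ValueError, match="constant"):
            fit_polygenic(y, X, small_kinship)

    def test_residuals_orthogonal_to_design_under_v_inner_product(
        self, small_f2, small_kinship, rng
    ):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        vc, adj = fit_polygenic(y, X, small_kinship)
        w = adj.v_weights()
        rt = adj._U.T @ adj.residuals.to_numpy()
        Xt = adj._U.T @ adj._X
        score = Xt.T @ (rt / w)
        assert np.abs(score).max() < 1e-8 * np.abs(y).max()

    def test_blup_mode_removes_polygenic_component(self, small_f2, small_kinship, rng):
        n = small_f2.n_samples
        w, U = np.linalg.eigh(small_kinship.values)
        gpoly = (U * np.sqrt(np.clip(w, 0, None))) @ rng.normal(size=n)
        gpoly = gpoly / gpoly.std()
        y = pd.Series(2 * gpoly + rng.normal(size=n), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj_gls = fit_polygenic(y, X, small_kinship, mode="gls")
        _, adj_blup = fit_polygenic(y, X, small_kinship, mode="ols-after-polygenic")
        r_gls = np.corrcoef(adj_gls.residuals, gpoly)[0, 1]
        r_blup = np.corrcoef(adj_blup.residuals, gpoly)[0, 1]
        assert abs(r_blup) < abs(r_gls)


class TestScoreTest:
    def test_orthogonal_dosage_gives_null_statistic(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj = fit_polygenic(y, X, small_kinship)
        # construct a dosage-like vector orthogonal to the residuals under V
        w = adj.v_weights()
        rt = adj._U.T @ adj.residuals.to_numpy()
        gt = rng.normal(size=len(rt))
        gt -= (gt @ (rt / w)) / (rt @ (rt / w)) * rt
        Xt = adj._U.T @ adj._X
        coef = np.linalg.solve(Xt.T @ (Xt / w[:, None]), Xt.T @ (gt / w))
        gt_c = gt - Xt @ coef
        # fold the covariate projection back in so only orthogonality to r remains
        g = pd.Series(adj._U @ (gt_c + Xt @ coef), index=adj.samples)
        chi2, p, sign = score_test(adj, g)
        assert chi2 == pytest.approx(0.0, abs=1e-16)
        assert p == pytest.approx(1.0)

    def test_dosage_flip_flips_sign_not_p(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj = fit_polygenic(y, X, small_kinship)
        g = small_f2.dosages.iloc[:, 17]
        c1, p1, s1 = score_test(adj, g)
        c2, p2, s2 = score_test(adj, 2.0 - g)
        assert c1 == pytest.approx(c2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)
        assert s1 == -s2

    def test_invariant_under_phenotype_rescaling(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        g = small_f2.dosages.iloc[:, 33]
        _, adj1 = fit_polygenic(y, X, small_kinship)
        _, adj2 = fit_polygenic(7.5 * y, X, small_kinship)
        c1, p1, _ = score_test(adj1, g)
        c2, p2, _ = score_test(adj2, g)
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_identity_kinship_matches_pearson_t(self, rng):
        """With K = I the score test reproduces the correlation t test."""
        n = 100
        idx = pd.Index([f"i{i}" for i in range(n)])
        K = KinshipMatrix(values=np.eye(n), samples=idx)
        X = pd.DataFrame({"intercept": 1.0}, index=idx)
        worst = 0.0
        for _ in range(60):
            y = pd.Series(rng.normal(size=n), index=idx)
            g = pd.Series(rng.binomial(2, 0.4, size=n).astype(float), index=idx)
            _, adj = fit_polygenic(y, X, K)
            _, p_score, _ = score_test(adj, g)
            r = np.corrcoef(y, g)[0, 1]
            t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
            p_t = 2 * stats.t.sf(t, n - 2)
            worst = max(worst, abs(np.log10(p_score) - np.log10(p_t)))
        assert worst <= 0.1

    def test_matches_exact_gls_f_oracle_with_arbitrary_kinship(self, rng):
        """Brute-force per-SNP GLS refit at the fitted variance components."""
        n, m = 60, 50
        cfg = tq.SimConfig(seed=21, n_f2=n, n_chrom=2, n_snps_per_chrom=m // 2, n_transcripts=1)
        g = tq.simulate_genotypes(cfg)
        f2 = g.subset(samples=g.f2_samples())
        K = compute_grm(f2)
        w, U = np.linalg.eigh(K.values)
        gpoly = (U * np.sqrt(np.clip(w, 0, None))) @ rng.normal(size=n)
        y = pd.Series(gpoly / gpoly.std() + rng.normal(size=n), index=f2.samples)
        X = build_design(f2.sex, f2.batch)
        vc, adj = fit_polygenic(y, X, K)
        V = vc.sigma2_g * K.values + vc.sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        yv = y.to_numpy()
        worst = 0.0
        for snp in f2.snps:
            gd = f2.dosages[snp].to_numpy()
            if gd.std() == 0:
                continue
            _, p_score, _ = score_test(adj, f2.dosages[snp])
            Xg = np.column_stack([X.to_numpy(), gd])
            A = Xg.T @ Vi @ Xg
            beta = np.linalg.solve(A, Xg.T @ Vi @ yv)
            se = np.sqrt(np.linalg.inv(A)[-1, -1])
            p_wald = 2 * stats.norm.sf(abs(beta[-1] / se))
            worst = max(worst, abs(np.log10(p_score) - np.log10(p_wald)))
        assert worst <= 0.1

    def test_missing_dosages_dropped_per_snp(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj = fit_polygenic(y, X, small_kinship)
        g = small_f2.dosages.iloc[:, 11].copy()
        g.iloc[:15] = np.nan
        chi2, p, _ = score_test(adj, g)
        assert np.isfinite(chi2) and 0 < p <= 1
        # oracle: explicit subset computation
        keep = g.notna()
        Ksub = small_kinship.values[np.ix_(keep.to_numpy(), keep.to_numpy())]
        V = adj.vc.sigma2_g * Ksub + adj.vc.sigma2_e * np.eye(int(keep.sum()))
        Vi = np.linalg.inv(V)
        gv = g[keep].to_numpy()
        Xs = adj._X[keep.to_numpy()]
        coef = np.linalg.solve(Xs.T @ Vi @ Xs, Xs.T @ Vi @ gv)
        gc = gv - Xs @ coef
        r = adj.residuals[keep].to_numpy()
        T = (gc @ Vi @ r) ** 2 / (gc @ Vi @ gc)
        assert chi2 == pytest.approx(T, rel=1e-8)

    def test_monomorphic_snp_skipped(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj = fit_polygenic(y, X, small_kinship)
        g = pd.Series(1.0, index=small_f2.samples)
        chi2, p, sign = score_test(adj, g)
        assert np.isnan(p) and sign == 0

    def test_vectorized_scan_matches_single_snp_path(self, small_f2, small_kinship, rng):
        y = pd.Series(rng.normal(size=small_f2.n_samples), index=small_f2.samples)
        X = build_design(small_f2.sex, small_f2.batch)
        _, adj = fit_polygenic(y, X, small_kinship)
        res = scan_vector(adj, small_f2.dosages.iloc[:, :25])
        for _, row in res.iterrows():
            c, p, s = score_test(adj, small_f2.dosages[row["snp"]])
            if np.isnan(c):
                assert np.isnan(row["chi2"])  # monomorphic in both paths
                continue
            assert row["chi2"] == pytest.approx(c, rel=1e-9)
            assert row["effect_sign"] == s
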