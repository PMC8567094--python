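"""Adjacency, TOM, soft threshold, module detection, eigengenes,
connectivity and edge export."""

import numpy as np
import pandas as pd
import pytest

import triadqtl as tq
from triadqtl import coexpr

from helpers import brute_force_tom, module_dataset, scale_free_expression


def _frame(A, prefix="g"):
    names = [f"{prefix}{i}" for i in range(A.shape[0])]
    return pd.DataFrame(A, index=names, columns=names)


class TestAdjacency:
    def test_power_arithmetic(self, rng):
        x = rng.normal(size=80)
        expr = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=80)})
        A1 = coexpr.adjacency(expr, beta=1)
        assert A1.loc["a", "b"] == pytest.approx(1.0)
        R = coexpr.correlation_matrix(expr)
        A2 = coexpr.adjacency(expr, beta=2)
        assert A2.loc["a", "c"] == pytest.approx(R.loc["a", "c"] ** 2)

    def test_power_monotonicity(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 20)))
        expr.columns = [f"g{i}" for i in range(20)]
        A2 = coexpr.adjacency(expr, beta=2).to_numpy()
        A6 = coexpr.adjacency(expr, beta=6).to_numpy()
        off = ~np.eye(20, dtype=bool)
        assert (A6[off] <= A2[off] + 1e-15).all()

    def test_constant_gene_rejected(self, rng):
        expr = pd.DataFrame({"flat": np.ones(30), "x": rng.normal(size=30)})
        with pytest.raises(ValueError, match="flat"):
            coexpr.adjacency(expr, beta=2)


class TestTom:
    def test_disconnected_nodes_have_zero_overlap(self):
        A = _frame(np.eye(4))
        T = coexpr.tom(A)
        off = ~np.eye(4, dtype=bool)
        assert (T.to_numpy()[off] == 0).all()
        assert (np.diag(T) == 1).all()

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_uniform_triangle_closed_form(self, a):
        # three nodes, all pairs at weight a: TOM = (a^2 + a)/(a + 1) = a
        A = _frame(np.full((3, 3), a))
        np.fill_diagonal(A.to_numpy(), 1.0)
        T = coexpr.tom(A)
        assert T.iloc[0, 1] == pytest.approx(a, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        m = 50
        R = rng.uniform(0, 1, size=(m, m))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        T = coexpr.tom(_frame(R))
        oracle = brute_force_tom(R)
        np.testing.assert_allclose(T.to_numpy(), oracle, atol=1e-10)
        assert (T.to_numpy() >= 0).all() and (T.to_numpy() <= 1).all()
        np.testing.assert_allclose(T.to_numpy(), T.to_numpy().T, atol=1e-12)


class TestSoftThreshold:
    def test_scale_free_input_reaches_high_fit(self):
        expr = scale_free_expression(250, 280, seed=0)
        table, beta, reached = coexpr.soft_threshold_scan(expr, betas=range(1, 11))
        assert reached
        assert table.loc[table["beta"] == beta, "r2"].iloc[0] >= 0.9

    def test_independent_genes_take_fallback(self, rng):
        expr = pd.DataFrame(rng.normal(size=(100, 120)))
        expr.columns = [f"g{i}" for i in range(120)]
        table, beta, reached = coexpr.soft_threshold_scan(expr, betas=range(1, 9))
        assert not reached
        assert (table["r2"] < 0.85).all()

    def test_minimum_gene_count_enforced(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 20)))
        with pytest.raises(ValueError, match="50 genes"):
            coexpr.soft_threshold_scan(expr)


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        n, b = 150, 50
        f1, f2_ = rng.normal(size=n), rng.normal(size=n)
        load = np.sqrt(0.6)
        X = np.concatenate(
            [
                load * f1[:, None] + np.sqrt(1 - 0.6) * rng.normal(size=(n, b)),
                load * f2_[:, None] + np.sqrt(1 - 0.6) * rng.normal(size=(n, b)),
            ],
            axis=1,
        )
        expr = pd.DataFrame(X, columns=[f"g{i:03d}" for i in range(2 * b)])
        A = coexpr.adjacency(expr, beta=2)
        T = coexpr.tom(A)
        mod = coexpr.detect_modules(T, A)
        assert len(mod.sizes) == 2
        left = set(mod.labels.iloc[:b])
        right = set(mod.labels.iloc[b:])
        assert left != right and len(left) == 1 and len(right) == 1

    def test_independent_genes_all_unassigned(self, rng):
        expr = pd.DataFrame(rng.normal(size=(80, 100)))
        expr.columns = [f"g{i}" for i in range(100)]
        A = coexpr.adjacency(expr, beta=2)
        T = coexpr.tom(A)
        mod = coexpr.detect_modules(T, A, min_size=30)
        assert (mod.labels == 0).all()

    def test_labels_invariant_to_gene_order(self):
        expr, _ = module_dataset(seed=42, sizes=(40, 50), n_background=40, n_f2=150)
        le = expr.log_values()
        perm = np.random.default_rng(1).permutation(le.shape[1])
        shuffled = le.iloc[:, perm]

        def partition(frame):
            A = coexpr.adjacency(frame, beta=2)
            mod = coexpr.detect_modules(coexpr.tom(A), A)
            return mod.labels.sort_index()

        a, b = partition(le), partition(shuffled)
        # same partition up to label names
        table = pd.crosstab(a, b)
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert (table.gt(0).sum(axis=0) == 1).all()

    def test_modules_ordered_by_decreasing_size(self):
        expr, truth = module_dataset(seed=7, sizes=(40, 60), n_background=30, n_f2=150)
        le = expr.log_values()
        A = coexpr.adjacency(le, beta=2)
        mod = coexpr.detect_modules(coexpr.tom(A), A)
        sizes = mod.sizes.to_numpy()
        assert (np.diff(sizes) <= 0).all()


class TestEigengene:
    def test_identical_genes_reproduce_common_profile(self, rng):
        x = rng.normal(size=60)
        expr = pd.DataFrame({f"g{i}": x * (i + 1) for i in range(4)})
        eg = coexpr.module_eigengene(expr, expr.columns)
        z = (x - x.mean()) / x.std()
        assert abs(np.corrcoef(eg.scores, z)[0, 1]) == pytest.approx(1.0)
        assert eg.variance_explained == pytest.approx(1.0)
        # sign convention: positively aligned with members
        assert np.corrcoef(eg.scores, x)[0, 1] > 0

    def test_gene_sign_flip_flips_eigengene(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        expr = expr.add(expr.mean(axis=1), axis=0)  # correlated block
        eg1 = coexpr.module_eigengene(expr, expr.columns)
        eg2 = coexpr.module_eigengene(-expr, expr.columns)
        assert np.corrcoef(eg1.scores, eg2.scores)[0, 1] == pytest.approx(-1.0)

    def test_eigengene_tracks_planted_factor(self):
        expr, truth = module_dataset(seed=3, sizes=(50,), n_background=50, n_f2=200)
        labels = pd.Series(truth.module_labels)
        genes = labels[labels == 1].index
        eg = coexpr.module_eigengene(expr.log_values(), genes)
        r = np.corrcoef(eg.scores, truth.module_factors[1])[0, 1]
        assert abs(r) >= 0.9


class TestModuleTrait:
    def test_reciprocal_product_threshold(self, rng):
        egenes = pd.DataFrame(rng.normal(size=(60, 5)), columns=[f"ME{i}" for i in range(1, 6)])
        traits = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("wxyz"))
        traits["mirror"] = egenes["ME1"]
        out, alpha = coexpr.module_trait_correlation(egenes, traits)
        assert alpha == pytest.approx(1.0 / (5 * 5))
        row = out[(out["module"] == "ME1") & (out["trait"] == "mirror")].iloc[0]
        assert row["r"] == pytest.approx(1.0) and bool(row["significant"])

    def test_null_traits_rarely_significant(self, rng):
        egenes = pd.DataFrame(rng.normal(size=(200, 10)), columns=[f"ME{i}" for i in range(10)])
        traits = pd.DataFrame(rng.normal(size=(200, 20)), columns=[f"t{i}" for i in range(20)])
        out, alpha = coexpr.module_trait_correlation(egenes, traits)
        assert out["significant"].mean() < 5 * alpha + 0.02


class TestConnectivity:
    def test_star_graph_hand_sums(self):
        m, c = 6, 0.4
        A = np.zeros((m, m))
        A[0, 1:] = c
        A[1:, 0] = c
        np.fill_diagonal(A, 1.0)
        labels = pd.Series(1, index=[f"g{i}" for i in range(m)])
        conn = coexpr.connectivity(_frame(A), labels)
        assert conn["k"].iloc[0] == pytest.approx((m - 1) * c)
        assert conn["k"].iloc[1] == pytest.approx(c)
        assert (conn["k_in"] <= conn["k"] + 1e-12).all()

    def test_kin_bounded_by_k_on_modules(self):
        expr, _ = module_dataset(seed=5, sizes=(40, 40), n_background=40, n_f2=150)
        le = expr.log_values()
        A = coexpr.adjacency(le, beta=2)
        mod = coexpr.detect_modules(coexpr.tom(A), A)
        assert (mod.connectivity["k_in"] <= mod.connectivity["k"] + 1e-12).all()

    def test_top_edges_ranking_and_ties(self):
        corr = _frame(
            np.array(
                [
                    [1.0, 0.9, -0.9, 0.2],
                    [0.9, 1.0, 0.5, 0.1],
                    [-0.9, 0.5, 1.0, 0.3],
                    [0.2, 0.1, 0.3, 1.0],
                ]
            )
        )
        edges = coexpr.top_edges(corr, corr.index, n=2)
        # |r| = 0.9 tie -> lexicographic (g0,g1) before (g0,g2)
        assert list(zip(edges["gene_a"], edges["gene_b"])) == [("g0", "g1"), ("g0", "g2")]


def test_hub_gene_is_module_driver():
    """The gene with the highest factor loading ranks in the top decile of
    intramodular connectivity."""
    rng = np.random.default_rng(12)
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        n, m = 200, 50
        shares = rng.uniform(0.2, 0.45, size=m)
        driver = 7
        shares[driver] = 0.65  # the planted driver loads distinctly higher
        loadings = np.sqrt(shares)
        f = rng.normal(size=n)
        X = f[:, None] * loadings[None, :] + rng.normal(size=(n, m)) * np.sqrt(1 - shares)
        expr = pd.DataFrame(X, columns=[f"g{i:02d}" for i in range(m)])
        A = coexpr.adjacency(expr, beta=2)
        labels = pd.Series(1, index=expr.columns)
        conn = coexpr.connectivity(A, labels)
        rank = conn["k_in"].rank(ascending=False)[f"g{driver:02d}"]
        wins += rank <= np.ceil(0.1 * m)
    assert wins >= int(0.9 * n_rep)
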