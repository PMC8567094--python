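"""Weighted co-expression network: adjacency, TOM, modules, eigengenes.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft-thresholding power beta chosen by the scale-free topology criterion.
The adjacency is transformed into a topological overlap matrix (TOM),
modules are cut from average-linkage hierarchical clustering of 1 - TOM
(static height cut plus a minimum size, small clusters fall into the
unassigned label 0), each module is summarised by its eigengene (first
principal component of the z-scored member submatrix) and related to
traits by Pearson correlation at the threshold 1/(N_modules x N_traits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def correlation_matrix(expr: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Gene-gene Pearson correlations, pairwise-complete when needed.

    Pairs with fewer than ``min_n`` joint observations get correlation 0
    (no evidence of co-expression). Constant genes are rejected.
    """
    X = expr.to_numpy(dtype=float)
    const = np.nanstd(X, axis=0) == 0
    if const.any():
        raise ValueError(f"constant genes: {list(expr.columns[const])}")
    if not np.isnan(X).any():
        R = np.corrcoef(X, rowvar=False)
    else:
        R = pd.DataFrame(X).corr(min_periods=min_n).to_numpy()
        counts = (~np.isnan(X)).astype(float)
        n_pair = counts.T @ counts
        R[np.isnan(R) | (n_pair < min_n)] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=expr.columns, columns=expr.columns)


def adjacency(expr: pd.DataFrame, beta: float, corr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Unsigned weighted adjacency |r|^beta."""
    R = correlation_matrix(expr) if corr is None else corr
    A = np.abs(R.to_numpy()) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=R.index, columns=R.columns)


def _connectivity(A: np.ndarray) -> np.ndarray:
    """Whole-network connectivity: row sums of adjacency with diag zeroed."""
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    return B.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Scale-free topology index of a connectivity distribution.

    Bins log10 k into ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean k per bin) and returns (R2, slope).
    A positive slope contradicts scale-free behaviour, so the reported
    index is 0 in that case (the sign-penalized convention).
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept, r, _, _ = stats.linregress(xs, ys)
    r2 = r**2 if slope < 0 else 0.0
    return float(r2), float(slope)


def soft_threshold_scan(
    expr: pd.DataFrame,
    betas=range(1, 21),
    target_r2: float = 0.85,
):
    """Scan soft powers; choose the smallest beta reaching the target R2.

    Returns (table, chosen_beta, reached) where ``table`` has one row per
    beta with the scale-free R2, slope and mean connectivity. If no beta
    reaches ``target_r2`` the argmax-R2 beta is returned with
    ``reached=False`` (fallback path).
    """
    if expr.shape[1] < 50:
        raise ValueError("need at least 50 genes for a soft-threshold scan")
    R = correlation_matrix(expr)
    rows = []
    for beta in betas:
        A = np.abs(R.to_numpy()) ** beta
        k = _connectivity(A)
        r2, slope = scale_free_fit(k)
        rows.append({"beta": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= target_r2]
    if len(ok):
        return table, int(ok.iloc[0]["beta"]), True
    return table, int(table.loc[table["r2"].idxmax(), "beta"]), False


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with u running over all other nodes, and TOM_ii = 1. The
    min-denominator variant is pinned by a brute-force oracle in the
    tests.
    """
    a = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # L_ij = sum_u a_iu a_uj, includes u = i, j with a_ii = 0
    num = L + a
    kmin = np.minimum.outer(k, k)
    den = kmin + 1.0 - a
    T = num / den
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(np.clip(T, 0.0, 1.0), index=A.index, columns=A.columns)


@dataclass
class ModuleAssignment:
    """Gene -> module label (0 = unassigned) plus connectivity measures."""

    labels: pd.Series
    sizes: pd.Series
    connectivity: pd.DataFrame  # columns k, k_in

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def detect_modules(
    T: pd.DataFrame,
    A: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.95,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` become label 0; surviving modules
    are renumbered 1, 2, ... by decreasing size (ties by smallest member
    index, for determinism).
    """
    genes = T.index
    D = 1.0 - T.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(len(genes), dtype=int)
    clusters = []
    for lab in np.unique(raw):
        members = np.where(raw == lab)[0]
        if members.size >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-m.size, m.min()))
    for new, members in enumerate(clusters, start=1):
        labels[members] = new
    label_s = pd.Series(labels, index=genes, name="module")
    sizes = label_s[label_s > 0].value_counts().sort_index()
    conn = connectivity(A, label_s)
    return ModuleAssignment(labels=label_s, sizes=sizes, connectivity=conn)


def connectivity(A: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene whole-network (k) and intramodular (k_in) connectivity."""
    a = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    lab = labels.reindex(A.index).to_numpy()
    same = lab[:, None] == lab[None, :]
    same &= lab[:, None] > 0
    k_in = (a * same).sum(axis=1)
    return pd.DataFrame({"k": k, "k_in": k_in}, index=A.index)


def hub_genes(assignment: ModuleAssignment, module: int, top_fraction: float = 0.1) -> pd.Index:
    """Top decile of intramodular connectivity within one module."""
    genes = assignment.genes_in(module)
    kin = assignment.connectivity.loc[genes, "k_in"].sort_values(ascending=False)
    n_top = max(1, int(np.ceil(top_fraction * len(genes))))
    return kin.index[:n_top]


@dataclass
class Eigengene:
    module: int
    scores: pd.Series
    variance_explained: float


def module_eigengene(expr: pd.DataFrame, genes) -> Eigengene:
    """First principal component of the z-scored module submatrix.

    The sign is aligned so that the eigengene's mean correlation with the
    member genes is non-negative.
    """
    genes = pd.Index(genes)
    if len(genes) < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    X = expr[genes].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("degenerate (constant) gene in module")
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0] / np.sqrt(Z.shape[0])
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_corr = np.mean([np.corrcoef(scores, Z[:, j])[0, 1] for j in range(Z.shape[1])])
    if mean_corr < 0:
        scores = -scores
    return Eigengene(
        module=0,
        scores=pd.Series(scores, index=expr.index),
        variance_explained=var_explained,
    )


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """Eigengene score matrix, samples x modules (columns ``ME<k>``)."""
    out = {}
    for module in assignment.sizes.index:
        eg = module_eigengene(expr, assignment.genes_in(module))
        out[f"ME{module}"] = eg.scores
    return pd.DataFrame(out, index=expr.index)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float | None = None,
):
    """Pearson r and p per (module, trait) plus a significance flag.

    The default threshold is the reciprocal-product rule
    alpha = 1 / (N_modules x N_traits); pass ``alpha`` to override (e.g.
    a conventional 0.05 Bonferroni).
    """
    shared = eigengenes.index.intersection(traits.index)
    E = eigengenes.loc[shared]
    Tm = traits.loc[shared]
    n_mod, n_trait = E.shape[1], Tm.shape[1]
    if alpha is None:
        alpha = 1.0 / (n_mod * n_trait)
    rows = []
    for me in E.columns:
        for trait in Tm.columns:
            pair = pd.concat([E[me], Tm[trait]], axis=1).dropna()
            n = len(pair)
            if n < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"module": me, "trait": trait, "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    return df, alpha


def top_edges(
    corr: pd.DataFrame,
    genes,
    n: int = 150,
    A: pd.DataFrame | None = None,
    T: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Strongest within-module gene pairs ranked by |r|.

    Ties break lexicographically on (gene_a, gene_b) with gene_a < gene_b.
    Adjacency and TOM values are attached when supplied.
    """
    genes = sorted(pd.Index(genes))
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            rows.append((ga, gb, float(corr.loc[ga, gb])))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["abs_r", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort")
    df = df.head(n).drop(columns="abs_r").reset_index(drop=True)
    if A is not None:
        df["a"] = [float(A.loc[a, b]) for a, b in zip(df["gene_a"], df["gene_b"])]
    if T is not None:
        df["tom"] = [float(T.loc[a, b]) for a, b in zip(df["gene_a"], df["gene_b"])]
    return df
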