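"""Shared fixture builders for the test suite.

Scenario builders return fully simulated datasets with planted truth;
sizes are desk-scale but preserve the statistical structure the pipeline
assumes (divergent founder lines, F2 linkage disequilibrium, kinship).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import triadqtl as tq
from triadqtl.mixedmodel import compute_grm
from triadqtl.pipeline import adjust_matrix, run_pipeline

#: Pig-like genome for association benchmarks: 18 autosomes x 128 Mb at
#: 1 cM/Mb (~2,300 cM), ~5,000 markers total. Mb-scale localization
#: behaviour (cis windows, QTL regions) depends on total map length, so
#: these benchmarks use the organism's recombination content rather than
#: the compressed 5-chromosome desk genome.
PIG_GENOME = dict(n_chrom=18, n_snps_per_chrom=278, chrom_length_bp=128_000_000)

#: Small genome for fast structural tests.
SMALL_GENOME = dict(n_chrom=2, n_snps_per_chrom=100, chrom_length_bp=100_000_000)


def pick_informative(genotypes, chrom: int, index: int, min_maf: float = 0.3) -> str:
    """The ``index``-th informative SNP on a chromosome."""
    good = tq.informative_snps(genotypes, min_maf=min_maf)
    on_chrom = [s for s in good if s.startswith(f"snp_c{chrom}_")]
    return on_chrom[index]


def spread_informative(genotypes, n: int, min_maf: float = 0.3) -> list:
    """``n`` informative SNPs spread evenly across the genome."""
    good = tq.informative_snps(genotypes, min_maf=min_maf)
    return list(good[np.linspace(0, len(good) - 1, n).astype(int)])


def planted_cis_dataset(seed: int, n_cis: int = 50, var_share: float = 0.10,
                        n_f2: int = 500, trans_hub_targets: int = 10,
                        trans_share: float = 0.15, genome: dict | None = None):
    """Dataset with ``n_cis`` cis-eQTLs plus one trans hub.

    Returns (genotypes-F2, expression, truth, planted_cis list, hub snp).
    """
    genome = dict(genome or PIG_GENOME)
    base = dict(n_f2=n_f2, n_transcripts=n_cis + trans_hub_targets + 1, **genome)
    g0 = tq.simulate_genotypes(tq.SimConfig(seed=seed, **base))
    chosen = spread_informative(g0, n_cis + 1)
    hub = chosen[n_cis // 2]
    cis_snps = [s for s in chosen if s != hub]
    planted_cis = [(f"tx{i + 1:05d}", s, var_share) for i, s in enumerate(cis_snps)]
    planted_trans = [
        (f"tx{i + n_cis + 2:05d}", hub, trans_share) for i in range(trans_hub_targets)
    ]
    cfg = tq.SimConfig(seed=seed, **base, planted_cis=planted_cis, planted_trans=planted_trans)
    g = tq.simulate_genotypes(cfg)
    e, truth = tq.simulate_expression(g, cfg)
    return g.subset(samples=g.f2_samples()), e, truth, planted_cis, hub


def triad_replicate(seed: int, n_f2: int = 400):
    """One mediation-vs-decoy replicate for the triad integration benchmark.

    A mediator transcript with a strong cis-eQTL drives the trait
    (expression mediation); a decoy transcript has an equally strong
    cis-eQTL on another chromosome but no trait effect. Returns the
    ranked candidate table plus the mediator/decoy transcript IDs.
    """
    base = dict(n_f2=n_f2, n_chrom=5, n_snps_per_chrom=30, n_transcripts=30)
    g0 = tq.simulate_genotypes(tq.SimConfig(seed=seed, **base))
    s_med = pick_informative(g0, 1, 7)
    s_decoy = pick_informative(g0, 3, 7)
    cfg = tq.SimConfig(
        seed=seed,
        **base,
        planted_cis=[("tx00010", s_med, 0.5), ("tx00020", s_decoy, 0.5)],
        trait_spec=[tq.TraitSpec(name="dripEZ", mediators=[("tx00010", 0.6)])],
    )
    g, e, t, truth = tq.simulate_dataset(cfg)
    res = run_pipeline(g, e, t, trait_names=["dripEZ"])
    return res.candidates, "tx00010", "tx00020"


def module_dataset(seed: int, sizes=(40, 50, 60, 70, 80), factor_share: float = 0.4,
                   n_background: int = 100, n_f2: int = 200):
    """Expression with planted co-expression modules plus background genes."""
    cfg = tq.SimConfig(
        seed=seed,
        n_f2=n_f2,
        **SMALL_GENOME,
        n_transcripts=sum(sizes) + n_background,
        module_spec=[(s, factor_share) for s in sizes],
    )
    g, e, truth = tq.simulate_genotypes(cfg), None, None
    e, truth = tq.simulate_expression(g, cfg)
    return e, truth


def exact_corr_expression(R0: np.ndarray, n: int, rng) -> np.ndarray:
    """Samples x genes matrix whose sample correlation matrix is exactly R0.

    Orthonormalizes Gaussian noise against the intercept, then colours it
    with the Cholesky factor of R0; useful for feeding a designed network
    topology to the soft-threshold scan without sampling noise.
    """
    m = R0.shape[0]
    G = rng.normal(size=(n, m + 1))
    G[:, 0] = 1.0
    Q, _ = np.linalg.qr(G)
    Q = Q[:, 1:]
    L = np.linalg.cholesky(R0 + 1e-10 * np.eye(m))
    return Q @ L.T


def scale_free_expression(m: int, n: int, seed: int, lmin: float = 0.15,
                          lmax: float = 0.95, tail: float = 1.5) -> pd.DataFrame:
    """Expression whose correlation network has an exact power-law
    connectivity distribution (single-factor loadings with truncated
    Pareto magnitudes)."""
    rng = np.random.default_rng(seed)
    u = rng.random(m)
    loadings = (lmin**-tail - u * (lmin**-tail - lmax**-tail)) ** (-1 / tail)
    R0 = np.outer(loadings, loadings)
    np.fill_diagonal(R0, 1.0)
    X = exact_corr_expression(R0, n, rng)
    return pd.DataFrame(X, columns=[f"g{i:04d}" for i in range(m)])


def adjusted_for(genotypes, values: pd.DataFrame, K=None):
    """Residualize a matrix and return (adjusted, vectors dict, K)."""
    if K is None:
        K = compute_grm(genotypes)
    adj, vecs, _ = adjust_matrix(values, genotypes, K=K)
    return adj, vecs, K


def brute_force_tom(A: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned TOM oracle (min denominator)."""
    a = A.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    m = a.shape[0]
    k = a.sum(axis=1)
    T = np.ones((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            shared = 0.0
            for u in range(m):
                if u != i and u != j:
                    shared += a[i, u] * a[u, j]
            T[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return T
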