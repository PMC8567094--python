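"""End-to-end orchestration: adjust -> scans -> QTT -> network -> triads.

The adjustment stage is shared by every downstream analysis: each trait
and each (log-TPM) transcript is residualized for sex, batch and kinship
with one polygenic REML fit, and the resulting
:class:`~triadqtl.mixedmodel.AdjustedVector` feeds both the score-test
scans and the correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coexpr, integrate, qtt, scan
from .containers import ExpressionMatrix, GenotypeMatrix, TraitTable
from .mixedmodel import KinshipMatrix, build_design, compute_grm, fit_polygenic


def adjust_matrix(
    values: pd.DataFrame,
    genotypes: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    mode: str = "gls",
):
    """Residualize every column of ``values`` for sex, batch and kinship.

    Returns (adjusted DataFrame, dict of AdjustedVector, DataFrame of
    variance components). Columns that are constant or fail to fit are
    skipped. The kinship eigendecomposition is shared across columns with
    complete data.
    """
    samples = values.index
    geno = genotypes.subset(samples=samples.intersection(genotypes.samples))
    if K is None:
        K = compute_grm(geno)
    X = build_design(geno.sex, geno.batch)
    eigvals, U = np.linalg.eigh(K.values)
    eig = (np.clip(eigvals, 0.0, None), U)
    adjusted = {}
    vectors = {}
    vcs = []
    for col in values.columns:
        y = values[col]
        try:
            vc, adj = fit_polygenic(y, X, K, mode=mode, label=str(col), _eig=eig)
        except ValueError:
            continue
        adjusted[col] = adj.residuals
        vectors[col] = adj
        vcs.append({"label": col, "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e, "h2": vc.h2})
    return pd.DataFrame(adjusted), vectors, pd.DataFrame(vcs)


@dataclass
class PipelineResult:
    qtt_records: pd.DataFrame
    eqtl_records: pd.DataFrame
    gwas_peaks: pd.DataFrame
    candidates: pd.DataFrame
    modules: object = None
    module_trait: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    traits: TraitTable,
    trait_names=None,
    transcripts=None,
    qtt_alpha: float = qtt.DEFAULT_QTT_ALPHA,
    eqtl_alpha: float = scan.DEFAULT_EQTL_ALPHA,
    suggestive_p: float = integrate.DEFAULT_SUGGESTIVE_P,
    run_network: bool = False,
    network_beta: int = 2,
) -> PipelineResult:
    """Run adjustment, GWAS, eQTL, QTT and triad integration.

    ``trait_names`` / ``transcripts`` restrict the analysed columns
    (defaults: every trait, every transcript). The co-expression branch
    is optional because it scales quadratically in gene count.
    """
    f2 = genotypes.f2_samples()
    geno = genotypes.subset(samples=f2.intersection(expr.samples))
    K = compute_grm(geno)

    trait_values = traits.values[list(trait_names)] if trait_names else traits.values
    trait_values = trait_values.reindex(geno.samples)
    log_expr = expr.log_values().reindex(geno.samples)
    if transcripts is not None:
        log_expr = log_expr[list(transcripts)]

    traits_adj, trait_vecs, _ = adjust_matrix(trait_values, geno, K=K)
    expr_adj, expr_vecs, _ = adjust_matrix(log_expr, geno, K=K)

    # GWAS per trait -> per-chromosome peaks
    gwas_records = pd.concat(
        [scan.scan(vec, geno) for vec in trait_vecs.values()], ignore_index=True
    )
    gwas_peaks = scan.peaks_per_chromosome(gwas_records)

    # eQTL per transcript -> significant classified peaks
    eqtl_records_all = pd.concat(
        [scan.scan(vec, geno) for vec in expr_vecs.values()], ignore_index=True
    )
    eqtls = scan.significant_eqtls(eqtl_records_all, expr.annotation, alpha=eqtl_alpha)

    qtt_records = qtt.qtt_scan(
        expr_adj, traits_adj, alpha=qtt_alpha, tissue="muscle", annotation=expr.annotation
    )

    candidates = integrate.triad_analysis(
        gwas_peaks,
        qtt_records,
        eqtls,
        expr.annotation,
        geno.chrom_lengths(),
        suggestive_p=suggestive_p,
    )

    modules = None
    module_trait = pd.DataFrame()
    if run_network:
        A = coexpr.adjacency(expr_adj, beta=network_beta)
        T = coexpr.tom(A)
        modules = coexpr.detect_modules(T, A)
        if len(modules.sizes):
            egenes = coexpr.module_eigengenes(expr_adj, modules)
            module_trait, _ = coexpr.module_trait_correlation(egenes, traits_adj)

    return PipelineResult(
        qtt_records=qtt_records,
        eqtl_records=eqtls,
        gwas_peaks=gwas_peaks,
        candidates=candidates,
        modules=modules,
        module_trait=module_trait,
    )
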