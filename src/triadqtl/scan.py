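"""Genome scans, peak calling, cis/trans classification, hotspot summaries.

GWAS on traits and eQTL mapping on transcripts share one engine: each
adjusted vector is tested against every SNP with the kinship-aware score
test from :mod:`triadqtl.mixedmodel`. A transcript's strongest association
is its eQTL peak; a peak within 2.5 Mb upstream of the transcription
start site to 2.5 Mb downstream of the gene end is classified cis, any
other peak trans. The 2.5 Mb window reflects the distance over which
linkage disequilibrium decays in a divergent-line F2 cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .mixedmodel import AdjustedVector, scan_vector

#: Default eQTL significance threshold (Bonferroni-style, kept configurable).
DEFAULT_EQTL_ALPHA = 2.08e-5

#: cis window: distance from TSS (upstream) / gene end (downstream), bp.
CIS_WINDOW_BP = 2_500_000


def scan(adjusted: AdjustedVector, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Score-test one adjusted vector against all testable SNPs.

    Returns one row per polymorphic SNP with columns ``target, snp,
    chrom, pos, chi2, p, effect_sign``, ordered by (chrom, pos).
    Monomorphic SNPs are omitted.
    """
    shared = adjusted.samples.intersection(genotypes.samples)
    if len(shared) == 0:
        raise ValueError("adjusted vector and genotypes share no samples")
    res = scan_vector(adjusted, genotypes.dosages.loc[shared])
    res = res[~res["p"].isna()].copy()
    snp_map = genotypes.snp_map
    res["chrom"] = snp_map.loc[res["snp"], "chrom"].to_numpy()
    res["pos"] = snp_map.loc[res["snp"], "pos"].to_numpy()
    res["target"] = adjusted.label
    res = res.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return res[["target", "snp", "chrom", "pos", "chi2", "p", "effect_sign"]]


def peak_per_target(records: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide peak per target: min p, ties broken by (chrom, pos)."""
    ordered = records.sort_values(["p", "chrom", "pos"], kind="mergesort")
    return ordered.groupby("target", sort=True).head(1).reset_index(drop=True)


def peaks_per_chromosome(records: pd.DataFrame) -> pd.DataFrame:
    """Per-target, per-chromosome peak rows (supports multi-QTL traits)."""
    ordered = records.sort_values(["p", "pos"], kind="mergesort")
    return (
        ordered.groupby(["target", "chrom"], sort=True)
        .head(1)
        .sort_values(["target", "chrom"], kind="mergesort")
        .reset_index(drop=True)
    )


def significant_eqtls(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = DEFAULT_EQTL_ALPHA,
) -> pd.DataFrame:
    """Per-transcript peak eQTLs below ``alpha``, classified cis/trans.

    ``records`` is the concatenated scan output over transcripts (the
    ``target`` column holds the transcript ID). Unannotated transcripts
    are excluded from classification (and from the output) with a log of
    their count. Columns: transcript, gene, snp, chrom, pos, p, chi2,
    effect_sign, cis_trans.
    """
    peaks = peak_per_target(records)
    peaks = peaks[peaks["p"] < alpha].copy()
    peaks = peaks.rename(columns={"target": "transcript"})
    ann = annotation.set_index("transcript") if annotation.index.name != "transcript" else annotation
    known = peaks["transcript"].isin(ann.index)
    peaks = peaks[known].copy()
    peaks["gene"] = ann.loc[peaks["transcript"], "gene"].to_numpy()
    peaks["cis_trans"] = [
        classify_cis_trans(row["chrom"], row["pos"], ann.loc[row["transcript"]])
        for _, row in peaks.iterrows()
    ]
    return peaks.reset_index(drop=True)


def classify_cis_trans(snp_chrom, snp_pos, tx_annotation) -> str:
    """cis iff same chromosome and within [start - 2.5 Mb, end + 2.5 Mb].

    The window runs from 2.5 Mb upstream of the TSS to 2.5 Mb downstream
    of the gene end; because the TSS is the start coordinate on the +
    strand and the end coordinate on the - strand, the genomic interval
    is strand-independent. Boundaries inclusive, 1-based coordinates.
    """
    if snp_chrom != tx_annotation["chrom"]:
        return "trans"
    lo = tx_annotation["start"] - CIS_WINDOW_BP
    hi = tx_annotation["end"] + CIS_WINDOW_BP
    return "cis" if lo <= snp_pos <= hi else "trans"


@dataclass
class PleiotropySummary:
    """Distinct-gene counts per eSNP and the derived hotspot table."""

    counts: pd.DataFrame  # snp, chrom, pos, cis_trans, n_genes
    hotspots: pd.DataFrame  # subset with n_genes >= 2


def pleiotropy_summary(eqtls: pd.DataFrame, min_genes: int = 2) -> PleiotropySummary:
    """Count distinct genes per eSNP, split by cis/trans.

    An eSNP associated with >= ``min_genes`` genes (default 2) is a
    hotspot candidate; counts conserve the number of (gene, eSNP) pairs.
    """
    if eqtls.empty:
        empty = pd.DataFrame(columns=["snp", "chrom", "pos", "cis_trans", "n_genes"])
        return PleiotropySummary(counts=empty, hotspots=empty.copy())
    counts = (
        eqtls.groupby(["snp", "chrom", "pos", "cis_trans"])["gene"]
        .nunique()
        .reset_index()
        .rename(columns={"gene": "n_genes"})
        .sort_values(["chrom", "pos", "cis_trans"], kind="mergesort")
        .reset_index(drop=True)
    )
    hotspots = counts[counts["n_genes"] >= min_genes].reset_index(drop=True)
    return PleiotropySummary(counts=counts, hotspots=hotspots)
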