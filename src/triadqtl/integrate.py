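"""Triad integration: GWAS regions x cis-eQTLs x QTTs -> candidate genes.

A QTL region is the +/- 2.5 Mb window around a retained GWAS peak.
Candidate transcripts are significant QTTs for the region's trait whose
gene overlaps the region; a candidate is accepted when it also has a
significant cis-eQTL whose peak SNP either *is* the GWAS peak SNP
(tier ``shared-peak``, the strongest evidence pattern) or at least lies
inside the region (tier ``region-overlap``). Sign consistency of the
triad (QTT r x eQTL effect x GWAS effect) is annotated: under pure
expression mediation the product of the three signs is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_HALF_WIDTH_BP = 2_500_000
DEFAULT_SUGGESTIVE_P = 1e-4


@dataclass
class QtlRegion:
    trait: str
    chrom: int
    start: int
    end: int
    peak_snp: str
    peak_p: float
    peak_sign: int = 0


@dataclass
class TriadCandidate:
    trait: str
    transcript: str
    gene: str
    region: QtlRegion
    gwas_snp: str
    gwas_p: float
    eqtl_snp: str
    eqtl_p: float
    qtt_r: float
    qtt_p: float
    tier: str  # "shared-peak" | "region-overlap"
    sign_consistent: bool


def define_qtl_regions(
    gwas_peaks: pd.DataFrame,
    chrom_lengths: dict,
    half_width: int = REGION_HALF_WIDTH_BP,
    suggestive_p: float = DEFAULT_SUGGESTIVE_P,
) -> list:
    """QTL regions around retained GWAS peaks.

    ``gwas_peaks`` holds per-chromosome peak rows (columns ``target, snp,
    chrom, pos, p, effect_sign``); peaks with p >= ``suggestive_p`` are
    dropped. Windows are clamped to [1, chromosome length] and
    overlapping same-trait regions are merged (the stronger peak wins).
    """
    peaks = gwas_peaks[gwas_peaks["p"] < suggestive_p]
    regions: list[QtlRegion] = []
    for (trait, chrom), grp in peaks.groupby(["target", "chrom"], sort=True):
        chrom_len = int(chrom_lengths.get(chrom, np.iinfo(np.int64).max))
        open_regions: list[QtlRegion] = []
        for _, row in grp.sort_values("pos", kind="mergesort").iterrows():
            start = max(1, int(row["pos"]) - half_width)
            end = min(chrom_len, int(row["pos"]) + half_width)
            if open_regions and start <= open_regions[-1].end:
                prev = open_regions[-1]
                prev.end = max(prev.end, end)
                if row["p"] < prev.peak_p:
                    prev.peak_snp = row["snp"]
                    prev.peak_p = float(row["p"])
                    prev.peak_sign = int(row["effect_sign"])
            else:
                open_regions.append(
                    QtlRegion(
                        trait=trait,
                        chrom=int(chrom),
                        start=start,
                        end=end,
                        peak_snp=row["snp"],
                        peak_p=float(row["p"]),
                        peak_sign=int(row["effect_sign"]),
                    )
                )
        regions.extend(open_regions)
    return regions


def screen_qtts_in_region(
    region: QtlRegion,
    qtt_records: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Significant QTTs for the region's trait whose gene overlaps it.

    Overlap is any-overlap: a gene straddling the boundary is included.
    """
    ann = annotation.set_index("transcript") if annotation.index.name != "transcript" else annotation
    sig = qtt_records[(qtt_records["significant"]) & (qtt_records["trait"] == region.trait)]
    sig = sig[sig["transcript"].isin(ann.index)]
    if sig.empty:
        return sig
    tx = ann.loc[sig["transcript"]]
    inside = (
        (tx["chrom"].to_numpy() == region.chrom)
        & (tx["end"].to_numpy() >= region.start)
        & (tx["start"].to_numpy() <= region.end)
    )
    return sig[inside].reset_index(drop=True)


def colocalize(
    region: QtlRegion,
    candidate: pd.Series,
    eqtl_records: pd.DataFrame,
):
    """Attempt the triad for one in-region QTT; returns TriadCandidate or
    (None, reason).

    Requires a significant cis-eQTL for the candidate transcript; tier
    ``shared-peak`` when its peak eSNP is exactly the GWAS peak SNP,
    ``region-overlap`` when the eSNP lies inside the region, otherwise
    rejection.
    """
    hits = eqtl_records[
        (eqtl_records["transcript"] == candidate["transcript"])
        & (eqtl_records["cis_trans"] == "cis")
    ]
    if hits.empty:
        return None, "no significant cis-eQTL"
    e = hits.iloc[0]
    if e["snp"] == region.peak_snp:
        tier = "shared-peak"
    elif e["chrom"] == region.chrom and region.start <= e["pos"] <= region.end:
        tier = "region-overlap"
    else:
        return None, "cis-eQTL peak outside QTL region"
    product = np.sign(candidate["r"]) * e["effect_sign"] * region.peak_sign
    return (
        TriadCandidate(
            trait=region.trait,
            transcript=candidate["transcript"],
            gene=candidate.get("gene", candidate["transcript"]),
            region=region,
            gwas_snp=region.peak_snp,
            gwas_p=region.peak_p,
            eqtl_snp=e["snp"],
            eqtl_p=float(e["p"]),
            qtt_r=float(candidate["r"]),
            qtt_p=float(candidate["p"]),
            tier=tier,
            sign_consistent=bool(product > 0),
        ),
        None,
    )


def rank_candidates(triads: list) -> pd.DataFrame:
    """Headline table: shared-peak first, then cis-eQTL p, then |QTT r|."""
    columns = [
        "rank", "trait", "transcript", "gene", "chrom", "region_start",
        "region_end", "gwas_snp", "gwas_p", "eqtl_snp", "eqtl_p",
        "qtt_r", "qtt_p", "tier", "sign_consistent",
    ]
    if not triads:
        return pd.DataFrame(columns=columns)
    tier_order = {"shared-peak": 0, "region-overlap": 1}
    rows = sorted(
        triads,
        key=lambda t: (tier_order[t.tier], t.eqtl_p, -abs(t.qtt_r), t.trait, t.transcript),
    )
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "trait": t.trait,
                "transcript": t.transcript,
                "gene": t.gene,
                "chrom": t.region.chrom,
                "region_start": t.region.start,
                "region_end": t.region.end,
                "gwas_snp": t.gwas_snp,
                "gwas_p": t.gwas_p,
                "eqtl_snp": t.eqtl_snp,
                "eqtl_p": t.eqtl_p,
                "qtt_r": t.qtt_r,
                "qtt_p": t.qtt_p,
                "tier": t.tier,
                "sign_consistent": t.sign_consistent,
            }
            for i, t in enumerate(rows)
        ],
        columns=columns,
    )


def triad_analysis(
    gwas_peaks: pd.DataFrame,
    qtt_records: pd.DataFrame,
    eqtl_records: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_lengths: dict,
    suggestive_p: float = DEFAULT_SUGGESTIVE_P,
) -> pd.DataFrame:
    """Full integration: regions -> in-region QTTs -> colocalization -> ranking."""
    regions = define_qtl_regions(gwas_peaks, chrom_lengths, suggestive_p=suggestive_p)
    triads = []
    for region in regions:
        screened = screen_qtts_in_region(region, qtt_records, annotation)
        for _, cand in screened.iterrows():
            triad, _ = colocalize(region, cand, eqtl_records)
            if triad is not None:
                triads.append(triad)
    return rank_candidates(triads)
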