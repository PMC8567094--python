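"""SNP and sample quality control, and tag-count to TPM normalization.

Default thresholds follow common 60K-chip practice for an F2 cross: a SNP
passes with call rate >= 0.9, MAF >= 0.05 and Hardy-Weinberg chi-square
p >= 1e-5; a sample passes with call rate >= 0.9 and trio Mendelian error
rate <= 0.05. Boundaries are inclusive on the pass side, matching removal
rules phrased as strict inequalities. HWE uses the one-degree-of-freedom
chi-square of observed vs expected genotype counts under the estimated
allele frequency (adequate at hundreds of samples and exactly
oracle-checkable); it is applied to all F2 samples even though a cross
segregates non-randomly at the family level - a documented caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    snp_call_rate: float = 0.9
    maf: float = 0.05
    hwe_p: float = 1e-5
    sample_call_rate: float = 0.9
    mendel_rate: float = 0.05


def hwe_chisq_p(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """1-df chi-square HWE test from genotype counts.

    Returns 1.0 for a monomorphic marker (no test possible).
    """
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 1.0
    p_alt = (2 * n_alt_hom + n_het) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2])
    obs = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-SNP call rate, MAF and HWE report with a pass flag.

    MAF is computed from non-missing dosages; a monomorphic SNP gets
    MAF 0 and HWE p 1 and fails the MAF filter.
    """
    th = thresholds or QcThresholds()
    dos = genotypes.dosages.to_numpy(dtype=float)
    n_samples = dos.shape[0]
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    call_rate = n_called / n_samples
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(dos, axis=0) / (2 * np.maximum(n_called, 1))
    p_alt[n_called == 0] = np.nan
    maf = np.minimum(p_alt, 1 - p_alt)
    maf = np.where(np.isnan(maf), 0.0, maf)

    n_alt_hom = np.nansum(dos == 2, axis=0)
    n_het = np.nansum(dos == 1, axis=0)
    n_ref_hom = np.nansum(dos == 0, axis=0)
    hwe = np.array(
        [hwe_chisq_p(int(a), int(b), int(c)) for a, b, c in zip(n_ref_hom, n_het, n_alt_hom)]
    )
    report = pd.DataFrame(
        {
            "snp": genotypes.snps,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe,
        }
    ).set_index("snp", drop=False)
    report["pass"] = (
        (report["call_rate"] >= th.snp_call_rate)
        & (report["maf"] >= th.maf)
        & (report["hwe_p"] >= th.hwe_p)
    )
    return report


def mendel_error_rate(child: pd.Series, sire: pd.Series, dam: pd.Series) -> float:
    """Fraction of complete-trio SNPs with an impossible transmission.

    A configuration is impossible when the child carries an allele count
    no combination of one transmitted allele per parent can produce
    (e.g. child 2 from 0 x 0). Returns NaN when no SNP has all three
    genotypes called; such samples are exempt from the Mendel filter.
    """
    c = child.to_numpy(dtype=float)
    s = sire.reindex(child.index).to_numpy(dtype=float)
    d = dam.reindex(child.index).to_numpy(dtype=float)
    complete = ~(np.isnan(c) | np.isnan(s) | np.isnan(d))
    if not complete.any():
        return float("nan")
    c, s, d = c[complete], s[complete], d[complete]
    # transmissible alt-allele counts per parent: hom -> {0} or {1}, het -> {0,1}
    s_min = (s == 2).astype(float)
    d_min = (d == 2).astype(float)
    s_max = (s >= 1).astype(float)
    d_max = (d >= 1).astype(float)
    errors = (c < s_min + d_min) | (c > s_max + d_max)
    return float(errors.mean())


def sample_qc(genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-sample call rate and (where a complete trio exists) Mendel rate."""
    th = thresholds or QcThresholds()
    dos = genotypes.dosages
    call_rate = dos.notna().mean(axis=1)
    rates = {}
    ped = genotypes.pedigree
    for sample in dos.index:
        rate = float("nan")
        if not ped.empty and sample in ped.index:
            sire = ped.loc[sample, "sire"]
            dam = ped.loc[sample, "dam"]
            if sire in dos.index and dam in dos.index:
                rate = mendel_error_rate(dos.loc[sample], dos.loc[sire], dos.loc[dam])
        rates[sample] = rate
    report = pd.DataFrame(
        {
            "sample": dos.index,
            "call_rate": call_rate.to_numpy(),
            "mendel_error_rate": [rates[s] for s in dos.index],
        }
    ).set_index("sample", drop=False)
    mendel_ok = report["mendel_error_rate"].isna() | (report["mendel_error_rate"] <= th.mendel_rate)
    n_exempt = int(report["mendel_error_rate"].isna().sum())
    if n_exempt:
        logger.info("%d samples without a complete trio exempt from the Mendel filter", n_exempt)
    report["pass"] = (report["call_rate"] >= th.sample_call_rate) & mendel_ok
    return report


def tpm_normalize(tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Tags-per-million: count / sample total * 1e6, rows = samples.

    This is the tag-count flavour of TPM (per million clean tags), with no
    transcript-length term. Raises on a sample with zero total counts.
    """
    counts = tag_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative tag counts")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValueError(f"samples with zero total counts: {list(tag_counts.index[zero])}")
    return pd.DataFrame(
        counts / totals[:, None] * 1e6, index=tag_counts.index, columns=tag_counts.columns
    )


def filter_expression(expr: ExpressionMatrix, min_expressed_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep transcripts with TPM > 0 in at least the given sample fraction."""
    frac = (expr.values > 0).mean(axis=0)
    keep = frac >= min_expressed_fraction
    ann = expr.annotation
    if not ann.empty:
        ann = ann.loc[ann.index.intersection(expr.values.columns[keep])]
    return ExpressionMatrix(values=expr.values.loc[:, keep], annotation=ann)


def filter_dataset(
    genotypes: GenotypeMatrix,
    snp_report: pd.DataFrame,
    sample_report: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Submatrix of passing SNPs x passing samples, with removal logging."""
    keep_snps = snp_report.index[snp_report["pass"]]
    if sample_report is not None:
        keep_samples = genotypes.samples.intersection(sample_report.index[sample_report["pass"]])
    else:
        keep_samples = genotypes.samples
    n_snp_removed = genotypes.n_snps - len(keep_snps)
    n_sample_removed = genotypes.n_samples - len(keep_samples)
    logger.info("QC removed %d SNPs and %d samples", n_snp_removed, n_sample_removed)
    if len(keep_snps) == 0 or len(keep_samples) == 0:
        raise ValueError("quality control removed every SNP or every sample")
    return genotypes.subset(samples=keep_samples, snps=keep_snps)
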