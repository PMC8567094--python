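"""Quantitative trait transcript (QTT) scanning.

A QTT is a transcript whose (adjusted) expression correlates with an
(adjusted) trait at Pearson p < 5e-4, two-sided from the t distribution
with n-2 degrees of freedom. Correlations are pairwise-complete; the
scan runs over every transcript x trait pair and downstream summaries
count multi-trait QTTs, tissue-shared QTTs and per-trait-group tallies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_QTT_ALPHA = 5e-4


def _pairwise_corr(E: np.ndarray, t: np.ndarray):
    """Pairwise-complete Pearson r of each column of E with vector t.

    Returns (r, n) arrays; columns with a constant support or too little
    overlap come back NaN.
    """
    me = ~np.isnan(E)
    mt = ~np.isnan(t)
    m = me & mt[:, None]
    Ez = np.where(m, np.nan_to_num(E), 0.0)
    tz = np.where(mt, np.nan_to_num(t), 0.0)
    n = m.sum(axis=0).astype(float)
    sx = Ez.sum(axis=0)
    sxx = (Ez**2).sum(axis=0)
    st = tz @ m
    stt = (tz**2) @ m
    sxt = tz @ Ez
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxt / n - (sx / n) * (st / n)
        vx = sxx / n - (sx / n) ** 2
        vt = stt / n - (st / n) ** 2
        r = cov / np.sqrt(vx * vt)
    r = np.where((vx <= 0) | (vt <= 0), np.nan, r)
    return np.clip(r, -1.0, 1.0), n


def qtt_scan(
    expr_adjusted: pd.DataFrame,
    traits_adjusted: pd.DataFrame,
    alpha: float = DEFAULT_QTT_ALPHA,
    tissue: str = "",
    min_n: int = 10,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlate every transcript with every trait.

    Both inputs are samples x columns matrices of residualized values on
    a shared (or overlapping) sample index. Returns one row per testable
    pair: transcript, gene, tissue, trait, r, p, n, significant. Pairs
    with fewer than ``min_n`` complete observations or a constant vector
    are skipped.
    """
    shared = expr_adjusted.index.intersection(traits_adjusted.index)
    if len(shared) < min_n:
        raise ValueError("fewer shared samples than min_n")
    E = expr_adjusted.loc[shared].to_numpy(dtype=float)
    gene_of = None
    if annotation is not None and not annotation.empty:
        ann = annotation.set_index("transcript") if annotation.index.name != "transcript" else annotation
        gene_of = ann["gene"]
    frames = []
    for trait in traits_adjusted.columns:
        t = traits_adjusted.loc[shared, trait].to_numpy(dtype=float)
        r, n = _pairwise_corr(E, t)
        ok = (~np.isnan(r)) & (n >= min_n)
        dfree = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = r * np.sqrt(dfree / (1.0 - r**2))
            p = 2.0 * stats.t.sf(np.abs(tstat), dfree)
            p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
        df = pd.DataFrame(
            {
                "transcript": expr_adjusted.columns[ok],
                "trait": trait,
                "r": r[ok],
                "p": p[ok],
                "n": n[ok].astype(int),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["tissue"] = tissue
    out["gene"] = (
        gene_of.reindex(out["transcript"]).to_numpy() if gene_of is not None else out["transcript"]
    )
    out["significant"] = out["p"] < alpha
    return out[["transcript", "gene", "tissue", "trait", "r", "p", "n", "significant"]]


def multi_trait_qtts(records: pd.DataFrame) -> pd.DataFrame:
    """Transcripts significantly associated with >= 2 distinct traits."""
    sig = records[records["significant"]]
    counts = sig.groupby("transcript")["trait"].nunique()
    multi = counts[counts >= 2].sort_index()
    return multi.rename("n_traits").reset_index()


def shared_qtts(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """(transcript, trait) pairs significant in both tissues.

    Each row carries both tissues' r and p plus a sign-agreement flag;
    tissue-discordant signs do occur and are reported, not dropped.
    """
    a = records_a[records_a["significant"]].set_index(["transcript", "trait"])
    b = records_b[records_b["significant"]].set_index(["transcript", "trait"])
    common = a.index.intersection(b.index)
    rows = []
    for key in sorted(common):
        ra, rb = a.loc[key], b.loc[key]
        rows.append(
            {
                "transcript": key[0],
                "trait": key[1],
                "gene": ra["gene"],
                "tissue_a": ra["tissue"],
                "r_a": ra["r"],
                "p_a": ra["p"],
                "tissue_b": rb["tissue"],
                "r_b": rb["r"],
                "p_b": rb["p"],
                "sign_agree": bool(np.sign(ra["r"]) == np.sign(rb["r"])),
            }
        )
    cols = [
        "transcript", "trait", "gene",
        "tissue_a", "r_a", "p_a", "tissue_b", "r_b", "p_b", "sign_agree",
    ]
    return pd.DataFrame(rows, columns=cols)


def trait_group_counts(records: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Distinct significant QTTs per trait group (and tissue).

    ``groups`` maps trait name -> group label; every trait appearing in a
    significant record must be mapped. A transcript significant for two
    traits of one group counts once in that group.
    """
    sig = records[records["significant"]]
    unmapped = set(sig["trait"]) - set(groups)
    if unmapped:
        raise ValueError(f"traits without a group mapping: {sorted(unmapped)}")
    sig = sig.assign(group=sig["trait"].map(groups))
    counts = (
        sig.groupby(["tissue", "group"])["transcript"]
        .nunique()
        .rename("n_qtts")
        .reset_index()
        .sort_values(["tissue", "group"], kind="mergesort")
        .reset_index(drop=True)
    )
    return counts
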