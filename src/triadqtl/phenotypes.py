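"""Derived meat-quality traits and descriptive statistics.

Glycolytic potential (GP) summarises the glycolytic substrate available
in muscle at slaughter and predicts postmortem pH decline:

    GP = 2 * (glucose + glycogen + glucose-6-phosphate) + lactate   [umol/g]

Residual glycogen (RG) is glucose + glycogen, so equivalently
GP = 2 * (RG + G6P) + lactate. pH drops are simple differences between an
earlier and a later postmortem pH reading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TraitTable


def _check_nonnegative(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError(f"{name} contains negative concentrations")


def derive_gp(glucose, glycogen, g6p, lactate):
    """Glycolytic potential, 2*(glucose + glycogen + G6P) + lactate (umol/g).

    Accepts scalars or aligned vectors; a missing component propagates to
    a missing GP. Negative concentrations are rejected.
    """
    for name, v in [("glucose", glucose), ("glycogen", glycogen), ("g6p", g6p), ("lactate", lactate)]:
        _check_nonnegative(name, v)
    return 2.0 * (np.asarray(glucose, dtype=float) + np.asarray(glycogen, dtype=float) + np.asarray(g6p, dtype=float)) + np.asarray(lactate, dtype=float)


def derive_rg(glucose, glycogen):
    """Residual glycogen: glucose + glycogen (umol/g)."""
    _check_nonnegative("glucose", glucose)
    _check_nonnegative("glycogen", glycogen)
    return np.asarray(glucose, dtype=float) + np.asarray(glycogen, dtype=float)


def derive_ph_drop(ph_early, ph_late):
    """pH decline between two postmortem time points (early minus late).

    Not clamped at zero: a slightly negative drop is biologically possible
    and kept as measured.
    """
    return np.asarray(ph_early, dtype=float) - np.asarray(ph_late, dtype=float)


def descriptive_stats(values) -> dict:
    """n, mean, sample SD (n-1 denominator) and CV% of a trait vector.

    CV is undefined (NaN) for a zero mean; requires >= 2 non-missing
    values.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 2:
        raise ValueError("descriptive statistics need at least 2 non-missing values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return {"n": int(v.size), "mean": mean, "sd": sd, "cv": cv}


def derive_all(traits: TraitTable) -> TraitTable:
    """Add derivable columns (RG, GP, pH drops) where components exist."""
    df = traits.values.copy()
    if {"glucose", "glycogen"} <= set(df.columns):
        df["RG"] = derive_rg(df["glucose"], df["glycogen"])
        if {"g6p", "lactate"} <= set(df.columns):
            df["GP"] = derive_gp(df["glucose"], df["glycogen"], df["g6p"], df["lactate"])
    for early, late, name in [
        ("pH45min", "pH3h", "pHdrop_45min_3h"),
        ("pH45min", "pH24h", "pHdrop_45min_24h"),
    ]:
        if {early, late} <= set(df.columns):
            df[name] = derive_ph_drop(df[early], df[late])
    return TraitTable(values=df)


def trait_correlations(traits: TraitTable, min_n: int = 3):
    """Pairwise-complete Pearson correlations among all traits.

    Returns three aligned DataFrames (r, p, n). p is two-sided from the
    t distribution with n-2 degrees of freedom; pairs with fewer than
    ``min_n`` complete observations are reported missing. Pairwise (not
    listwise) deletion is used because per-trait sample sizes can differ
    substantially.
    """
    df = traits.values
    cols = df.columns
    X = df.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    n_pair = mask.T.astype(float) @ mask.astype(float)
    s1 = Xz.T @ mask.astype(float)  # sum of x over joint support
    s2 = (Xz**2).T @ mask.astype(float)
    cross = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = s1 / n_pair
        cov = cross / n_pair - mean_x * mean_x.T
        var_x = s2 / n_pair - mean_x**2
        denom = np.sqrt(var_x * var_x.T)
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    low = n_pair < min_n
    r[low] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        dfree = n_pair - 2
        t = r * np.sqrt(dfree / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), dfree)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[low] = np.nan
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return mk(r), mk(p), mk(n_pair.astype(int))
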