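"""Simplified negative-binomial differential expression.

A two-level NB contrast in the spirit of the standard Bioconductor workflow:
median-of-ratios size factors, method-of-moments dispersion pooled within
design levels, per-gene Wald test on the log fold change between the two
levels, Benjamini-Hochberg adjustment, and DEG calling at FDR < 0.01 with a
twofold (|log2FC| >= 1) expression-change cutoff.  No fold-change shrinkage
is applied; thresholds act on the maximum-likelihood log2FC.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

__all__ = [
    "size_factors_median_of_ratios",
    "normalized_counts",
    "estimate_dispersion",
    "nb_wald_contrast",
    "call_degs",
    "bh_adjust",
    "venn_overlaps",
]

ALPHA_MIN = 1e-8


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio of counts to per-gene geometric means.

    Genes with a zero count in any sample are excluded from the reference set
    (their log geometric mean is -inf).
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = c.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(arr[usable])
    log_geo = logs.mean(axis=1)
    log_ratios = logs - log_geo[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=c.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    return c / size_factors


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series | None = None,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene NB dispersion alpha by method of moments on normalized counts.

    alpha = max(alpha_min, (s^2 - mean) / mean^2), with the sample variance
    pooled within design levels (df-weighted) when ``groups`` is given, so a
    real group difference is not mistaken for dispersion.  Genes with zero
    mean get alpha_min.
    """
    norm = normalized_counts(counts, size_factors)
    arr = norm.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    if groups is None:
        var = arr.var(axis=1, ddof=1)
    else:
        groups = pd.Series(groups).reindex(norm.columns)
        ss = np.zeros(arr.shape[0])
        df = 0
        for _, idx in groups.groupby(groups).groups.items():
            cols = [norm.columns.get_loc(s) for s in idx]
            if len(cols) < 2:
                continue
            sub = arr[:, cols]
            ss += sub.var(axis=1, ddof=1) * (len(cols) - 1)
            df += len(cols) - 1
        if df == 0:
            raise ValueError("need >= 2 samples in at least one level")
        var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, alpha_min)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=norm.index, name="dispersion")


def nb_wald_contrast(
    counts: CountMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str,
    contrast: tuple[str, str],
    fdr: float = 0.01,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Two-level NB Wald contrast (level B vs level A).

    Samples whose ``factor`` level is missing/empty or outside the contrast
    are dropped.  The per-gene group mean of size-factor-normalized counts is
    the NB maximum-likelihood mean; the Wald statistic for
    log(mu_B / mu_A) uses the delta-method variance (1/n^2) sum(mu/s_j +
    alpha mu^2) per group.  Genes with all-zero counts in both levels are
    reported with ``tested = False``.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    if factor not in metadata.columns:
        raise ValueError(f"factor {factor!r} not in metadata")
    a_level, b_level = contrast
    levels = metadata[factor].astype(str)
    keep = levels.isin([a_level, b_level]) & (levels != "")
    samples = metadata.index[keep]
    if not set(samples).issubset(c.columns):
        raise ValueError("metadata samples missing from count matrix")
    sub = c[list(samples)]
    lv = levels.loc[samples]
    n_a, n_b = (lv == a_level).sum(), (lv == b_level).sum()
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per contrast level")

    sf = size_factors_median_of_ratios(sub)
    alpha = estimate_dispersion(sub, sf, groups=lv)
    norm = normalized_counts(sub, sf).to_numpy(dtype=float)
    mask_a = (lv == a_level).to_numpy()
    mask_b = (lv == b_level).to_numpy()
    s = sf.to_numpy()

    tested = sub.to_numpy().sum(axis=1) > 0
    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # half-count continuity only when a group mean is exactly zero, so a gene
    # expressed in one level gets a finite log2FC; identical groups stay at 0
    mu_a = np.where(mean_a > 0, mean_a, 0.5 / n_a)
    mu_b = np.where(mean_b > 0, mean_b, 0.5 / n_b)

    al = alpha.to_numpy()
    inv_s_a = (1.0 / s[mask_a]).sum()
    inv_s_b = (1.0 / s[mask_b]).sum()
    var_a = (mu_a * inv_s_a + al * mu_a**2 * n_a) / n_a**2
    var_b = (mu_b * inv_s_b + al * mu_b**2 * n_b) / n_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_a / mu_a**2 + var_b / mu_b**2)
        log2fc = np.log2(mu_b / mu_a)
        wald = np.log(mu_b / mu_a) / se
    pvalues = 2 * stats.norm.sf(np.abs(wald))
    pvalues = np.where(np.isfinite(wald), pvalues, np.nan)
    # exact-zero contrast: identical group means -> z = 0, p = 1
    pvalues = np.where(np.isclose(mu_a, mu_b) & tested, 1.0, pvalues)
    wald = np.where(np.isclose(mu_a, mu_b) & tested, 0.0, wald)
    log2fc = np.where(np.isclose(mu_a, mu_b), 0.0, log2fc)

    padj = np.full_like(pvalues, np.nan)
    ok = tested & np.isfinite(pvalues)
    if ok.any():
        padj[ok] = bh_adjust(pvalues[ok])

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "wald_stat": wald,
            "pvalue": np.where(tested, pvalues, np.nan),
            "padj": np.where(tested, padj, np.nan),
            "tested": tested,
        },
        index=sub.index,
    )
    up, down = call_degs(res, fdr=fdr, fold=fold)
    call = np.full(len(res), "null", dtype=object)
    call[res.index.isin(up)] = "up"
    call[res.index.isin(down)] = "down"
    res["call"] = call
    return res


def call_degs(result: pd.DataFrame, fdr: float = 0.01, fold: float = 2.0):
    """DEG sets: FDR below cutoff AND at least ``fold``-change (inclusive)."""
    if fold < 1:
        raise ValueError("fold cutoff must be >= 1")
    if "padj" not in result.columns:
        raise ValueError("result has no FDR (padj) column")
    lfc_cut = np.log2(fold)
    sig = result["padj"] < fdr
    up = set(result.index[sig & (result["log2fc"] >= lfc_cut)])
    down = set(result.index[sig & (result["log2fc"] <= -lfc_cut)])
    return up, down


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def venn_overlaps(named_sets: dict[str, set]) -> dict:
    """Exact Venn regions for 2 or 3 named DEG sets.

    Returns ``regions`` mapping each nonempty combination of set names
    (a sorted tuple) to the genes exclusive to exactly that combination,
    plus ``counts`` with the region cardinalities.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    if len(names) > 3:
        raise ValueError("Venn overlap supports at most 3 sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    regions = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[tuple(sorted(combo))] = inside - outside
    counts = {k: len(v) for k, v in regions.items()}
    return {"regions": regions, "counts": counts}
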