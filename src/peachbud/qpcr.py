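"""qPCR normalization, RNA-seq validation, return bloom and letter displays.

Mean normalized expression (MNE) follows the standard two-reference-gene
scheme: relative quantity RQ = E^(-Ct) per well, technical replicates
averaged on the RQ scale, and the target RQ divided by the geometric mean of
the reference-gene RQs.  Return bloom is each block's mean flower-covered
area as a percentage of the untreated control, and multiple-comparison
results are summarized as compact letter displays (groups sharing a letter
are not significantly different).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .network import pearson

__all__ = [
    "normalize_qpcr",
    "validate_vs_rnaseq",
    "return_bloom_percent",
    "ap1_bloom_correlation",
    "tukey_letters",
]


def normalize_qpcr(
    table: pd.DataFrame,
    target: str,
    reference_genes: tuple[str, ...] | list[str],
) -> pd.Series:
    """Mean normalized expression of ``target`` per sample (arbitrary units).

    ``table`` is a long-format well table with columns ``sample_id``,
    ``gene``, ``ct`` and optionally ``efficiency`` (default 2.0 per gene).
    MNE = mean RQ of the target / geometric mean of the reference RQs, which
    makes the result invariant to a global per-sample Ct shift.
    """
    if len(reference_genes) < 2:
        raise ValueError("need at least 2 reference genes")
    req = {"sample_id", "gene", "ct"}
    if not req.issubset(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(req)}")
    tab = table.copy()
    if "efficiency" not in tab.columns:
        tab["efficiency"] = 2.0
    if (tab["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    eff = tab["efficiency"].astype(float)
    if ((eff <= 1) | (eff > 2)).any():
        raise ValueError("amplification efficiency must lie in (1, 2]")
    tab["rq"] = eff ** (-tab["ct"].astype(float))
    # technical replicates averaged on the RQ scale
    rq = tab.groupby(["sample_id", "gene"])["rq"].mean().unstack("gene")
    for gene in (target, *reference_genes):
        if gene not in rq.columns:
            raise ValueError(f"gene {gene!r} not measured in any sample")
        missing = rq.index[rq[gene].isna()]
        if len(missing):
            raise ValueError(f"gene {gene!r} missing in sample {missing[0]!r}")
    nf = np.exp(np.log(rq[list(reference_genes)]).mean(axis=1))
    return (rq[target] / nf).rename(f"MNE_{target}")


def validate_vs_rnaseq(
    qpcr_values: pd.DataFrame, rnaseq_values: pd.DataFrame
) -> pd.Series:
    """Per-gene Pearson r between qPCR MNE and RNA-seq expression.

    Both inputs are gene x condition tables over >= 3 matched conditions
    (typically per-timepoint means).  Genes present in both tables are
    correlated; constant profiles yield NaN.
    """
    common_genes = qpcr_values.index.intersection(rnaseq_values.index)
    common_cond = qpcr_values.columns.intersection(rnaseq_values.columns)
    if len(common_cond) < 3:
        raise ValueError("need >= 3 matched conditions")
    out = {}
    for g in common_genes:
        r = pearson(
            qpcr_values.loc[g, common_cond].to_numpy(dtype=float),
            rnaseq_values.loc[g, common_cond].to_numpy(dtype=float),
        )
        out[g] = np.nan if r is None else r
    return pd.Series(out, name="pearson_r")


def return_bloom_percent(bloom: pd.DataFrame, utc_label: str = "UTC") -> pd.Series:
    """Per-block mean flower area as a percentage of the untreated control."""
    req = {"block", "flower_area"}
    if not req.issubset(bloom.columns):
        raise ValueError(f"bloom table needs columns {sorted(req)}")
    if (bloom["flower_area"] < 0).any():
        raise ValueError("flower areas must be >= 0")
    means = bloom.groupby("block")["flower_area"].mean()
    if utc_label not in means.index:
        raise ValueError(f"no {utc_label!r} block present")
    utc = means[utc_label]
    if utc == 0:
        raise ValueError("UTC mean area is zero")
    return (100.0 * means / utc).rename("percent_of_utc")


def ap1_bloom_correlation(ap1_by_block: pd.Series, bloom_by_block: pd.Series) -> float:
    """Pearson r between block-level marker expression and return bloom."""
    common = ap1_by_block.index.intersection(bloom_by_block.index)
    if len(common) < 3:
        raise ValueError("need >= 3 blocks")
    r = pearson(
        ap1_by_block[common].to_numpy(dtype=float),
        bloom_by_block[common].to_numpy(dtype=float),
    )
    if r is None:
        raise ValueError("correlation undefined: constant input")
    return r


def _compact_letters(groups: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered (by descending mean); every significantly
    different pair must share no letter and every other pair must share at
    least one.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in significant:
            continue
        for ls in list(letter_sets):
            if a in ls and b in ls:
                letter_sets.remove(ls)
                la, lb = ls - {b}, ls - {a}
                letter_sets.extend([la, lb])
        # absorb letter sets fully contained in another
        letter_sets = [
            ls
            for ls in letter_sets
            if not any(ls < other for other in letter_sets)
        ]
        # deduplicate while keeping order
        seen, unique = [], []
        for ls in letter_sets:
            if ls not in seen:
                seen.append(ls)
                unique.append(ls)
        letter_sets = unique
    # assign letters in group order for a deterministic display
    letter_sets.sort(key=lambda ls: min(groups.index(g) for g in ls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in groups}
    for i, ls in enumerate(letter_sets):
        for g in groups:
            if g in ls:
                out[g].append(alphabet[i % len(alphabet)])
    return {g: "".join(v) for g, v in out.items()}


def tukey_letters(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> pd.Series:
    """Compact letter display from one-way ANOVA + all-pairs Tukey HSD.

    Groups are lettered in order of descending mean; groups that are not
    significantly different at ``alpha`` share at least one letter.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).reindex(values.index).astype(str)
    level_vals = {g: values[groups == g].to_numpy() for g in groups.unique()}
    if len(level_vals) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in level_vals.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    order = sorted(level_vals, key=lambda g: (-level_vals[g].mean(), g))
    arrays = [level_vals[g] for g in order]
    pooled_var = np.concatenate([v - v.mean() for v in arrays]).var(ddof=len(arrays))
    significant: set[frozenset] = set()
    if pooled_var == 0:
        # zero within-group variance: any mean difference is significant in
        # the limit; identical means share everything
        for a, b in itertools.combinations(order, 2):
            if not math.isclose(level_vals[a].mean(), level_vals[b].mean()):
                significant.add(frozenset((a, b)))
    else:
        res = stats.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(len(order)), 2):
            if res.pvalue[i, j] < alpha:
                significant.add(frozenset((order[i], order[j])))
    letters = _compact_letters(order, significant)
    return pd.Series({g: letters[g] for g in order}, name="letters")
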