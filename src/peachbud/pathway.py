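"""Gene-set activity scanning and over-representation analysis.

Two complementary functional views: a parametric per-sample gene-set
activity score (one-sample z of standardized log expression, tested across
sample groups by one-way ANOVA; pathway significance at FDR <= 0.05), and a
classical hypergeometric over-representation test of a DEG list against a
gene universe with BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "pgsea_activity",
    "pgsea_significance",
    "hypergeom_enrichment",
]


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"duplicate gene-set ID {name!r}")
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            sets[name] = (desc, frozenset(members))
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def pgsea_activity(
    log_expr: pd.DataFrame,
    sets: dict[str, tuple[str, frozenset]],
    min_size: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample gene-set activity on standardized log expression.

    Each gene is z-scored across samples (constant genes are dropped); the
    activity of set S in sample j is mean(z_gj, g in S) * sqrt(|S|), the
    one-sample z form, so coordinated shifts in large sets score higher.
    Sets with fewer than ``min_size`` genes present are skipped and listed.

    Returns (activity sets x samples, skipped set names).
    """
    X = log_expr.to_numpy(dtype=float)
    sd = X.std(axis=1)  # population sd: z is an exact per-gene standardization
    keep = sd > 0
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zdf = pd.DataFrame(Z, index=log_expr.index[keep], columns=log_expr.columns)
    rows, names, skipped = [], [], []
    for name, (_, members) in sets.items():
        present = zdf.index.intersection(sorted(members))
        if len(present) < min_size:
            skipped.append(name)
            continue
        sub = zdf.loc[present]
        rows.append(sub.mean(axis=0).to_numpy() * np.sqrt(len(present)))
        names.append(name)
    activity = pd.DataFrame(rows, index=names, columns=log_expr.columns)
    return activity, skipped


def pgsea_significance(
    activity: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-set one-way ANOVA of activity across sample groups, BH over sets.

    A set is flagged when its adjusted p is at or below ``fdr``, i.e. the
    pathway as a whole shows a group-supported expression trend.
    """
    groups = pd.Series(groups).reindex(activity.columns)
    if groups.isna().any():
        raise ValueError("every activity sample needs a group label")
    level_cols = {g: np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()}
    if len(level_cols) < 2:
        raise ValueError("need >= 2 groups")
    for g, cols in level_cols.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has a single sample")
    F = np.empty(len(activity))
    p = np.empty(len(activity))
    A = activity.to_numpy(dtype=float)
    for i in range(len(activity)):
        samples = [A[i, cols] for cols in level_cols.values()]
        if np.ptp(A[i]) == 0:  # identical activity everywhere: no trend
            F[i], p[i] = 0.0, 1.0
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F[i], p[i] = stats.f_oneway(*samples)
        if not np.isfinite(p[i]):
            # zero within-group variance with distinct means: limit p -> 0
            p[i] = 0.0 if np.isinf(F[i]) else 1.0
            F[i] = F[i] if np.isfinite(F[i]) else 0.0
    padj = bh_adjust(p)
    return pd.DataFrame(
        {"F": F, "pvalue": p, "padj": padj, "significant": padj <= fdr},
        index=activity.index,
    )


def hypergeom_enrichment(
    query,
    universe,
    sets: dict[str, tuple[str, frozenset]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` per term.

    ``query`` must be a subset of ``universe``; set members outside the
    universe are ignored.  Terms with zero overlap are reported with p = NaN
    and excluded from BH correction.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} not in universe")
    M, N = len(universe), len(query)
    rows = []
    for name, (desc, members) in sets.items():
        in_univ = members & universe
        k = len(in_univ & query)
        n = len(in_univ)
        if k > 0:
            p = float(stats.hypergeom.sf(k - 1, M, n, N))
        else:
            p = np.nan
        rows.append((name, desc, n, k, p))
    res = pd.DataFrame(
        rows, columns=["term", "description", "set_size", "overlap", "pvalue"]
    ).set_index("term")
    res["padj"] = np.nan
    tested = res["pvalue"].notna()
    if tested.any():
        res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "pvalue"].to_numpy())
    return res
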