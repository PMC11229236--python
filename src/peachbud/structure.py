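"""Sample-structure analyses: variable genes, clustering, PCA, ordering.

Works on log-expression matrices (genes x samples).  PCA is computed on the
sample x gene matrix after per-gene centering, with a deterministic sign
convention (each component's largest-magnitude loading is positive).  PC1,
when associated with sampling time, serves as a one-dimensional
developmental axis on which position x timepoint groups are ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "top_variable_genes",
    "ClusteringResult",
    "hierarchical_clusters",
    "PcaResult",
    "pca",
    "pc_factor_association",
    "developmental_ordering",
]


def top_variable_genes(log_expr: pd.DataFrame, n: int = 2000) -> pd.Index:
    """The ``n`` genes of highest variance across samples (ties by gene ID)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = log_expr.var(axis=1, ddof=1)
    order = sorted(log_expr.index, key=lambda g: (-var[g], g))
    return pd.Index(order[: min(n, len(order))])


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix over samples
    labels: pd.Series  # flat cluster label per sample at the requested k
    samples: pd.Index


def hierarchical_clusters(
    log_expr: pd.DataFrame, k: int, method: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering of samples at distance 1 - Pearson.

    Samples with zero variance have undefined correlation and are rejected
    by name.  The flat labels cut the dendrogram into ``k`` clusters.
    """
    if log_expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = log_expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = log_expr.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(
        Z, pd.Series(flat, index=log_expr.columns, name="cluster"), log_expr.columns
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PC1..PCk
    variance_fractions: np.ndarray  # all components, non-increasing, sums to 1
    loadings: pd.DataFrame  # genes x PC1..PCk

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def pca(log_expr: pd.DataFrame, k: int = 2) -> PcaResult:
    """PCA of samples in gene space (per-gene centering, SVD).

    Sign convention: each component's largest-magnitude gene loading is made
    positive, so results are reproducible across SVD implementations.
    """
    n_samples, n_genes = log_expr.shape[1], log_expr.shape[0]
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if k > min(n_samples, n_genes):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(n_samples, n_genes)}")
    X = log_expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation
    for i in range(len(S)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = (S**2).sum()
    fractions = (S**2) / total if total > 0 else np.zeros_like(S)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U * S)[:, :k], index=log_expr.columns, columns=cols)
    loadings = pd.DataFrame(Vt[:k].T, index=log_expr.index, columns=cols)
    return PcaResult(scores, fractions, loadings)


def pc_factor_association(
    result: PcaResult, metadata: pd.DataFrame, factor: str
) -> pd.Series:
    """One-way ANOVA p-value of each PC's scores across factor levels."""
    levels = metadata.loc[result.scores.index, factor].astype(str)
    groups = levels.groupby(levels).groups
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"level {g!r} has fewer than 2 samples")
    out = {}
    for pc in result.scores.columns:
        vals = [result.scores.loc[idx, pc].to_numpy() for idx in groups.values()]
        if np.ptp(result.scores[pc].to_numpy()) == 0:
            out[pc] = 1.0
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F, p = stats.f_oneway(*vals)
        if not np.isfinite(p):
            p = 0.0 if np.isinf(F) else 1.0
        out[pc] = float(p)
    return pd.Series(out, name=factor)


def developmental_ordering(
    result: PcaResult,
    metadata: pd.DataFrame,
    time_factor: str = "timepoint",
    position_factor: str = "position",
    anchor: str = "T5",
) -> pd.DataFrame:
    """Mean PC1 coordinate per position x timepoint group, as a developmental axis.

    Orientation is fixed by requiring the ``anchor`` (latest) timepoint groups
    to carry the largest coordinates, so a global sign flip of PC1 never
    changes the reported ordering.  Groups are returned in increasing order.
    """
    md = metadata.loc[result.scores.index]
    pc1 = result.scores["PC1"]
    key = md[position_factor].astype(str) + "_" + md[time_factor].astype(str)
    means = pc1.groupby(key).mean()
    if means.isna().any():
        raise ValueError("empty position x timepoint group")
    anchor_groups = [g for g in means.index if g.endswith("_" + anchor)]
    if anchor_groups and means[anchor_groups].mean() < means.mean():
        means = -means
    out = means.sort_values().rename("pc1_coordinate").to_frame()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
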