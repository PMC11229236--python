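"""Hormone-gene correlative network and its minimum spanning forest.

The procedure: average basal-bud log expression and hormone concentrations
per timepoint; connect each gene to each hormone whose profile it tracks
with |Pearson r| strictly above a threshold (default 0.90), keeping the sign
(direct vs inverse correlation); reduce the resulting bipartite graph to a
minimum spanning forest with Prim's algorithm on edge weight 1 - |r|; read
off per-hormone subnetworks, node eccentricities, and hormone-hormone
synergism/antagonism calls from the sign pairs of bridging genes (genes
joined to two or more hormones in the forest).

The graph machinery (Prim, BFS eccentricity, bipartite bookkeeping) is
implemented natively and checked in the test suite against independent
graph-library oracles.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "timepoint_means",
    "pearson",
    "CorrelationGraph",
    "build_graph",
    "SpanningForest",
    "prim_msf",
    "minimum_spanning_forest_edges",
    "eccentricity",
    "assign_subnetworks",
    "subnetwork_summary",
    "InteractionCall",
    "call_interactions",
    "write_graphml",
    "write_edge_list",
]


def timepoint_means(
    matrix: pd.DataFrame, timepoints: pd.Series, order: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Arithmetic mean of each row per timepoint, columns in timepoint order.

    ``timepoints`` maps column names of ``matrix`` to timepoint labels.
    """
    tp = pd.Series(timepoints).reindex(matrix.columns)
    if tp.isna().any():
        raise ValueError("every column needs a timepoint label")
    if order is None:
        order = tuple(dict.fromkeys(tp))
    missing = [t for t in order if t not in set(tp)]
    if missing:
        raise ValueError(f"timepoint {missing[0]!r} has no replicates")
    out = {t: matrix.loc[:, (tp == t).to_numpy()].mean(axis=1) for t in order}
    return pd.DataFrame(out)[list(order)]


def pearson(x, y) -> float | None:
    """Product-moment correlation; None when undefined (constant input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return None
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


@dataclass
class CorrelationGraph:
    """Bipartite hormone-gene graph with signed correlation edges.

    ``edges`` columns: gene, hormone, r (signed), weight (= 1 - |r|).
    Only genes with at least one retained edge appear in ``genes``.
    """

    hormones: list[str]
    genes: list[str]
    edges: pd.DataFrame
    threshold: float
    gene_mean_expression: pd.Series | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.hormones) + list(self.genes)

    def edge_sign(self, gene: str, hormone: str) -> int:
        sel = self.edges[(self.edges["gene"] == gene) & (self.edges["hormone"] == hormone)]
        if sel.empty:
            raise KeyError(f"no edge between {gene!r} and {hormone!r}")
        return 1 if float(sel["r"].iloc[0]) > 0 else -1


def build_graph(
    gene_means: pd.DataFrame,
    hormone_means: pd.DataFrame,
    threshold: float = 0.90,
    gene_mean_expression: pd.Series | None = None,
) -> CorrelationGraph:
    """Thresholded bipartite correlation graph over shared timepoints.

    An edge (gene, hormone) is retained iff |r| > threshold (strictly); r is
    stored signed, so direct and inverse correlations are distinguished.
    Genes with no retained edge are excluded.  Constant profiles have
    undefined correlation and simply contribute no edges.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if list(gene_means.columns) != list(hormone_means.columns):
        raise ValueError("gene and hormone profiles must share identical timepoints")
    G = gene_means.to_numpy(dtype=float)
    H = hormone_means.to_numpy(dtype=float)
    Gc = G - G.mean(axis=1, keepdims=True)
    Hc = H - H.mean(axis=1, keepdims=True)
    gnorm = np.sqrt((Gc**2).sum(axis=1))
    hnorm = np.sqrt((Hc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Gc @ Hc.T) / np.outer(gnorm, hnorm)
    R = np.clip(R, -1.0, 1.0)
    R[~np.isfinite(R)] = 0.0  # constant vectors: correlation undefined, no edge
    keep = np.abs(R) > threshold
    gi, hi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "gene": gene_means.index.to_numpy()[gi],
            "hormone": hormone_means.index.to_numpy()[hi],
            "r": R[gi, hi],
        }
    )
    edges["weight"] = 1.0 - edges["r"].abs()
    edges = edges.sort_values(["gene", "hormone"], kind="mergesort").reset_index(drop=True)
    genes = sorted(set(edges["gene"]))
    return CorrelationGraph(
        hormones=list(hormone_means.index),
        genes=genes,
        edges=edges,
        threshold=threshold,
        gene_mean_expression=gene_mean_expression,
    )


@dataclass
class SpanningForest:
    """Prim-reduced forest of a correlation graph."""

    edges: pd.DataFrame  # forest edges: gene, hormone, r, weight
    components: dict[str, int]  # node -> component id
    graph: CorrelationGraph = field(repr=False)

    @property
    def n_components(self) -> int:
        return len(set(self.components.values()))

    @property
    def nodes(self) -> list[str]:
        return list(self.components)

    def total_weight(self) -> float:
        return float(self.edges["weight"].sum())

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n: [] for n in self.components}
        for g, h in zip(self.edges["gene"], self.edges["hormone"]):
            adj[g].append(h)
            adj[h].append(g)
        return {n: sorted(v) for n, v in adj.items()}


def _adjacency_from_edges(nodes, edges: pd.DataFrame) -> dict[str, list[tuple]]:
    adj: dict[str, list[tuple]] = {n: [] for n in nodes}
    for g, h, r, w in zip(edges["gene"], edges["hormone"], edges["r"], edges["weight"]):
        adj[g].append((h, float(w), float(r)))
        adj[h].append((g, float(w), float(r)))
    for n in adj:
        adj[n].sort(key=lambda e: (e[1], e[0]))
    return adj


def minimum_spanning_forest_edges(nodes, edges: pd.DataFrame) -> list[tuple]:
    """Prim's algorithm with restarts per component; deterministic tie-break.

    Heap entries are ordered by (weight, lexicographic endpoint pair), so
    equal-weight ties resolve identically regardless of input node order.
    Returns a list of (gene, hormone, r, weight) forest edges.
    """
    adj = _adjacency_from_edges(nodes, edges)
    visited: set[str] = set()
    forest: list[tuple] = []
    gene_set = set(edges["gene"])
    for start in sorted(adj):
        if start in visited:
            continue
        visited.add(start)
        heap: list[tuple] = []
        for nb, w, r in adj[start]:
            heapq.heappush(heap, (w, *sorted((start, nb)), start, nb, r))
        while heap:
            w, _, _, u, v, r = heapq.heappop(heap)
            if v in visited:
                continue
            visited.add(v)
            # orient as (gene, hormone) for bipartite bookkeeping
            g, h = (u, v) if u in gene_set else (v, u)
            forest.append((g, h, r, w))
            for nb, w2, r2 in adj[v]:
                if nb not in visited:
                    heapq.heappush(heap, (w2, *sorted((v, nb)), v, nb, r2))
    return forest


def prim_msf(graph: CorrelationGraph) -> SpanningForest:
    """Minimum spanning forest of the thresholded correlation graph."""
    if len(graph.nodes) == 0:
        raise ValueError("graph is empty")
    forest_edges = minimum_spanning_forest_edges(graph.nodes, graph.edges)
    fdf = pd.DataFrame(forest_edges, columns=["gene", "hormone", "r", "weight"])
    # component labels by BFS over forest edges
    adj: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for g, h in zip(fdf["gene"], fdf["hormone"]):
        adj[g].append(h)
        adj[h].append(g)
    components: dict[str, int] = {}
    cid = 0
    for start in sorted(adj):
        if start in components:
            continue
        stack = [start]
        components[start] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in components:
                    components[v] = cid
                    stack.append(v)
        cid += 1
    return SpanningForest(edges=fdf, components=components, graph=graph)


def eccentricity(forest: SpanningForest) -> pd.Series:
    """Per-node eccentricity: max shortest-path edge count within its component."""
    adj = forest.adjacency()
    ecc = {}
    for source in adj:
        dist = {source: 0}
        frontier = [source]
        far = 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        far = max(far, dist[v])
                        nxt.append(v)
            frontier = nxt
        ecc[source] = far
    return pd.Series(ecc, name="eccentricity")


def assign_subnetworks(forest: SpanningForest) -> pd.DataFrame:
    """Per-gene hormone-subnetwork assignment from the forest.

    Edges are hormone-gene only, so every gene's forest neighbours are
    hormones: the nearest hormone is a direct neighbour.  Genes with two or
    more forest neighbours bridge distinct subnetworks; they get a primary
    assignment (lexicographically smallest hormone) and are flagged.  The
    correlation sign of the gene's edge to each hormone gives the
    direct/inverse accounting.

    Columns: gene, hormone (primary), sign, is_bridge, hormones (all forest
    neighbours, '|'-joined).
    """
    neighbours: dict[str, list[tuple[str, float]]] = {}
    for g, h, r in zip(forest.edges["gene"], forest.edges["hormone"], forest.edges["r"]):
        neighbours.setdefault(g, []).append((h, float(r)))
    rows = []
    for g in sorted(neighbours):
        hs = sorted(neighbours[g])
        primary, r = hs[0]
        rows.append(
            (
                g,
                primary,
                1 if r > 0 else -1,
                len(hs) > 1,
                "|".join(h for h, _ in hs),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "hormone", "sign", "is_bridge", "hormones"]
    ).set_index("gene")


def subnetwork_summary(
    forest: SpanningForest, count_bridges_in_all: bool = False
) -> pd.DataFrame:
    """Per-hormone subnetwork sizes with direct/inverse edge counts.

    With ``count_bridges_in_all`` False (primary mode) every gene is counted
    once, under its primary hormone, and sizes sum to the gene-node total;
    True reproduces the per-subnetwork accounting in which a bridging gene
    appears in every subnetwork it touches.
    """
    rows = []
    edges = forest.edges
    assign = assign_subnetworks(forest)
    for h in forest.graph.hormones:
        if count_bridges_in_all:
            sub = edges[edges["hormone"] == h]
            n = len(sub)
            direct = int((sub["r"] > 0).sum())
            inverse = int((sub["r"] < 0).sum())
        else:
            sub = assign[assign["hormone"] == h]
            n = len(sub)
            direct = int((sub["sign"] > 0).sum())
            inverse = int((sub["sign"] < 0).sum())
        rows.append((h, n, direct, inverse))
    return pd.DataFrame(
        rows, columns=["hormone", "n_genes", "n_direct", "n_inverse"]
    ).set_index("hormone")


@dataclass
class InteractionCall:
    """A hormone-pair relationship supported by bridging genes.

    Concordant sign pairs (both direct or both inverse) support synergism;
    discordant pairs support antagonism; a mixture yields 'mixed'.
    """

    hormone_a: str
    hormone_b: str
    verdict: str
    bridge_genes: list[str]
    sign_pairs: list[tuple[int, int]]


def call_interactions(forest: SpanningForest) -> list[InteractionCall]:
    """Synergism/antagonism calls for every hormone pair sharing a bridge gene.

    Bridge genes are identified in the forest (two or more forest edges); the
    sign pairs that support a verdict come from all of a bridge gene's
    retained correlation edges in the full thresholded graph, so two bridges
    can disagree and produce a 'mixed' verdict.
    """
    forest_degree = forest.edges["gene"].value_counts()
    bridges = set(forest_degree.index[forest_degree >= 2])
    edges = forest.graph.edges
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for g, h, r in zip(edges["gene"], edges["hormone"], edges["r"]):
        if g in bridges:
            by_gene.setdefault(g, []).append((h, float(r)))
    support: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    for g, hs in by_gene.items():
        hs = sorted(hs)
        for i in range(len(hs)):
            for j in range(i + 1, len(hs)):
                (ha, ra), (hb, rb) = hs[i], hs[j]
                sa, sb = (1 if ra > 0 else -1), (1 if rb > 0 else -1)
                support.setdefault((ha, hb), []).append((g, sa, sb))
    calls = []
    for (ha, hb), items in sorted(support.items()):
        concord = [sa * sb > 0 for _, sa, sb in items]
        if all(concord):
            verdict = "synergism"
        elif not any(concord):
            verdict = "antagonism"
        else:
            verdict = "mixed"
        calls.append(
            InteractionCall(
                ha,
                hb,
                verdict,
                [g for g, _, _ in items],
                [(sa, sb) for _, sa, sb in items],
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_edge_list(graph: CorrelationGraph, forest: SpanningForest, path) -> None:
    """Plain TSV edge list with an in_forest flag."""
    fset = set(zip(forest.edges["gene"], forest.edges["hormone"]))
    out = graph.edges.copy()
    out["sign"] = np.where(out["r"] > 0, "direct", "inverse")
    out["in_forest"] = [
        (g, h) in fset for g, h in zip(out["gene"], out["hormone"])
    ]
    out.to_csv(path, sep="\t", index=False)


def write_graphml(graph: CorrelationGraph, forest: SpanningForest, path) -> None:
    """GraphML export with node kind/subnetwork/eccentricity/mean expression
    and edge r/sign/weight/in_forest attributes."""
    ecc = eccentricity(forest)
    assign = assign_subnetworks(forest)
    fset = set(zip(forest.edges["gene"], forest.edges["hormone"]))

    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    keys = [
        ("kind", "node", "string"),
        ("subnetwork", "node", "string"),
        ("eccentricity", "node", "int"),
        ("mean_expression", "node", "double"),
        ("r", "edge", "double"),
        ("sign", "edge", "string"),
        ("weight", "edge", "double"),
        ("in_forest", "edge", "boolean"),
    ]
    for name, domain, typ in keys:
        ET.SubElement(
            root, "key", id=name, **{"for": domain, "attr.name": name, "attr.type": typ}
        )
    g_el = ET.SubElement(root, "graph", id="hormone_gene_network", edgedefault="undirected")

    def _data(parent, key, value):
        el = ET.SubElement(parent, "data", key=key)
        el.text = str(value)

    expr = graph.gene_mean_expression
    for node in graph.nodes:
        n_el = ET.SubElement(g_el, "node", id=node)
        is_h = node in graph.hormones
        _data(n_el, "kind", "hormone" if is_h else "gene")
        if not is_h and node in assign.index:
            _data(n_el, "subnetwork", assign.loc[node, "hormone"])
        elif is_h:
            _data(n_el, "subnetwork", node)
        if node in ecc.index:
            _data(n_el, "eccentricity", int(ecc[node]))
        if not is_h and expr is not None and node in expr.index:
            _data(n_el, "mean_expression", float(expr[node]))
    for i, row in graph.edges.iterrows():
        e_el = ET.SubElement(
            g_el, "edge", id=f"e{i}", source=str(row["gene"]), target=str(row["hormone"])
        )
        _data(e_el, "r", float(row["r"]))
        _data(e_el, "sign", "direct" if row["r"] > 0 else "inverse")
        _data(e_el, "weight", float(row["weight"]))
        _data(e_el, "in_forest", str((row["gene"], row["hormone"]) in fset).lower())
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
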