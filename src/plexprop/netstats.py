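"""Structural characterization of network layers.

Covers the per-layer summary statistics (coverage, density, global
clustering/transitivity, degree assortativity), a node-level decomposition of
assortativity (local assortativity, which sums over nodes to the global
value), the literature/annotation bias of a layer (rank correlation of degree
with an external per-gene count), and the edge-conservation profile across a
stack of layers.

Undefined statistics (e.g. assortativity of a regular graph) are reported as
NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .multiplex import Layer

__all__ = [
    "LayerSummary",
    "LocalAssortativityMap",
    "layer_summary",
    "local_assortativity",
    "annotation_bias",
    "edge_conservation_profile",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class LayerSummary:
    name: str
    n_nodes: int
    n_edges: int
    density: float
    clustering: float
    assortativity: float  # NaN when degree variance is zero


@dataclass(frozen=True)
class LocalAssortativityMap:
    """Per-node assortativity contributions plus the shared null quantities.

    ``rho`` sums over nodes to the network's global degree assortativity.
    ``mu_q`` / ``var_q`` are the mean and (population) variance of the excess
    degree distribution q(k) = (k+1) p(k+1) / <k> taken over edge ends, and
    ``m_edges`` the number of undirected edges.
    """

    rho: dict[str, float]
    mu_q: float
    var_q: float
    m_edges: int
    mean_excess: float

    def total(self) -> float:
        return float(sum(self.rho.values()))


def _excess_degrees_at_edge_ends(l: Layer) -> np.ndarray:
    adj = l.adjacency()
    ends = []
    for u, v in l.edges:
        ends.append(len(adj[u]) - 1)
        ends.append(len(adj[v]) - 1)
    return np.asarray(ends, dtype=float)


def _transitivity(l: Layer) -> float:
    """Global clustering: 3 * triangles / connected triples."""
    adj = l.adjacency()
    triangles = 0
    triples = 0
    for node, nbrs in adj.items():
        k = len(nbrs)
        triples += k * (k - 1) // 2
        ns = sorted(nbrs)
        for i, u in enumerate(ns):
            for v in ns[i + 1 :]:
                if v in adj[u]:
                    triangles += 1
    # each triangle counted once per corner, i.e. 3 times, which is exactly
    # the numerator of 3*triangles/triples
    return triangles / triples if triples else UNDEFINED


def layer_summary(l: Layer) -> LayerSummary:
    """Density, transitivity and degree assortativity of one layer."""
    nodes = l.nodes
    n = len(nodes)
    if n < 2:
        raise ValueError("layer summary requires at least two nodes")
    m = l.n_edges
    density = 2 * m / (n * (n - 1))
    clustering = _transitivity(l)
    ends = _excess_degrees_at_edge_ends(l)
    # Pearson correlation of excess degrees across the two ends of each edge,
    # counting each undirected edge in both orientations.
    x = ends.reshape(-1, 2)
    xs = np.concatenate([x[:, 0], x[:, 1]])
    ys = np.concatenate([x[:, 1], x[:, 0]])
    if xs.var() == 0:
        assort = UNDEFINED
    else:
        assort = float(np.corrcoef(xs, ys)[0, 1])
    return LayerSummary(
        name=l.name,
        n_nodes=n,
        n_edges=m,
        density=density,
        clustering=clustering,
        assortativity=assort,
    )


def local_assortativity(l: Layer) -> LocalAssortativityMap:
    """Node-level decomposition of degree assortativity.

    rho_v = j (j+1) (kbar_v - mu_q) / (2 M var_q), where j is node v's excess
    degree, kbar_v the mean excess degree of v's neighbours, mu_q and var_q
    the mean and population variance of the excess degree over edge ends, and
    M the edge count.  Summed over all nodes this recovers the global
    assortativity exactly, which is the defining invariant.
    """
    ends = _excess_degrees_at_edge_ends(l)
    mu_q = float(ends.mean())
    var_q = float(ends.var())  # population variance over the 2M edge ends
    if var_q == 0:
        raise ValueError("degree variance is zero; assortativity undefined")
    adj = l.adjacency()
    m = l.n_edges
    rho: dict[str, float] = {}
    for v, nbrs in adj.items():
        j = len(nbrs) - 1
        kbar_v = float(np.mean([len(adj[u]) - 1 for u in nbrs]))
        rho[v] = j * (j + 1) * (kbar_v - mu_q) / (2 * m * var_q)
    return LocalAssortativityMap(
        rho=rho, mu_q=mu_q, var_q=var_q, m_edges=m, mean_excess=mu_q
    )


def annotation_bias(l: Layer, counts: Mapping[str, float]) -> float:
    """Rank correlation between node degree and an external per-gene count.

    Used with publication counts this measures the literature bias of a layer:
    a strongly positive value means well-studied genes are also the hubs.
    Returns NaN when either variable is constant over the shared genes.
    """
    adj = l.adjacency()
    shared = sorted(set(adj) & set(counts))
    if len(shared) < 3:
        raise ValueError("need at least three genes present in both inputs")
    degrees = np.array([len(adj[g]) for g in shared], dtype=float)
    vals = np.array([counts[g] for g in shared], dtype=float)
    if degrees.var() == 0 or vals.var() == 0:
        return UNDEFINED
    rho, _ = stats.spearmanr(degrees, vals)
    return float(rho)


def edge_conservation_profile(
    layers: Sequence[Layer], marked: set[str]
) -> dict[int, float]:
    """Fraction of c-times-conserved edges whose endpoints are both marked.

    For each conservation count c (number of layers an edge appears in), the
    value is the fraction of those edges with both endpoints in ``marked``
    (e.g. essential genes).  Counts with no edges are absent from the result.
    """
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    counts: dict[tuple[str, str], int] = {}
    for l in layers:
        for e in l.edges:
            counts[e] = counts.get(e, 0) + 1
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for (u, v), c in counts.items():
        totals[c] = totals.get(c, 0) + 1
        if u in marked and v in marked:
            hits[c] = hits.get(c, 0) + 1
    return {c: hits.get(c, 0) / t for c, t in sorted(totals.items())}
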