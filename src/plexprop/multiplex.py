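"""Core data model: network layers, multiplex networks, and inter-layer overlap.

A *layer* is one undirected gene-gene network at a single biological scale
(co-expression, physical interaction, pathway co-membership, semantic
similarity, ...).  A *multiplex network* is an ordered collection of layers
over a shared gene universe; a gene keeps its identity across layers, which is
what allows a random walker to switch layers without moving in gene space.

Inter-layer similarity is quantified by the edge overlap index

    S_AB = |E_A n E_B| / min(|E_A|, |E_B|)

whose significance is assessed against node-label permutations of each layer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Layer",
    "MultiplexNetwork",
    "OverlapResult",
    "canonical_edge",
    "edge_overlap_similarity",
    "overlap_significance",
    "dissimilarity_matrix",
]

SCALES = ("genome", "transcriptome", "proteome", "pathway", "function", "phenotype", "other")

Edge = tuple[str, str]


def canonical_edge(u: str, v: str) -> Edge:
    """Canonical (sorted) form of an undirected edge between two genes."""
    return (u, v) if u <= v else (v, u)


class Layer:
    """One named network layer: undirected gene-gene edges, optionally weighted.

    Self-loops are silently dropped on ingestion and every edge is stored once
    under its canonical sorted-pair key.  Weights, when given, must cover all
    edges and be non-negative.

    Parameters
    ----------
    name : str
        Layer identifier, unique within a multiplex.
    edges : iterable of (gene, gene)
        Undirected edges; order within a pair is irrelevant.
    weights : mapping edge -> float, optional
        Non-negative weight per edge (keys in any orientation).
    scale : str
        Biological-scale tag, one of ``SCALES``.
    """

    __slots__ = ("name", "scale", "edges", "weights", "_nodes", "_adj")

    def __init__(
        self,
        name: str,
        edges: Iterable[Edge],
        weights: Mapping[Edge, float] | None = None,
        scale: str = "other",
    ):
        if scale not in SCALES:
            raise ValueError(f"unknown scale tag {scale!r}; expected one of {SCALES}")
        self.name = name
        self.scale = scale
        canon: set[Edge] = set()
        for u, v in edges:
            if u == v:
                continue  # self-loops carry no relational information
            canon.add(canonical_edge(u, v))
        self.edges: frozenset[Edge] = frozenset(canon)
        if weights is not None:
            w: dict[Edge, float] = {}
            for (u, v), val in weights.items():
                if u == v:
                    continue
                e = canonical_edge(u, v)
                if e not in self.edges:
                    raise ValueError(f"weight given for absent edge {e}")
                if val < 0:
                    raise ValueError(f"negative weight {val} for edge {e}")
                if e in w and not math.isclose(w[e], val):
                    raise ValueError(f"conflicting weights for edge {e}")
                w[e] = float(val)
            missing = self.edges - w.keys()
            if missing:
                raise ValueError(
                    f"weights must cover all edges or none; {len(missing)} edges unweighted"
                )
            self.weights: dict[Edge, float] | None = w
        else:
            self.weights = None
        self._nodes: frozenset[str] | None = None
        self._adj: dict[str, set[str]] | None = None

    @property
    def nodes(self) -> frozenset[str]:
        if self._nodes is None:
            self._nodes = frozenset(itertools.chain.from_iterable(self.edges))
        return self._nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def weighted(self) -> bool:
        return self.weights is not None

    def adjacency(self) -> dict[str, set[str]]:
        """Node -> set of neighbours (computed once, cached)."""
        if self._adj is None:
            adj: dict[str, set[str]] = {}
            for u, v in self.edges:
                adj.setdefault(u, set()).add(v)
                adj.setdefault(v, set()).add(u)
            self._adj = adj
        return self._adj

    def degree(self, node: str) -> int:
        return len(self.adjacency().get(node, ()))

    def relabel(self, mapping: Mapping[str, str]) -> "Layer":
        """Return a copy with node identifiers mapped through ``mapping``."""
        edges = {canonical_edge(mapping.get(u, u), mapping.get(v, v)) for u, v in self.edges}
        return Layer(self.name, edges, scale=self.scale)

    def drop_weights(self) -> "Layer":
        return Layer(self.name, self.edges, scale=self.scale)

    def __contains__(self, edge: Edge) -> bool:
        return canonical_edge(*edge) in self.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        w = "weighted" if self.weighted else "unweighted"
        return f"Layer({self.name!r}, {len(self.nodes)} nodes, {self.n_edges} edges, {w})"


class MultiplexNetwork:
    """Ordered collection of layers over a shared gene universe.

    The universe defaults to the union of all layer node sets; a larger
    explicit universe may be supplied (genes present in some data source but
    isolated in every layer).
    """

    def __init__(self, layers: Sequence[Layer], universe: Iterable[str] | None = None):
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers: list[Layer] = list(layers)
        union: set[str] = set()
        for l in self.layers:
            union |= l.nodes
        if universe is None:
            self.universe: frozenset[str] = frozenset(union)
        else:
            uni = frozenset(universe)
            if not union <= uni:
                raise ValueError("universe must contain every layer endpoint")
            self.universe = uni

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "MultiplexNetwork":
        return MultiplexNetwork([self[n] for n in names], universe=self.universe)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultiplexNetwork({len(self.layers)} layers, {len(self.universe)} genes)"


@dataclass(frozen=True)
class OverlapResult:
    """Edge-overlap similarity of two layers with permutation significance."""

    similarity: float
    z: float  # NaN when the null distribution is degenerate
    p_empirical: float
    n_permutations: int
    null_mean: float = field(default=float("nan"))
    null_sd: float = field(default=float("nan"))


def edge_overlap_similarity(a: Layer, b: Layer) -> float:
    """Edge overlap index S_AB = |E_A n E_B| / min(|E_A|, |E_B|).

    Symmetric in its arguments; 1.0 when one edge set contains the other,
    0.0 for edge-disjoint layers.
    """
    if a.n_edges == 0 or b.n_edges == 0:
        raise ValueError("edge overlap undefined for an empty layer")
    return len(a.edges & b.edges) / min(a.n_edges, b.n_edges)


def _permuted_edge_sets(layer: Layer, n: int, rng: np.random.Generator) -> list[set[Edge]]:
    nodes = sorted(layer.nodes)
    out: list[set[Edge]] = []
    for _ in range(n):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        out.append(
            {canonical_edge(mapping[u], mapping[v]) for u, v in layer.edges}
        )
    return out


def overlap_significance(
    a: Layer, b: Layer, n_perm_per_net: int = 10, seed: int = 0
) -> OverlapResult:
    """Permutation test of the edge overlap between two layers.

    Each layer's node labels are permuted (a uniform bijection of its own node
    set onto itself, preserving the degree sequence) ``n_perm_per_net`` times;
    all pairings of permuted copies yield ``n_perm_per_net**2`` null overlaps.
    The empirical p-value uses the +1/(n+1) correction so it is never zero.
    """
    if n_perm_per_net < 2:
        raise ValueError("need at least 2 permutations per network")
    observed = edge_overlap_similarity(a, b)
    rng = np.random.default_rng(seed)
    perms_a = _permuted_edge_sets(a, n_perm_per_net, rng)
    perms_b = _permuted_edge_sets(b, n_perm_per_net, rng)
    denom = min(a.n_edges, b.n_edges)
    null = np.array(
        [len(ea & eb) / denom for ea in perms_a for eb in perms_b], dtype=float
    )
    n = null.size
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (int(np.sum(null >= observed)) + 1) / (n + 1)
    return OverlapResult(
        similarity=observed,
        z=z,
        p_empirical=p,
        n_permutations=n,
        null_mean=mean,
        null_sd=sd,
    )


def dissimilarity_matrix(m: MultiplexNetwork) -> np.ndarray:
    """Pairwise layer dissimilarity d_AB = 1 - S_AB (symmetric, zero diagonal).

    This is the matrix consumed by non-metric MDS layouts of the layer
    collection; the projection itself is out of scope here.
    """
    if len(m) < 2:
        raise ValueError("need at least two layers")
    L = len(m)
    d = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            s = edge_overlap_similarity(m.layers[i], m.layers[j])
            d[i, j] = d[j, i] = 1.0 - s
    return d
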