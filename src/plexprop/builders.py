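"""Layer construction from primary data.

Co-expression layers come from all-pairs Spearman correlation of an
expression matrix with a hard |rho| cutoff; dense weighted graphs (from
correlation or semantic similarity) are reduced to their multiscale backbone
by the disparity filter, which keeps edge (i, j) only when its weight is
unexpectedly large given *both* endpoints' local weight distributions:

    p_ij = (1 - w_ij)^(k_i - 1) < alpha   and   p_ji < alpha

with w_ij the weight normalized over node i's incident weights and k_i its
degree.  Pathway layers connect genes sharing at least ``min_shared`` gene
sets; tissue co-expression layers are split into a conserved core and
tissue-specific remainders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .multiplex import Layer, canonical_edge
from .ontology import (
    AnnotationTable,
    ICTable,
    Ontology,
    gene_semantic_similarity,
    only_root_in_common,
)

__all__ = [
    "ExpressionMatrix",
    "build_coexpression",
    "disparity_filter",
    "disparity_pvalues",
    "split_core_and_specific",
    "build_ontology_layer",
    "build_pathway_layer",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix (TPM-like, non-negative)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene rows")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample labels")
        if len(self.samples) < 2:
            raise ValueError("need at least two samples")


def build_coexpression(
    x: ExpressionMatrix, rho_cutoff: float = 0.75, name: str = "coexpression"
) -> Layer:
    """Weighted co-expression layer from all-pairs Spearman correlation.

    Genes with zero variance across samples are excluded (their correlation is
    undefined); an edge is kept iff |rho| > ``rho_cutoff`` and carries weight
    |rho|.  Ties are handled by average ranks (scipy's convention).
    """
    if not 0 < rho_cutoff < 1:
        raise ValueError("rho_cutoff must be in (0, 1)")
    if len(x.samples) < 3:
        raise ValueError("need at least three samples for rank correlation")
    variances = x.values.var(axis=1)
    keep = variances > 0
    genes = [g for g, k in zip(x.genes, keep) if k]
    if len(genes) < 2:
        warnings.warn("fewer than two variable genes; empty co-expression layer")
        return Layer(name, [], weights={}, scale="transcriptome")
    # rank rows once, then Pearson on ranks == Spearman (average-rank ties)
    ranks = np.apply_along_axis(stats.rankdata, 1, x.values[keep])
    rho = np.corrcoef(ranks)
    edges: dict[tuple[str, str], float] = {}
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = np.abs(rho[iu, ju]) > rho_cutoff
    for i, j in zip(iu[mask], ju[mask]):
        edges[canonical_edge(genes[i], genes[j])] = abs(float(rho[i, j]))
    return Layer(name, edges.keys(), weights=edges, scale="transcriptome")


def disparity_pvalues(weighted: Layer) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-edge disparity p-values (p_ij, p_ji), keyed by canonical edge.

    For each endpoint i of an edge, p = (1 - w)^(k-1) with w the edge weight
    normalized over i's incident weights and k = deg(i).  The degree-1 case
    (w = 1, exponent 0) is defined as p = 1: a pendant edge is never
    significant on its own side.
    """
    if not weighted.weighted:
        raise ValueError("disparity filter requires edge weights")
    strength: dict[str, float] = {}
    for (u, v), w in weighted.weights.items():
        strength[u] = strength.get(u, 0.0) + w
        strength[v] = strength.get(v, 0.0) + w
    adj = weighted.adjacency()
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for (u, v), w in weighted.weights.items():
        ps = []
        for a in (u, v):
            k = len(adj[a])
            if k <= 1 or strength[a] == 0:
                ps.append(1.0)
            else:
                ps.append((1.0 - w / strength[a]) ** (k - 1))
        out[(u, v)] = (ps[0], ps[1])
    return out


def disparity_filter(weighted: Layer, alpha: float = 0.05, or_rule: bool = False) -> Layer:
    """Backbone of a weighted layer: keep edges significant at both endpoints.

    With ``or_rule=True`` an edge survives when either endpoint's p-value
    passes (the criterion of the original backbone-extraction literature);
    the default requires both, which also means degree-1 nodes lose their
    pendant edge unless the OR rule is enabled.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    combine = any if or_rule else all
    kept = [
        e
        for e, (pij, pji) in disparity_pvalues(weighted).items()
        if combine(p < alpha for p in (pij, pji))
    ]
    return Layer(weighted.name, kept, scale=weighted.scale)


def split_core_and_specific(
    layers: Sequence[Layer], min_count: int = 5, core_name: str = "core"
) -> tuple[Layer, list[Layer]]:
    """Split tissue layers into conserved-core and tissue-specific edges.

    Edges present in at least ``min_count`` of the input layers form the core;
    each returned specific layer is its input layer minus the core edges.
    """
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    if min_count < 1:
        raise ValueError("min_count must be positive")
    counts: dict[tuple[str, str], int] = {}
    for l in layers:
        for e in l.edges:
            counts[e] = counts.get(e, 0) + 1
    core_edges = {e for e, c in counts.items() if c >= min_count}
    core = Layer(core_name, core_edges, scale="transcriptome")
    specific = [
        Layer(l.name, l.edges - core_edges, scale=l.scale) for l in layers
    ]
    return core, specific


def build_ontology_layer(
    a: AnnotationTable,
    o: Ontology,
    ic: ICTable | None = None,
    method: str = "resnik_bma",
    alpha: float = 0.05,
    name: str = "ontology",
    scale: str = "function",
) -> Layer:
    """Semantic-similarity layer over all annotated gene pairs, backboned.

    Pairs whose only common ancestry is the ontology root are unrelated and
    removed before filtering; the remaining dense weighted similarity graph is
    passed through the disparity filter.
    """
    from .ontology import term_information_content

    if ic is None:
        ic = term_information_content(o)
    genes = a.genes()
    weights: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            if method in ("resnik_bma", "lin_bma") and only_root_in_common(g1, g2, a, o, ic):
                continue
            if method == "frequency" and len(a.closure(g1, o) & a.closure(g2, o)) <= 1:
                continue  # root is always shared; sharing only it means unrelated
            sim = gene_semantic_similarity(g1, g2, a, o, ic, method=method)
            if sim > 0:
                weights[canonical_edge(g1, g2)] = sim
    dense = Layer(name, weights.keys(), weights=weights, scale=scale)
    if dense.n_edges == 0:
        return dense.drop_weights()
    return disparity_filter(dense, alpha=alpha)


def build_pathway_layer(
    sets: Mapping[str, Iterable[str]], min_shared: int = 5, name: str = "pathway"
) -> Layer:
    """Co-membership layer: connect genes sharing >= ``min_shared`` gene sets."""
    if min_shared < 1:
        raise ValueError("min_shared must be positive")
    membership: dict[str, set[str]] = {}
    for set_name, members in sets.items():
        for g in set(members):
            membership.setdefault(g, set()).add(set_name)
    genes = sorted(membership)
    edges = []
    for i, g1 in enumerate(genes):
        m1 = membership[g1]
        if len(m1) < min_shared:
            continue
        for g2 in genes[i + 1 :]:
            if len(m1 & membership[g2]) >= min_shared:
                edges.append((g1, g2))
    return Layer(name, edges, scale="pathway")
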