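import numpy as np
import pytest

from plexprop.multiplex import Layer, canonical_edge
from plexprop.ontology import AnnotationTable, Ontology


@pytest.fixture
def toy_ontology():
    """Five-term ontology: root R with children A, B; A has leaves a1, a2."""
    return Ontology({"R": set(), "A": {"R"}, "B": {"R"}, "a1": {"A"}, "a2": {"A"}})


@pytest.fixture
def toy_annotations():
    return AnnotationTable(
        direct={"g1": {"a1"}, "g2": {"a2"}, "g3": {"B"}, "g4": {"a1"}}
    )


@pytest.fixture
def two_clique_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    left = ["a", "b", "c", "d"]
    right = ["e", "f", "g", "h"]
    edges = set()
    for clique in (left, right):
        for i, u in enumerate(clique):
            for v in clique[i + 1 :]:
                edges.add((u, v))
    edges.add(("d", "e"))
    return Layer("bridge", edges)


def random_layer(n_nodes, n_edges, seed, name="rand", weighted=False):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = set()
    while len(edges) < n_edges:
        u, v = rng.choice(n_nodes, size=2, replace=False)
        edges.add(canonical_edge(nodes[u], nodes[v]))
    if weighted:
        weights = {e: float(rng.uniform(0.1, 10)) for e in edges}
        return Layer(name, edges, weights=weights)
    return Layer(name, edges)


def er_layer(n_nodes, p, seed, name="er"):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {
        canonical_edge(nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    }
    return Layer(name, edges)
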