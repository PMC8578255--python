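"""Deterministic synthetic fixtures with the statistical structure the method assumes.

These generators stand in for the curated resources the pipeline normally
consumes: multiplex networks with a disease module planted in a known subset
of layers, block-correlated expression matrices, balanced toy ontologies with
gene annotations, and simulated solved patient cases (one causal gene among
decoy candidates).  Every generator is a pure function of its parameters and
seed.

The default multiplex fixture mirrors the study-scale ratios at desk size:
300 genes, 6 layers of which 3 carry the module, background edge probability
0.02, and a 20-gene module (the approximate minimum module size detectable on
a PPI-scale network), guaranteed connected in the relevant layers via a
random spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import ExpressionMatrix
from .modules import DiseaseGroup
from .multiplex import Layer, MultiplexNetwork, canonical_edge
from .ontology import AnnotationTable, Ontology

__all__ = [
    "MultiplexSpec",
    "LayerSpec",
    "make_multiplex",
    "make_expression",
    "make_toy_ontology",
    "make_patient_case",
    "make_gene_features",
    "PatientCase",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class LayerSpec:
    name: str
    background_p: float
    relevant: bool = False
    scale: str = "other"


@dataclass(frozen=True)
class MultiplexSpec:
    """Parameters of a planted-module multiplex fixture."""

    n_genes: int = 300
    layers: tuple[LayerSpec, ...] = (
        LayerSpec("coexpr_brain", 0.02, True, "transcriptome"),
        LayerSpec("ppi", 0.02, True, "proteome"),
        LayerSpec("pathway", 0.02, True, "pathway"),
        LayerSpec("coexpr_liver", 0.02, False, "transcriptome"),
        LayerSpec("go_bp", 0.02, False, "function"),
        LayerSpec("hpo", 0.02, False, "phenotype"),
    )
    module_size: int = 20
    module_p: float = 0.35
    guarantee_connected: bool = True
    degree_preserving_background: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.module_size < self.n_genes:
            raise ValueError("module size must be in [2, n_genes)")
        for ls in self.layers:
            if not 0 < ls.background_p < 1:
                raise ValueError(f"background probability of {ls.name} not in (0, 1)")
        if not 0 < self.module_p < 1:
            raise ValueError("module probability must be in (0, 1)")


DEFAULT_SPEC = MultiplexSpec()


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _er_edges(genes: list[str], p: float, rng: np.random.Generator) -> set[tuple[str, str]]:
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return {canonical_edge(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])}


def _configuration_like_edges(
    genes: list[str], p: float, rng: np.random.Generator
) -> set[tuple[str, str]]:
    # heavier-tailed background for robustness checks of the LCC null:
    # per-gene propensities scale the ER acceptance probability
    n = len(genes)
    prop = rng.gamma(shape=1.0, scale=1.0, size=n)
    prop /= prop.mean()
    iu, ju = np.triu_indices(n, k=1)
    pij = np.clip(p * prop[iu] * prop[ju], 0, 1)
    mask = rng.random(iu.size) < pij
    return {canonical_edge(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])}


def _spanning_tree_edges(genes: list[str], rng: np.random.Generator) -> set[tuple[str, str]]:
    order = list(rng.permutation(genes))
    edges = set()
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        edges.add(canonical_edge(order[i], order[j]))
    return edges


def make_multiplex(
    spec: MultiplexSpec = DEFAULT_SPEC,
) -> tuple[MultiplexNetwork, DiseaseGroup, frozenset[str]]:
    """Planted-module multiplex: (network, disease group, relevant layer names).

    Every layer is a random background graph over the full gene set; layers
    flagged relevant additionally wire the module genes with ``module_p`` and
    (when ``guarantee_connected``) a random spanning tree, so the module's
    LCC equals the module size there.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    module = sorted(rng.choice(genes, size=spec.module_size, replace=False).tolist())
    background = (
        _configuration_like_edges if spec.degree_preserving_background else _er_edges
    )
    layers = []
    for ls in spec.layers:
        edges = background(genes, ls.background_p, rng)
        if ls.relevant:
            edges |= _er_edges(module, spec.module_p, rng)
            if spec.guarantee_connected:
                edges |= _spanning_tree_edges(module, rng)
        layers.append(Layer(ls.name, edges, scale=ls.scale))
    network = MultiplexNetwork(layers, universe=genes)
    group = DiseaseGroup(id="planted", label="planted disease module", genes=frozenset(module))
    relevant = frozenset(ls.name for ls in spec.layers if ls.relevant)
    return network, group, relevant


def make_expression(
    n_blocks: int = 2,
    genes_per_block: int = 10,
    n_samples: int = 100,
    latent_corr: float = 0.9,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Block-correlated TPM-like expression matrix.

    Each block shares one latent sample profile; a gene's log-abundance is
    latent * latent_corr plus independent Gaussian noise, exponentiated to a
    non-negative scale.  Genes within a block are therefore strongly
    rank-correlated while genes from different blocks are independent.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not 0 < latent_corr < 1:
        raise ValueError("latent_corr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = []
    rows = []
    for b in range(n_blocks):
        latent = rng.standard_normal(n_samples)
        for i in range(genes_per_block):
            genes.append(f"B{b}G{i:03d}")
            rows.append(latent * latent_corr + rng.standard_normal(n_samples) * noise_sd)
    values = np.exp(np.vstack(rows))
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


def make_toy_ontology(
    branching: int = 3,
    depth: int = 3,
    genes_per_leaf: int = 5,
    seed: int = 0,
    extra_leaf_prob: float = 0.0,
    genes: list[str] | None = None,
) -> tuple[Ontology, AnnotationTable]:
    """Balanced-tree ontology plus leaf-level gene annotations.

    The tree has ``depth`` levels below the root and ``branching`` children
    per internal term (branching=3, depth=3 gives 40 terms).  Genes are
    assigned to leaves in consecutive chunks of ``genes_per_leaf``; with
    ``extra_leaf_prob`` each gene may pick up additional random leaves.  An
    explicit gene list can be supplied (e.g. the universe of a multiplex
    fixture) and is consumed in order, so related genes land on shared leaves.
    """
    if branching < 2 or depth < 2:
        raise ValueError("branching and depth must each be at least 2")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {"T0": set()}
    level = ["T0"]
    counter = 1
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                term = f"T{counter}"
                counter += 1
                parents[term] = {parent}
                nxt.append(term)
        level = nxt
    leaves = level
    n_slots = len(leaves) * genes_per_leaf
    if genes is None:
        genes = [f"g{i:04d}" for i in range(n_slots)]
    if len(genes) > n_slots:
        raise ValueError(f"at most {n_slots} genes fit {len(leaves)} leaves")
    direct: dict[str, set[str]] = {}
    for idx, g in enumerate(genes):
        leaf = leaves[idx // genes_per_leaf]
        terms = {leaf}
        if extra_leaf_prob > 0:
            for other in leaves:
                if other != leaf and rng.random() < extra_leaf_prob:
                    terms.add(other)
        direct[g] = terms
    return Ontology(parents), AnnotationTable(direct={g: frozenset(t) for g, t in direct.items()})


@dataclass(frozen=True)
class PatientCase:
    """A simulated (or real) solved case: phenotypes, candidates, causal gene."""

    id: str
    phenotype_terms: frozenset[str]
    candidates: frozenset[str]
    causal: str | None
    disease_group: str

    def __post_init__(self):
        if self.causal is not None and self.causal not in self.candidates:
            raise ValueError("causal gene must be among the candidates")


def make_patient_case(
    network: MultiplexNetwork,
    group: DiseaseGroup,
    ontology: Ontology,
    annotations: AnnotationTable,
    n_candidates: int = 50,
    n_noise_terms: int = 2,
    seed: int = 0,
    case_id: str = "case",
) -> PatientCase:
    """Simulated solved case: causal gene from the module, decoys off-module.

    The patient's phenotype terms are the causal gene's annotations plus
    ``n_noise_terms`` noise leaves drawn from terms annotating off-module
    genes.  Decoy candidates are sampled off-module, preferentially including
    the genes annotated to the noise terms — emulating real candidate lists,
    which survive variant filtering partly because they relate to the
    patient's symptoms.
    """
    rng = np.random.default_rng(seed)
    module = sorted(group.genes)
    annotated_module = [g for g in module if g in annotations.direct]
    if not annotated_module:
        raise ValueError("no module gene is phenotype-annotated")
    causal = annotated_module[int(rng.integers(0, len(annotated_module)))]
    causal_terms = set(annotations.direct[causal])

    module_terms = set().union(*(annotations.direct.get(g, frozenset()) for g in module))
    off_module_terms = sorted(
        {
            t
            for g, ts in annotations.direct.items()
            if g not in group.genes
            for t in ts
        }
        - module_terms
    )
    n_noise = min(n_noise_terms, len(off_module_terms))
    noise_terms = (
        rng.choice(off_module_terms, size=n_noise, replace=False).tolist()
        if n_noise
        else []
    )
    phenotype_terms = frozenset(causal_terms | set(noise_terms))

    off_module = sorted(set(network.universe) - group.genes)
    confusable = sorted(
        g
        for g in off_module
        if annotations.direct.get(g, frozenset()) & set(noise_terms)
    )
    n_decoys = n_candidates - 1
    if n_decoys > len(off_module):
        raise ValueError("not enough off-module genes for the requested decoys")
    decoys = confusable[:n_decoys]
    remaining = [g for g in off_module if g not in set(decoys)]
    n_fill = n_decoys - len(decoys)
    if n_fill > 0:
        decoys += rng.choice(remaining, size=n_fill, replace=False).tolist()
    return PatientCase(
        id=case_id,
        phenotype_terms=phenotype_terms,
        candidates=frozenset([causal, *decoys]),
        causal=causal,
        disease_group=group.id,
    )


def make_gene_features(
    genes: list[str], seed: int = 0
) -> dict[str, dict[str, float]]:
    """Uninformative gene-level covariates for baseline ranking methods.

    Emulates the shape of pathway-count, mean-expression and literature-count
    features without any relation to the planted module, so baseline rankers
    have realistic inputs but no signal beyond chance.
    """
    rng = np.random.default_rng(seed)
    pathway = rng.poisson(5, size=len(genes)).astype(float)
    expression = np.exp(rng.standard_normal(len(genes)))
    literature = np.round(np.exp(rng.standard_normal(len(genes)) * 1.5 + 2.0))
    return {
        "pathway_count": dict(zip(genes, pathway)),
        "expression": dict(zip(genes, expression)),
        "literature": dict(zip(genes, literature)),
    }
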