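"""Cross-validated gene retrieval, gene-level baselines, and patient prioritization.

The retrieval benchmark asks: seeding the propagation with most of a
disease's genes, how well are the held-out genes ranked against the rest of
the genome?  Performance is the rank-based (Mann-Whitney) AUROC per fold of a
k-fold split, compared across four layer-selection regimes: a single
designated reference layer (the PPI in the original setting), the single most
relevant layer per disease, all layers with uniform weights, and the relevant
layers weighted by their normalized module z-scores.

Patient prioritization seeds the walk with genes annotated to the patient's
phenotype terms (weight proportional to how many patient terms a gene
matches), propagates with the disease group's relevance profile, and ranks
the patient's candidate genes by visiting probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .modules import DiseaseGroup
from .multiplex import MultiplexNetwork
from .ontology import AnnotationTable, ICTable, Ontology, gene_semantic_similarity
from .propagation import (
    LayerKernel,
    RelevanceProfile,
    SeedVector,
    aggregate_and_rank,
    informed_rwr,
    layer_transition_kernel,
    relevance_scores,
)

__all__ = [
    "CVResult",
    "PatientResult",
    "auroc",
    "kfold_retrieval",
    "baseline_rank",
    "prioritize_patient",
    "REGIMES",
]

REGIMES = ("ppi_only", "best_single", "all_layers", "relevant_layers")

BASELINE_MODES = ("pathway_count", "expression", "literature", "phenotype_similarity")


def auroc(
    scores: Mapping[str, float], positives: set[str], negatives: set[str]
) -> float:
    """Rank-based AUROC: P(random positive outscores a random negative).

    Computed from the Mann-Whitney U statistic with average ranks, so tied
    scores contribute 1/2.  Invariant under any strictly monotone transform
    of the scores.
    """
    pos = [scores[g] for g in positives]
    neg = [scores[g] for g in negatives]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative")
    allvals = np.array(pos + neg, dtype=float)
    ranks = stats.rankdata(allvals)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass(frozen=True)
class CVResult:
    """k-fold retrieval performance of one disease group under one regime."""

    group_id: str
    regime: str
    fold_aurocs: tuple[float, ...]
    layers_used: tuple[tuple[str, ...], ...]

    @property
    def median_auroc(self) -> float:
        return float(np.median(self.fold_aurocs))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.fold_aurocs, [25, 75])
        return float(lo), float(hi)


def _regime_profile(
    regime: str,
    z: Mapping[str, float],
    layer_order: Sequence[str],
    threshold: float,
    reference_layer: str | None,
) -> RelevanceProfile:
    if regime == "ppi_only":
        if reference_layer is None:
            raise ValueError("ppi_only regime needs a designated reference layer")
        return RelevanceProfile.single(reference_layer)
    if regime == "best_single":
        finite = {n: v for n, v in z.items() if not math.isnan(v)}
        if not finite:
            raise ValueError("no finite z-score to pick the best single layer")
        best = max(sorted(finite), key=lambda n: finite[n])
        return RelevanceProfile.single(best)
    if regime == "all_layers":
        return RelevanceProfile.uniform(layer_order)
    if regime == "relevant_layers":
        return relevance_scores(z, threshold=threshold, layer_order=layer_order)
    raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")


def kfold_retrieval(
    m: MultiplexNetwork,
    group: DiseaseGroup,
    z: Mapping[str, float],
    k: int = 10,
    regime: str = "relevant_layers",
    seed: int = 0,
    reference_layer: str | None = None,
    threshold: float = 1.645,
    r: float = 0.7,
    tol: float = 1e-8,
) -> CVResult:
    """k-fold cross-validated retrieval of a disease group's genes.

    Group genes (restricted to the universe) are shuffled deterministically by
    ``seed`` into k folds; per fold the remaining genes seed the propagation
    (uniform weights) and the held-out genes are the positives.  Negatives are
    all universe genes neither in the group nor seeding the walk.
    """
    genes = sorted(group.genes & m.universe)
    if len(genes) < k:
        raise ValueError(f"group has {len(genes)} mappable genes, fewer than k={k}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(genes))
    folds = [order[i::k] for i in range(k)]
    profile = _regime_profile(regime, z, m.layer_names, threshold, reference_layer)
    kernel = layer_transition_kernel(profile)
    sub = m.subset(list(kernel.layer_names))
    fold_aurocs = []
    for fold in folds:
        held_out = set(fold)
        seeds = SeedVector.uniform([g for g in genes if g not in held_out])
        res = informed_rwr(sub, kernel, seeds, r=r, tol=tol)
        scores = res.aggregated
        negatives = set(m.universe) - set(group.genes) - seeds.support
        fold_aurocs.append(auroc(scores, held_out, negatives))
    return CVResult(
        group_id=group.id,
        regime=regime,
        fold_aurocs=tuple(fold_aurocs),
        layers_used=tuple(kernel.layer_names for _ in folds),
    )


def baseline_rank(
    candidates: set[str],
    features: Mapping[str, float] | None = None,
    mode: str = "pathway_count",
    patient_terms: set[str] | None = None,
    annotations: AnnotationTable | None = None,
    ontology: Ontology | None = None,
    ic: ICTable | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate genes by a single gene-level feature.

    Modes mirror the usual clinical baselines: count of pathways a gene
    belongs to, expression level in a context of interest, literature counts,
    or phenotypic similarity (Best-Match-Average semantic similarity between
    a candidate's phenotype annotations and the patient's term set).
    Candidates without a feature value rank last; ties break lexicographically.
    """
    if mode not in BASELINE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {BASELINE_MODES}")
    scored: dict[str, float] = {}
    if mode == "phenotype_similarity":
        if patient_terms is None or annotations is None or ontology is None or ic is None:
            raise ValueError("phenotype_similarity needs patient terms, annotations, ontology, ic")
        patient = AnnotationTable(direct={"__patient__": frozenset(patient_terms)})
        merged = AnnotationTable(direct={**annotations.direct, **patient.direct})
        for g in candidates:
            if g in annotations.direct:
                scored[g] = gene_semantic_similarity(
                    g, "__patient__", merged, ontology, ic, method="resnik_bma"
                )
    else:
        if features is None:
            raise ValueError(f"mode {mode!r} needs a feature mapping")
        for g in candidates:
            if g in features:
                scored[g] = float(features[g])
    if not scored:
        raise ValueError("no candidate has a feature value")
    missing = sorted(candidates - scored.keys())
    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked + [(g, float("-inf")) for g in missing]


@dataclass(frozen=True)
class PatientResult:
    """Candidate ranking for one patient, with benchmark positions."""

    case_id: str
    ranking: tuple[tuple[str, float], ...]
    seed_weights: dict[str, float]
    causal_rank: int | None  # 1-based; None when the causal gene is unknown

    def in_top(self, k: int) -> bool | None:
        if self.causal_rank is None:
            return None
        return self.causal_rank <= k


def phenotype_seed_vector(
    patient_terms: set[str], annotations: AnnotationTable
) -> SeedVector:
    """Seed genes from patient phenotypes, weighted by matched-term count.

    A gene annotated to several of the patient's terms gets proportionally
    more seed weight; weights are normalized to sum to one.
    """
    weights = {
        g: float(len(ts & patient_terms))
        for g, ts in annotations.direct.items()
        if ts & patient_terms
    }
    if not weights:
        raise ValueError(
            "no gene is annotated to any of the patient's phenotype terms; "
            "cannot derive seed genes"
        )
    return SeedVector(weights)


def prioritize_patient(
    m: MultiplexNetwork,
    case,
    relevance: RelevanceProfile,
    phenotype_annotations: AnnotationTable,
    r: float = 0.7,
    tol: float = 1e-8,
    include_seed_candidates: bool = True,
) -> PatientResult:
    """Patient-specific informed propagation over the candidate gene list.

    Seeds come from the patient's phenotype terms (frequency-weighted); the
    layer kernel from the disease group's relevance profile.  Candidate genes
    that are themselves seeds stay in the ranking by default, since a causal
    gene is often itself phenotype-annotated.
    """
    if not case.candidates:
        raise ValueError("patient case has no candidate genes")
    seeds = phenotype_seed_vector(set(case.phenotype_terms), phenotype_annotations)
    kernel = layer_transition_kernel(relevance)
    sub = m.subset(list(kernel.layer_names))
    res = informed_rwr(sub, kernel, seeds, r=r, tol=tol)
    ranking = aggregate_and_rank(
        res, seeds, restrict_to=set(case.candidates), include_seeds=include_seed_candidates
    )
    if not ranking:
        # all candidates were seeds and got excluded, or none in universe:
        # fall back to seed-weight ordering
        ranking = sorted(
            ((g, seeds.weights.get(g, 0.0)) for g in case.candidates),
            key=lambda kv: (-kv[1], kv[0]),
        )
    causal_rank = None
    if case.causal is not None:
        for i, (g, _) in enumerate(ranking, start=1):
            if g == case.causal:
                causal_rank = i
                break
    return PatientResult(
        case_id=case.id,
        ranking=tuple(ranking),
        seed_weights=dict(seeds.weights),
        causal_rank=causal_rank,
    )
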