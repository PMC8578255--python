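"""Ontology DAGs, information content, and semantic similarity of genes.

The information content of a term is derived from the ontology topology:
IC(t) = -ln(n_t / N) where n_t counts the descendants of t (including t
itself) and N those of the root, so the root has IC 0 and leaves are maximally
informative.  Term similarity follows Resnik (IC of the most informative
common ancestor, MICA) or Lin (2*IC(MICA) / (IC(t1)+IC(t2))); gene similarity
combines term similarities by the Best-Match Average (BMA) over the genes'
direct annotations, or simply counts shared annotations (ancestor closure
included) for the frequency variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Ontology",
    "AnnotationTable",
    "ICTable",
    "term_information_content",
    "term_similarity",
    "gene_semantic_similarity",
]


class Ontology:
    """A rooted is_a DAG of terms.

    Parameters
    ----------
    parents : mapping term -> set of parent terms
        Every term must appear as a key (the root with an empty parent set).
    root : str, optional
        Root term id; inferred as the unique parentless term when omitted.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]], root: str | None = None):
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        for t, ps in self.parents.items():
            unknown = [p for p in ps if p not in self.parents]
            if unknown:
                raise ValueError(f"term {t!r} has unknown parent(s) {unknown}")
        roots = [t for t, ps in self.parents.items() if not ps]
        if root is None:
            if len(roots) != 1:
                raise ValueError(f"expected exactly one root, found {roots}")
            root = roots[0]
        elif root not in self.parents or self.parents[root]:
            raise ValueError(f"{root!r} is not a parentless term")
        self.root = root
        # children map + cycle check (TopologicalSorter raises on cycles)
        self.children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        self._order = list(
            TopologicalSorter({t: set(ps) for t, ps in self.parents.items()}).static_order()
        )
        self._ancestors: dict[str, frozenset[str]] = {}
        for t in self._order:  # parents precede children in static_order
            anc: set[str] = {t}
            for p in self.parents[t]:
                anc |= self._ancestors[p]
            self._ancestors[t] = frozenset(anc)
        unreachable = [t for t in self.parents if self.root not in self._ancestors[t]]
        if unreachable:
            raise ValueError(f"terms not reaching root: {sorted(unreachable)[:5]}")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term``, including the term itself."""
        return self._ancestors[term]

    def leaves(self) -> list[str]:
        return sorted(t for t, cs in self.children.items() if not cs)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)


@dataclass
class AnnotationTable:
    """Direct gene -> ontology-term annotations."""

    direct: dict[str, frozenset[str]]

    def __post_init__(self):
        self.direct = {g: frozenset(ts) for g, ts in self.direct.items() if ts}

    def validate(self, ontology: Ontology) -> None:
        for g, ts in self.direct.items():
            bad = [t for t in ts if t not in ontology]
            if bad:
                raise ValueError(f"gene {g!r} annotated to unknown term(s) {bad}")

    def genes(self) -> list[str]:
        return sorted(self.direct)

    def closure(self, gene: str, ontology: Ontology) -> frozenset[str]:
        """Direct annotations of ``gene`` plus all their ancestors."""
        terms: set[str] = set()
        for t in self.direct[gene]:
            terms |= ontology.ancestors(t)
        return frozenset(terms)


@dataclass(frozen=True)
class ICTable:
    """Per-term information content in nats (natural log)."""

    ic: dict[str, float]
    descendant_counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def term_information_content(o: Ontology) -> ICTable:
    """Topology-based information content for every term of an ontology.

    n_t is the number of descendants of t *including t itself* (so p(t) is in
    (0, 1] and IC(root) = 0); in a DAG a shared descendant is counted once.
    """
    desc: dict[str, frozenset[str]] = {}
    for t in reversed(o._order):  # children before parents
        d: set[str] = {t}
        for c in o.children[t]:
            d |= desc[c]
        desc[t] = frozenset(d)
    n_root = len(desc[o.root])
    counts = {t: len(d) for t, d in desc.items()}
    ic = {t: -math.log(counts[t] / n_root) for t in o.parents}
    return ICTable(ic=ic, descendant_counts=counts)


def _mica(o: Ontology, ic: ICTable, t1: str, t2: str) -> str:
    common = o.ancestors(t1) & o.ancestors(t2)
    return max(common, key=lambda t: (ic.ic[t], t))  # id tie-break for determinism


def term_similarity(o: Ontology, ic: ICTable, t1: str, t2: str, method: str = "resnik") -> float:
    """Pairwise term similarity via the most informative common ancestor.

    resnik: IC(MICA), unbounded above.  lin: 2*IC(MICA)/(IC(t1)+IC(t2)) in
    [0, 1], defined as 0 when both terms are the root.
    """
    if t1 not in o or t2 not in o:
        raise KeyError("both terms must be in the ontology")
    mica_ic = ic.ic[_mica(o, ic, t1, t2)]
    if method == "resnik":
        return mica_ic
    if method == "lin":
        denom = ic.ic[t1] + ic.ic[t2]
        return 2.0 * mica_ic / denom if denom > 0 else 0.0
    raise ValueError(f"unknown term similarity method {method!r}")


def _bma(sim: np.ndarray) -> float:
    # (sum of column maxima + sum of row maxima) / (m + n)
    m, n = sim.shape
    return float(sim.max(axis=0).sum() + sim.max(axis=1).sum()) / (m + n)


def gene_semantic_similarity(
    g1: str,
    g2: str,
    a: AnnotationTable,
    o: Ontology,
    ic: ICTable,
    method: str = "resnik_bma",
) -> float:
    """Semantic similarity between two annotated genes.

    ``resnik_bma`` / ``lin_bma``: Best-Match Average over the m x n matrix of
    pairwise term similarities of the genes' *direct* annotations,
    (sum colmax + sum rowmax) / (m + n).  ``frequency``: number of shared
    terms after ancestor closure, |T_g1 n T_g2|.
    """
    for g in (g1, g2):
        if g not in a.direct:
            raise KeyError(f"gene {g!r} has no annotations")
    if method == "frequency":
        return float(len(a.closure(g1, o) & a.closure(g2, o)))
    if method in ("resnik_bma", "lin_bma"):
        base = "resnik" if method == "resnik_bma" else "lin"
        ts1 = sorted(a.direct[g1])
        ts2 = sorted(a.direct[g2])
        sim = np.empty((len(ts1), len(ts2)))
        for i, t1 in enumerate(ts1):
            for j, t2 in enumerate(ts2):
                sim[i, j] = term_similarity(o, ic, t1, t2, method=base)
        return _bma(sim)
    raise ValueError(f"unknown gene similarity method {method!r}")


def only_root_in_common(g1: str, g2: str, a: AnnotationTable, o: Ontology, ic: ICTable) -> bool:
    """True when every best-match common ancestor of the two genes is the root.

    Such pairs carry minimal similarity (their only shared annotation is the
    uninformative root) and are treated as unrelated when building
    similarity-derived network layers.
    """
    for t1 in a.direct[g1]:
        for t2 in a.direct[g2]:
            if _mica(o, ic, t1, t2) != o.root and ic.ic[_mica(o, ic, t1, t2)] > 0:
                return False
    return True
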