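"""Disease-module significance: LCC z-scores per layer and the relevance table.

A disease's genes form a *module* on a layer when they are more connected
among themselves than random gene sets of the same size.  Connectedness is
measured by the size of the largest connected component (LCC) of the induced
subgraph; significance comes from a Monte-Carlo null of uniformly drawn node
sets from the same layer, summarized as a z-score and an empirical p-value.
Across a collection of disease groups and layers the p-values are
Benjamini-Hochberg adjusted jointly, giving the disease x layer relevance
table that later drives the informed propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .multiplex import Layer, MultiplexNetwork

__all__ = [
    "DiseaseGroup",
    "ModuleSignificance",
    "RelevanceTable",
    "lcc_size",
    "lcc_significance",
    "relevance_table",
    "significance_stars",
]

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class DiseaseGroup:
    """A named disease group with its associated gene set."""

    id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("disease group must have at least one gene")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class ModuleSignificance:
    """LCC-based module significance of one disease group on one layer."""

    lcc_observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd = 0)
    p_empirical: float
    p_adjusted: float = field(default=float("nan"))
    n_in_layer: int = 0
    testable: bool = True


def lcc_size(l: Layer, genes: Iterable[str]) -> int:
    """Size of the largest connected component of the induced gene subgraph.

    Genes absent from the layer are ignored; an empty intersection gives 0.
    """
    adj = l.adjacency()
    present = set(genes) & adj.keys()
    if not present:
        return 0
    best = 0
    unseen = set(present)
    while unseen:
        start = unseen.pop()
        comp = 1
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr in unseen:
                    unseen.discard(nbr)
                    comp += 1
                    stack.append(nbr)
        best = max(best, comp)
    return best


def _lcc_of_subset(adj: dict[str, set[str]], subset: Sequence[str]) -> int:
    present = set(subset)
    best = 0
    unseen = set(present)
    while unseen:
        start = unseen.pop()
        comp = 1
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr in unseen:
                    unseen.discard(nbr)
                    comp += 1
                    stack.append(nbr)
        best = max(best, comp)
    return best


def lcc_null_distribution(
    l: Layer, subset_size: int, n_rand: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo null: LCC sizes of uniform node subsets of the layer.

    Subsets are drawn without replacement from the layer's own node set, so
    coverage differences between layers do not distort the null.
    """
    adj = l.adjacency()
    nodes = np.array(sorted(adj))
    rng = np.random.default_rng(seed)
    out = np.empty(n_rand, dtype=np.int64)
    for i in range(n_rand):
        sample = nodes[rng.choice(len(nodes), size=subset_size, replace=False)]
        out[i] = _lcc_of_subset(adj, sample.tolist())
    return out


def lcc_significance(
    l: Layer, genes: Iterable[str], n_rand: int = 1000, seed: int = 0
) -> ModuleSignificance:
    """Monte-Carlo significance of a gene set's LCC on one layer.

    z uses the null sample standard deviation (ddof=1); the empirical p-value
    carries the +1/(n+1) correction and counts null >= observed.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    genes = set(genes)
    present = genes & l.nodes
    if len(present) < 2:
        raise ValueError("need at least two disease genes present in the layer")
    observed = lcc_size(l, present)
    null = lcc_null_distribution(l, len(present), n_rand, seed=seed)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (int(np.sum(null >= observed)) + 1) / (n_rand + 1)
    return ModuleSignificance(
        lcc_observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_empirical=p,
        n_in_layer=len(present),
    )


_NOT_TESTABLE = ModuleSignificance(
    lcc_observed=0,
    null_mean=float("nan"),
    null_sd=float("nan"),
    z=float("nan"),
    p_empirical=float("nan"),
    n_in_layer=0,
    testable=False,
)


@dataclass
class RelevanceTable:
    """Disease-group x layer table of ModuleSignificance cells."""

    group_ids: list[str]
    layer_names: list[str]
    cells: dict[tuple[str, str], ModuleSignificance]

    def __getitem__(self, key: tuple[str, str]) -> ModuleSignificance:
        return self.cells[key]

    def z_scores(self, group_id: str) -> dict[str, float]:
        """Layer -> LCC z-score for one disease group (NaN where untestable)."""
        return {ln: self.cells[(group_id, ln)].z for ln in self.layer_names}

    def significant_layers(self, group_id: str, alpha: float = 0.05) -> list[str]:
        return [
            ln
            for ln in self.layer_names
            if self.cells[(group_id, ln)].testable
            and self.cells[(group_id, ln)].p_adjusted < alpha
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.group_ids:
            for ln in self.layer_names:
                c = self.cells[(g, ln)]
                rows.append(
                    {
                        "group": g,
                        "layer": ln,
                        "n_in_layer": c.n_in_layer,
                        "lcc": c.lcc_observed,
                        "null_mean": c.null_mean,
                        "null_sd": c.null_sd,
                        "z": c.z,
                        "p": c.p_empirical,
                        "p_adj": c.p_adjusted,
                        "stars": significance_stars(c.p_adjusted) if c.testable else "NT",
                    }
                )
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    return "*" * sum(p < t for t in STAR_THRESHOLDS)


def relevance_table(
    m: MultiplexNetwork,
    groups: Sequence[DiseaseGroup],
    n_rand: int = 1000,
    seed: int = 0,
    per_layer_correction: bool = False,
) -> RelevanceTable:
    """Compute module significance for every (group, layer) pair with BH control.

    Benjamini-Hochberg adjustment is applied jointly over all testable cells
    of the table (per-layer families via ``per_layer_correction``).  Cells
    where fewer than two of a group's genes map into the layer are marked
    not-testable and carried as NaN sentinels.
    """
    cells: dict[tuple[str, str], ModuleSignificance] = {}
    rng = np.random.default_rng(seed)
    for g in groups:
        for l in m.layers:
            cell_seed = int(rng.integers(0, 2**31 - 1))
            if len(g.genes & l.nodes) < 2:
                cells[(g.id, l.name)] = _NOT_TESTABLE
            else:
                cells[(g.id, l.name)] = lcc_significance(
                    l, g.genes, n_rand=n_rand, seed=cell_seed
                )

    def adjust(keys: list[tuple[str, str]]) -> None:
        testable = [k for k in keys if cells[k].testable]
        if not testable:
            return
        pvals = [cells[k].p_empirical for k in testable]
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for k, pa in zip(testable, padj):
            cells[k] = replace(cells[k], p_adjusted=max(float(pa), cells[k].p_empirical))

    all_keys = [(g.id, l.name) for g in groups for l in m.layers]
    if per_layer_correction:
        for l in m.layers:
            adjust([k for k in all_keys if k[1] == l.name])
    else:
        adjust(all_keys)
    return RelevanceTable(
        group_ids=[g.id for g in groups],
        layer_names=m.layer_names,
        cells=cells,
    )
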