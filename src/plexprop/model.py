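"""Model/Results front end tying the pipeline together.

``MultiplexDiseaseModel`` holds the data (a multiplex network plus disease
groups); ``fit()`` estimates each group's per-layer module significance
(Monte-Carlo LCC z-scores, empirical and BH-adjusted p-values) and returns a
``MultiplexDiseaseResults`` carrying the estimates, their uncertainties and a
summary table.  Propagation, cross-validation and patient prioritization hang
off the results object, which caches the fitted relevance profiles.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .evaluation import CVResult, PatientResult, kfold_retrieval, prioritize_patient
from .modules import DiseaseGroup, RelevanceTable, relevance_table
from .multiplex import MultiplexNetwork
from .ontology import AnnotationTable
from .propagation import (
    PropagationResult,
    RelevanceProfile,
    SeedVector,
    aggregate_and_rank,
    informed_rwr,
    layer_transition_kernel,
    relevance_scores,
)

__all__ = ["MultiplexDiseaseModel", "MultiplexDiseaseResults"]


class MultiplexDiseaseModel:
    """Disease-module relevance model over a multiplex gene network.

    Parameters
    ----------
    multiplex : MultiplexNetwork
        The layered network.
    groups : sequence of DiseaseGroup
        Disease groups whose module significance is to be estimated.

    Examples
    --------
    >>> from plexprop.simulate import make_multiplex
    >>> net, group, relevant = make_multiplex()
    >>> results = MultiplexDiseaseModel(net, [group]).fit(seed=1)
    >>> profile = results.relevance_profile(group.id)
    """

    def __init__(self, multiplex: MultiplexNetwork, groups: Sequence[DiseaseGroup]):
        self.multiplex = multiplex
        self.groups = list(groups)
        if not self.groups:
            raise ValueError("need at least one disease group")

    @classmethod
    def from_files(cls, manifest_path, groups_gmt) -> "MultiplexDiseaseModel":
        from .io import gene_sets_to_groups, read_gene_sets, read_multiplex

        return cls(read_multiplex(manifest_path), gene_sets_to_groups(read_gene_sets(groups_gmt)))

    def fit(
        self,
        n_rand: int = 1000,
        seed: int = 0,
        threshold: float = 1.645,
        per_layer_correction: bool = False,
    ) -> "MultiplexDiseaseResults":
        """Estimate the group x layer relevance table by Monte-Carlo LCC nulls."""
        table = relevance_table(
            self.multiplex,
            self.groups,
            n_rand=n_rand,
            seed=seed,
            per_layer_correction=per_layer_correction,
        )
        return MultiplexDiseaseResults(self, table, threshold=threshold)


class MultiplexDiseaseResults:
    """Fitted disease-module relevance: estimates, uncertainties, diagnostics."""

    def __init__(
        self, model: MultiplexDiseaseModel, table: RelevanceTable, threshold: float = 1.645
    ):
        self.model = model
        self.table = table
        self.threshold = threshold
        self._profiles: dict[str, RelevanceProfile] = {}

    def summary(self) -> pd.DataFrame:
        """Group x layer table: LCC, null mean/sd, z, p, BH-adjusted p, stars."""
        return self.table.to_frame()

    def relevance_profile(self, group_id: str) -> RelevanceProfile:
        """Normalized relevance weights pi for one group (cached)."""
        if group_id not in self._profiles:
            z = self.table.z_scores(group_id)
            self._profiles[group_id] = relevance_scores(
                z, threshold=self.threshold, layer_order=self.model.multiplex.layer_names
            )
        return self._profiles[group_id]

    def propagate(
        self,
        group_id: str,
        seeds: SeedVector | None = None,
        r: float = 0.7,
        tol: float = 1e-8,
    ) -> PropagationResult:
        """Informed propagation for one group; seeds default to its gene set."""
        group = self._group(group_id)
        if seeds is None:
            seeds = SeedVector.uniform(sorted(group.genes & self.model.multiplex.universe))
        profile = self.relevance_profile(group_id)
        kernel = layer_transition_kernel(profile)
        sub = self.model.multiplex.subset(list(kernel.layer_names))
        return informed_rwr(sub, kernel, seeds, r=r, tol=tol)

    def rank_genes(self, group_id: str, **kwargs) -> list[tuple[str, float]]:
        group = self._group(group_id)
        seeds = SeedVector.uniform(sorted(group.genes & self.model.multiplex.universe))
        res = self.propagate(group_id, seeds=seeds, **kwargs)
        return aggregate_and_rank(res, seeds)

    def crossval(
        self,
        group_id: str,
        regime: str = "relevant_layers",
        k: int = 10,
        seed: int = 0,
        reference_layer: str | None = None,
        **kwargs,
    ) -> CVResult:
        return kfold_retrieval(
            self.model.multiplex,
            self._group(group_id),
            self.table.z_scores(group_id),
            k=k,
            regime=regime,
            seed=seed,
            reference_layer=reference_layer,
            threshold=self.threshold,
            **kwargs,
        )

    def prioritize(
        self, case, phenotype_annotations: AnnotationTable, **kwargs
    ) -> PatientResult:
        return prioritize_patient(
            self.model.multiplex,
            case,
            self.relevance_profile(case.disease_group),
            phenotype_annotations,
            **kwargs,
        )

    def _group(self, group_id: str) -> DiseaseGroup:
        for g in self.model.groups:
            if g.id == group_id:
                return g
        raise KeyError(group_id)
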