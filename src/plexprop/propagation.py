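"""Informed multiplex network propagation (relevance-weighted RWR).

The walker lives on (gene, layer) states.  Per step it either moves along a
degree-normalized edge of its current layer (probability ``t[n -> n]``) or
switches to the same gene's copy in another informative layer
(``t[n -> m]``).  The layer kernel is a Metropolis chain built from the
per-layer relevance scores pi (normalized LCC z-scores of the disease
module):

    t[n -> m] = (1/L) * min(1, pi_m / pi_n)   for m != n
    t[n -> n] = 1 - sum_{m != n} t[n -> m]

which satisfies detailed balance pi_n t[n -> m] = pi_m t[m -> n] and hence
has pi as its stationary distribution: over a long walk the visiting
probability of a layer is proportional to its relevance.  Restart with
probability r returns the walker to the seed distribution:

    p_{t+1} = (1 - r) S~ p_t + r p_0,   r = 0.7 by default.

Layers with pi = 0 are dropped from the state space; mass that would move
intra-layer from a gene isolated in its current layer is redirected to the
restart vector, keeping the operator stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .multiplex import MultiplexNetwork

__all__ = [
    "RelevanceProfile",
    "LayerKernel",
    "SeedVector",
    "PropagationResult",
    "relevance_scores",
    "layer_transition_kernel",
    "informed_rwr",
    "aggregate_and_rank",
]

INFORMATIVE_Z = 1.645  # one-sided 95% confidence level of a standard normal


@dataclass(frozen=True)
class RelevanceProfile:
    """Per-layer relevance weights pi for one disease group.

    pi sums to 1 and is strictly positive exactly on the informative layers
    (those whose module z-score passed the threshold, or all layers under the
    uniform fallback).
    """

    pi: dict[str, float]
    informative: tuple[str, ...]
    z_source: dict[str, float] = field(default_factory=dict)
    fallback: bool = False

    @classmethod
    def uniform(cls, layer_names: Sequence[str], fallback: bool = False) -> "RelevanceProfile":
        L = len(layer_names)
        return cls(
            pi={n: 1.0 / L for n in layer_names},
            informative=tuple(layer_names),
            fallback=fallback,
        )

    @classmethod
    def single(cls, layer_name: str) -> "RelevanceProfile":
        return cls(pi={layer_name: 1.0}, informative=(layer_name,))


def relevance_scores(
    z: Mapping[str, float],
    threshold: float = INFORMATIVE_Z,
    layer_order: Sequence[str] | None = None,
) -> RelevanceProfile:
    """Normalize module z-scores into per-layer relevance weights.

    Layers with z >= ``threshold`` are informative and get pi = z / sum(z)
    over the informative set; all others get 0.  If no layer passes (or every
    z is undefined), the profile falls back to uniform weights over all
    layers, flagged via ``fallback``.
    """
    if not z:
        raise ValueError("need at least one layer z-score")
    order = list(layer_order) if layer_order is not None else list(z)
    informative = [n for n in order if not np.isnan(z[n]) and z[n] >= threshold]
    if not informative:
        prof = RelevanceProfile.uniform(order, fallback=True)
        return RelevanceProfile(
            pi=prof.pi, informative=prof.informative, z_source=dict(z), fallback=True
        )
    total = float(sum(z[n] for n in informative))
    pi = {n: (z[n] / total if n in informative else 0.0) for n in order}
    return RelevanceProfile(pi=pi, informative=tuple(informative), z_source=dict(z))


@dataclass(frozen=True)
class LayerKernel:
    """Row-stochastic layer-switching kernel with stationary distribution pi."""

    t: np.ndarray  # t[n, m] = probability of moving from layer n to layer m
    layer_names: tuple[str, ...]
    pi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))


def layer_transition_kernel(p: RelevanceProfile) -> LayerKernel:
    """Metropolis kernel over the informative layers of a relevance profile.

    Off-diagonal entries are (1/L) min(1, pi_m / pi_n); the diagonal absorbs
    the remainder, so rows sum to one and detailed balance
    pi_n t[n,m] = pi_m t[m,n] holds exactly.
    """
    names = p.informative
    L = len(names)
    if L == 0:
        raise ValueError("relevance profile has no informative layers")
    pi = np.array([p.pi[n] for n in names], dtype=float)
    t = np.zeros((L, L))
    for n in range(L):
        for m in range(L):
            if m != n:
                t[n, m] = min(1.0, pi[m] / pi[n]) / L
        t[n, n] = 1.0 - t[n].sum()
    return LayerKernel(t=t, layer_names=tuple(names), pi=pi)


@dataclass
class SeedVector:
    """Non-negative per-gene seed weights, normalized to sum to one."""

    weights: dict[str, float]

    def __post_init__(self):
        w = {g: float(v) for g, v in self.weights.items() if v > 0}
        if not w:
            raise ValueError("seed vector must have non-empty support")
        total = sum(w.values())
        self.weights = {g: v / total for g, v in w.items()}

    @classmethod
    def uniform(cls, genes: Iterable[str]) -> "SeedVector":
        genes = list(genes)
        return cls({g: 1.0 for g in genes})

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.weights)


@dataclass
class PropagationResult:
    """Converged per-(gene, layer) visiting probabilities and aggregates."""

    genes: list[str]
    layer_names: tuple[str, ...]
    visiting: np.ndarray  # shape (n_genes, n_layers), sums to 1
    iterations: int
    residual: float
    converged: bool

    @property
    def aggregated(self) -> dict[str, float]:
        """Per-gene score: arithmetic mean of visiting probability over layers."""
        means = self.visiting.mean(axis=1)
        return {g: float(means[i]) for i, g in enumerate(self.genes)}

    def visiting_probability(self, gene: str, layer: str) -> float:
        return float(
            self.visiting[self.genes.index(gene), self.layer_names.index(layer)]
        )


def _build_operator(
    m: MultiplexNetwork, kernel: LayerKernel
) -> tuple[list[str], sparse.csr_matrix, np.ndarray]:
    """Column-stochastic supra-transition operator over (gene, layer) states.

    Returns (gene order, sparse operator S, dangling coefficient vector d):
    one step maps a state distribution p to S @ p + (d . p) * p0, where d[s]
    is the intra-layer probability t[n, n] for states whose gene is isolated
    in layer n (their intra-layer mass is redirected to the restart vector).
    """
    genes = sorted(m.universe)
    gene_idx = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    L = len(kernel.layer_names)
    n_states = N * L

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    dangling = np.zeros(n_states)

    for n, lname in enumerate(kernel.layer_names):
        layer = m[lname]
        adj = layer.adjacency()
        offset_n = n * N
        # inter-layer switches: same gene, layer n -> layer m
        for mm in range(L):
            if mm == n or kernel.t[n, mm] == 0.0:
                continue
            offset_m = mm * N
            for gi in range(N):
                rows.append(offset_m + gi)
                cols.append(offset_n + gi)
                vals.append(kernel.t[n, mm])
        # intra-layer moves: degree-normalized within layer n
        stay = kernel.t[n, n]
        if stay > 0:
            for g, nbrs in adj.items():
                gi = gene_idx[g]
                share = stay / len(nbrs)
                for h in nbrs:
                    rows.append(offset_n + gene_idx[h])
                    cols.append(offset_n + gi)
                    vals.append(share)
        # genes with no edges in this layer: intra mass goes to restart
        isolated = m.universe - adj.keys()
        for g in isolated:
            dangling[offset_n + gene_idx[g]] = stay

    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states), dtype=float
    )
    return genes, S, dangling


def informed_rwr(
    m: MultiplexNetwork,
    kernel: LayerKernel,
    seeds: SeedVector,
    r: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    dangling_policy: str = "restart",
) -> PropagationResult:
    """Random walk with restart on the informed supra-adjacency operator.

    Seeds are spread uniformly across the informative layers; iteration stops
    when the L1 change drops below ``tol``.  ``dangling_policy`` controls the
    intra-layer move of a gene isolated in its current layer: ``"restart"``
    (default) sends that mass to the seed distribution, ``"stay"`` leaves it
    in place.
    """
    if not 0 < r <= 1:
        raise ValueError("restart probability r must be in (0, 1]")
    if dangling_policy not in ("restart", "stay"):
        raise ValueError("dangling_policy must be 'restart' or 'stay'")
    in_universe = seeds.support & m.universe
    if not in_universe:
        raise ValueError("no seed gene is present in the network universe")
    dropped = seeds.support - m.universe
    if dropped:
        warnings.warn(f"{len(dropped)} seed gene(s) outside the universe dropped")
        seeds = SeedVector({g: seeds.weights[g] for g in in_universe})

    genes, S, dangling = _build_operator(m, kernel)
    gene_idx = {g: i for i, g in enumerate(genes)}
    N, L = len(genes), len(kernel.layer_names)
    p0 = np.zeros(N * L)
    for g, w in seeds.weights.items():
        for n in range(L):
            p0[n * N + gene_idx[g]] = w / L

    if dangling_policy == "stay":
        S = S + sparse.diags(dangling)
        dangling = np.zeros_like(dangling)

    p = p0.copy()
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        step = S @ p + float(dangling @ p) * p0
        p_next = (1.0 - r) * step + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"propagation did not converge in {max_iter} iterations (L1 residual {residual:.3e})"
        )
    visiting = p.reshape(L, N).T  # (gene, layer)
    return PropagationResult(
        genes=genes,
        layer_names=kernel.layer_names,
        visiting=visiting,
        iterations=it,
        residual=residual,
        converged=converged,
    )


def solve_rwr_exact(
    m: MultiplexNetwork,
    kernel: LayerKernel,
    seeds: SeedVector,
    r: float = 0.7,
    dangling_policy: str = "restart",
) -> PropagationResult:
    """Direct linear-system solution of the RWR fixed point (dense; small inputs).

    Solves (I - (1-r) M) p = r p_0 with M the full one-step operator
    including dangling redirection.  Intended as an exact cross-check of the
    iterative solver on problems with few (gene, layer) states.
    """
    genes, S, dangling = _build_operator(m, kernel)
    gene_idx = {g: i for i, g in enumerate(genes)}
    N, L = len(genes), len(kernel.layer_names)
    p0 = np.zeros(N * L)
    for g, w in seeds.weights.items():
        if g in gene_idx:
            for n in range(L):
                p0[n * N + gene_idx[g]] = w / L
    p0 /= p0.sum()
    M = S.toarray()
    if dangling_policy == "restart":
        M = M + np.outer(p0, dangling)
    else:
        M = M + np.diag(dangling)
    A = np.eye(N * L) - (1.0 - r) * M
    p = np.linalg.solve(A, r * p0)
    return PropagationResult(
        genes=genes,
        layer_names=kernel.layer_names,
        visiting=p.reshape(L, N).T,
        iterations=0,
        residual=0.0,
        converged=True,
    )


def aggregate_and_rank(
    res: PropagationResult,
    seeds: SeedVector,
    restrict_to: Iterable[str] | None = None,
    include_seeds: bool = False,
) -> list[tuple[str, float]]:
    """Rank genes by mean visiting probability across informative layers.

    Seed genes are omitted from the ranking (``include_seeds=True`` retains
    them, as used for patient candidate lists where the causal gene may itself
    be phenotype-annotated).  Ties are broken by gene identifier, so the
    ranking is deterministic.
    """
    scores = res.aggregated
    if restrict_to is not None:
        restrict = set(restrict_to)
        scores = {g: s for g, s in scores.items() if g in restrict}
        if not scores:
            warnings.warn("restriction set is disjoint from the universe")
            return []
    if not include_seeds:
        scores = {g: s for g, s in scores.items() if g not in seeds.support}
        if not scores:
            warnings.warn("all candidate genes are seeds; empty ranking")
            return []
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
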