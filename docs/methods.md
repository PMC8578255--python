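# Methods

## Overview

`plexprop` implements a cross-scale multiplex network framework for rare
disease gene analysis. Genes are nodes; each *layer* encodes one kind of
relationship between them (co-expression, physical interaction, pathway
co-membership, annotation similarity, phenotype similarity). The pipeline has
three stages:

1. **Layer construction** — build each layer from its primary data and reduce
   dense weighted graphs to a sparse backbone.
2. **Disease-module relevance** — for each disease group and layer, quantify
   how strongly the disease's genes cluster (largest-connected-component
   z-score against a random-gene null), giving a per-layer relevance weight
   π.
3. **Informed propagation** — a random walk with restart over (gene, layer)
   states whose layer-switching probabilities are tilted so that the walker
   visits layer *m* with long-run probability π_m; the stationary visiting
   probability of a gene, averaged over layers, is its disease-association
   score.

## Layer construction

**Co-expression.** All-pairs Spearman correlation of a genes × samples
abundance matrix (TPM-like). Ties are handled by average ranks; genes with
zero variance are excluded before pairing because their correlation is
undefined. An edge is kept when |ρ| exceeds the cutoff (default 0.75), with
weight |ρ|. The absolute value is used as the backbone weight because the
sign has already been consumed by the cutoff; anti-correlation is as
informative a relationship as correlation here.

**Disparity backbone.** For dense weighted graphs (co-expression above the
cutoff, all-pairs semantic similarity), edge (i, j) receives, at each
endpoint i, a p-value p_ij = (1 − w_ij)^(k_i − 1), where w_ij is the weight
normalized over i's incident weights and k_i is i's degree — the probability
that a uniformly split weight budget would produce a share this large. The
edge survives when **both** endpoint p-values fall below α (default 0.05).
Two conventions are deliberate and loudly documented:

- *AND rule.* The original backbone-extraction literature keeps an edge when
  *either* endpoint finds it significant; this package defaults to requiring
  both, with the OR behaviour available via `or_rule=True`.
- *Degree-1 nodes.* A pendant edge has w = 1 and exponent 0; (1 − 1)^0 is
  defined as p = 1, so pendant edges are never significant on their own side
  and survive only under the OR rule.

On a graph whose weights are *flat* (every node distributes its strength
nearly uniformly, as in a perfectly balanced synthetic ontology) the filter
correctly keeps almost nothing at α = 0.05 — no edge is surprising. Real
similarity data are heterogeneous, which is what makes the filter selective
rather than empty.

**Core/tissue-specific split.** Across a stack of tissue co-expression
layers, edges present in at least `min_count` (default 5) layers form a
conserved core; each tissue layer minus the core is its tissue-specific
remainder. Every input edge lands in exactly one of {core, its layer's
specific set}.

**Ontology similarity layers.** Term information content is topological:
IC(t) = −ln(n_t / N) with n_t the number of descendants of t *including t
itself* (shared descendants in a DAG counted once) and N the root's count.
Including the term itself makes p(t) ∈ (0, 1], IC(root) = 0 and leaves
maximal — the standard convention. Natural log is used; any fixed base
rescales Resnik uniformly and leaves Lin invariant. Term similarity is
Resnik (IC of the most informative common ancestor, MICA, where ancestor
sets include the terms themselves) or Lin (2·IC(MICA)/(IC(t1)+IC(t2)),
defined as 0 when both terms are the root). Gene similarity is the
Best-Match Average over the genes' **direct** annotations,
(Σ colmax(S) + Σ rowmax(S)) / (m + n); the frequency variant counts shared
terms after ancestor closure. Direct annotations feed the BMA matrix and
the closure feeds only the frequency method, mirroring the two formulas'
own definitions. Gene pairs whose every best-match common ancestor is the
root are unrelated and removed before the disparity backbone is applied.

**Pathway co-membership.** Edge when two genes share at least `min_shared`
(default 5) gene sets of a GMT collection.

## Inter-layer similarity

Layers are compared by the edge overlap index
S_AB = |E_A ∩ E_B| / min(|E_A|, |E_B|), computed on the raw edge sets (not
restricted to shared nodes, matching the index's definition). Significance
comes from permuting each layer's node labels within its own node set — a
uniform bijection, which preserves each layer's degree sequence — 10 times
per layer by default, yielding 100 permuted pairings as the null. The
empirical p-value uses the +1/(n+1) correction so it is never zero; the
dissimilarity d_AB = 1 − S_AB is the input a layout method (e.g. non-metric
MDS) would consume.

## Network statistics

Global clustering is transitivity (3 · triangles / connected triples), not
average local clustering. Degree assortativity is the Pearson correlation of
excess degrees over directed edge ends, computed over all edges jointly on
disconnected graphs; it is NaN (never silently 0) when the degree variance is
zero. The local assortativity of node v is

ρ_v = j (j + 1) (k̄_v − μ_q) / (2 M σ_q²),

with j = deg(v) − 1, k̄_v the mean excess degree of v's neighbours, μ_q and
σ_q² the mean and **population** variance of the excess degree over the 2M
edge ends. Read this way the decomposition sums exactly to the global
assortativity (the defining invariant, checked to 1e−9); reading k̄ as a
global constant would make the sum identically zero. Annotation (literature)
bias is the Spearman correlation between degree and an external per-gene
count.

## Disease-module relevance

The module statistic is the size of the largest connected component (LCC) of
the subgraph induced by a disease's genes on a layer. The null draws
`n_rand` (default 1000, p-resolution 1/1001) equally sized node sets
uniformly **from the layer's own node set** — not the multiplex universe —
so coverage differences between layers do not distort the null. The z-score
uses the null's sample standard deviation (ddof 1); the empirical p counts
null ≥ observed with the +1/(n+1) correction. Across a disease × layer table,
Benjamini–Hochberg adjustment is applied jointly over all testable cells
(per-layer families behind a flag); cells with fewer than two mappable genes
are carried as explicit not-testable sentinels. Above the percolation
threshold the null LCC is approximately normal, which motivates the z-score
summary; the empirical p does not rely on normality.

## Informed propagation

Layers with z ≥ 1.645 (the 95th percentile of the standard normal) are
*informative*; π_m = z_m / Σ z over the informative set, zero elsewhere.
When no layer passes — or every z is undefined — the profile falls back to
uniform weights over all layers, flagged on the result. Uninformative layers
are removed from the state space entirely (equivalent to zero visiting
probability, and cheaper).

Layer switching is a Metropolis chain over the L informative layers:
t[n→m] = (1/L) min(1, π_m/π_n) off-diagonal, diagonal absorbing the
remainder. This is the orientation for which detailed balance
π_n t[n→m] = π_m t[m→n] holds exactly and π is the stationary distribution —
both verified to 1e−12 as invariants, since the defining equations can be
written with either index order.

One step of the walk: from state (gene g, layer n), with probability t[n→n]
move along a degree-normalized edge of layer n (edge weights are not used;
post-backbone layers are unweighted), with t[n→m] jump to g's copy in layer
m. If g has no edges in layer n, the intra-layer mass is redirected to the
restart vector, keeping the operator stochastic (a stay-in-place variant is
available). Restart: p_{t+1} = (1 − r) S̃ p_t + r p_0 with r = 0.7. Seed
weight is split equally across the informative layers. Convergence is an L1
change below 1e−8 (capped at 10,000 iterations and flagged if hit; exact
equality of successive iterates is not achievable in floating point). The
iterative solution matches a direct linear solve of the fixed point to
better than 1e−8, and with uniform π the informed walk reduces exactly to
the uninformed multiplex walk.

A gene's score is the arithmetic mean of its visiting probability across the
informative layers. Seed genes are omitted from rankings by default; in the
patient setting candidate genes that are themselves seeds are retained
(toggleable), because a causal gene is often itself phenotype-annotated.
Ties break lexicographically, making rankings deterministic.

## Evaluation

AUROC is rank-based (Mann–Whitney with average ranks; ties contribute 1/2),
hence invariant under monotone transforms. k-fold retrieval (k = 10) shuffles
a group's mappable genes deterministically by seed; per fold the remaining
genes seed the walk, held-out genes are positives, and negatives are all
universe genes neither in the group nor seeding — seeds are excluded because
they are omitted from rankings. Four layer-selection regimes are compared:
a designated single reference layer (generalizing "the PPI" so any layer can
play that role), the single highest-z layer, all layers with uniform π, and
the relevant layers with normalized-z π. The headline summary is the median
over folds.

Patient prioritization seeds the walk with genes annotated to the patient's
phenotype terms, weighted by the number of patient terms each gene matches
(normalized), runs the informed walk with the disease group's π, and ranks
the candidate list. Per-patient top-k membership is the primary report;
pooling candidates across patients into one AUROC is available as an option.
Gene-level baselines rank candidates by a single feature (pathway count,
expression level in a caller-specified context, literature count, or BMA
phenotype similarity to the patient's terms); missing features rank last.

## Synthetic fixtures

The generators produce inputs with exactly the structure the method assumes,
so every stage is testable without external data:

- **Planted-module multiplex** (default: 300 genes, 6 layers, background
  edge probability 0.02, a 20-gene module wired at 0.35 in 3 relevant
  layers, connectivity guaranteed by a random spanning tree). The defaults
  mirror the study-scale ratios at desk size; 20 is about the smallest
  module size detectable on a PPI-scale network. Backgrounds are
  Erdős–Rényi, with a heavier-tailed (gamma-propensity) variant behind a
  flag for robustness checks of the LCC null.
- **Block expression matrices**: one latent profile per block; each gene is
  latent·0.9 plus N(0, 0.3²) noise, exponentiated to a TPM-like scale. The
  implied within-block correlation (≈0.9) comfortably exceeds the 0.75
  cutoff while between-block pairs are independent.
- **Balanced toy ontologies** with leaf-level annotations; an explicit gene
  list can be chunked onto leaves so that related genes share terms.
- **Simulated solved cases**: the causal gene is drawn from the module; the
  patient's terms are the causal gene's annotations plus noise leaves drawn
  from off-module terms; decoys are sampled off-module, *preferentially
  including genes annotated to the noise terms*. This last choice emulates
  real candidate lists, which survive variant filtering partly because they
  relate to the patient's symptoms — without such confounders a phenotype-
  similarity baseline would be trivially perfect and the comparison
  meaningless.

What the fixtures do **not** emulate: scale-free degree distributions,
correlated layer topologies, annotation-depth heterogeneity, and the
literature bias of curated interactomes. Passing tests therefore demonstrate
the algorithmic correctness and the qualitative behaviour of the method
(relevant layers detected, module genes retrieved, causal genes ranked
high), not its headline performance numbers on real cohorts, which depend on
access-restricted data.

## Numerical choices and degenerate inputs

- Undefined statistics (assortativity of regular graphs, z with a degenerate
  null) are NaN sentinels, never 0; NaN z-scores count as uninformative.
- Monte-Carlo z-scores use sample sd (ddof 1); excess-degree variance in the
  assortativity decomposition uses population variance (what makes the sum
  identity exact).
- Empirical p-values use the +1/(n+1) correction (never exactly 0).
- Probabilities and scores are serialized at 10 significant digits so
  determinism checks are meaningful across platforms.
- Gene identifiers are case-sensitive opaque strings; identifier mapping is
  the caller's responsibility.
- Problem sizes in the test and acceptance studies (20 replicate fixtures,
  1000-draw nulls, 10-fold CV on the 300-gene fixture) were chosen as the
  smallest at which the planted structure is unambiguous.

## Known limitations

- The disparity filter's AND rule removes all pendant edges by design; use
  the OR rule when peripheral nodes must stay connected.
- LCC significance is meaningless for groups with fewer than two mappable
  genes per layer (reported as not-testable rather than guessed).
- The walk uses degree normalization only; weighted intra-layer steps are
  not implemented because backboned layers are unweighted.
- On balanced synthetic ontologies the similarity backbone is empty at
  strict α (flat weight profiles); this is a property of the filter, not a
  bug, and disappears on heterogeneous data.
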