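# plexprop

Cross-scale multiplex gene networks and informed network propagation for
rare-disease gene prioritization.

Rare genetic diseases manifest at different levels of biological
organization — some disrupt physical protein complexes, others regulatory
co-expression programs, pathways, or phenotype-level similarity clusters. A
single interactome therefore under-serves most diseases. `plexprop` is for
computational biologists and clinical-genomics analysts who want to (a)
build a *multiplex* network whose layers each capture one biological scale,
(b) measure, per disease, which layers actually carry signal, and (c)
exploit that measurement when propagating from known disease genes to rank
new candidates — including the candidate variants of an individual patient.

## The method

**Layer relevance.** For disease *d* and layer *m*, the module statistic is
the size of the largest connected component (LCC) of the disease genes'
induced subgraph. Against a null of equally many uniformly drawn nodes from
the same layer it yields a z-score *z_dm* and an empirical p-value
(Benjamini–Hochberg adjusted across the disease × layer table). Layers with
*z_dm* ≥ 1.645 are *informative*, and the relevance weight is the normalized
z-score

&nbsp;&nbsp;&nbsp;&nbsp;π_dm = z_dm / Σ_m z_dm,&nbsp;&nbsp;Σ_m π_dm = 1.

**Informed propagation.** A random walker lives on (gene, layer) states.
Layer switching follows a Metropolis kernel obeying detailed balance
π_m p(m|n) = π_n p(n|m), realized as p(m|n) = (1/L)·min(1, π_m/π_n), so the
walker visits layer *m* with long-run probability π_m. Within a layer it
moves along degree-normalized edges. With restart probability *r* = 0.7 it
returns to the seed distribution p₀:

&nbsp;&nbsp;&nbsp;&nbsp;p_{t+1} = (1 − r) S̃ p_t + r p₀,

with S̃ the relevance-weighted supra-adjacency operator. A gene's score is
its mean visiting probability across layers; seed genes are omitted from
rankings. Patient-specific runs seed the walk with genes annotated to the
patient's phenotype terms (weighted by how many patient terms each gene
matches) and restrict the ranking to the patient's candidate genes.

The package also provides the surrounding toolkit: co-expression layer
construction (Spearman |ρ| > 0.75), disparity-filter backbone extraction
(p_ij = (1 − w_ij)^(k−1), both endpoints < α), ontology semantic-similarity
layers (Resnik/Lin with Best-Match Average), pathway co-membership layers,
inter-layer edge-overlap similarity with permutation significance, layer
statistics (density, transitivity, local assortativity, literature bias),
cross-validated retrieval benchmarks, and deterministic synthetic fixtures
for all of the above.

## Worked example

Fit the relevance model on a synthetic multiplex with a 20-gene disease
module planted in 3 of 6 layers, then rank genes by informed propagation:

```python
from plexprop import MultiplexDiseaseModel
from plexprop.simulate import make_multiplex, MultiplexSpec

net, group, relevant = make_multiplex(MultiplexSpec(seed=1))
results = MultiplexDiseaseModel(net, [group]).fit(n_rand=1000, seed=1)
print(results.summary()[["layer", "lcc", "null_mean", "z", "p", "p_adj", "stars"]])
```

```
       layer  lcc  null_mean      z     p  p_adj stars
coexpr_brain   20      3.165 13.413 0.001  0.002    **
         ppi   20      3.249 12.497 0.001  0.002    **
     pathway   20      3.299 11.250 0.001  0.002    **
coexpr_liver    2      2.949 -0.790 0.983  0.983
       go_bp    4      2.954  0.851 0.240  0.360
         hpo    2      2.949 -0.787 0.975  0.983
```

The module's LCC spans all 20 genes in the three layers that carry it
(`z ≈ 11–13`, adjusted p = 0.002), while in the background-only layers it
looks like a random gene set (LCC 2–4, p ≫ 0.05). The fitted relevance
profile keeps exactly the informative layers:

```python
>>> results.relevance_profile(group.id).pi
{'coexpr_brain': 0.361, 'ppi': 0.336, 'pathway': 0.303,
 'coexpr_liver': 0.0, 'go_bp': 0.0, 'hpo': 0.0}
```

and `results.rank_genes(group.id)` returns the non-seed genes ordered by
visiting probability (here led by `G244` at 3.6e-4, the genes best connected
to the module in the informative layers).

The same steps run from the shell:

```sh
plexprop simulate --seed 1 --out fixture/
plexprop modules --multiplex fixture/manifest.json --groups fixture/groups.gmt \
    --seed 1 --out relevance.tsv
plexprop propagate --multiplex fixture/manifest.json --seeds seeds.tsv \
    --relevance relevance.tsv --group planted --out ranking.tsv
```

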