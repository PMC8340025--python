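# nmfna

Joint non-negative matrix factorization of paired omics co-expression
networks, with a graph-regularized ("manifold") penalty, module extraction
and centrality-based characteristic-gene ranking.

## The problem

Two omics layers — say DNA methylation beta values `X1 (m1 × n)` and
copy-number values `X2 (m2 × n)` — are measured on the same `n` samples.
Interactions among features are captured by three co-expression networks
built from the absolute Pearson correlation coefficient (|PCC|):

* `R11 (m1 × m1)` — within layer 1,
* `R22 (m2 × m2)` — within layer 2,
* `R12 (m1 × m2)` — across the two layers.

The package decomposes all three networks *simultaneously* by symmetric
non-negative tri-factorization:

```
min  ‖R11 − G1 S11 G1ᵀ‖²F + α ‖R12 − G1 G2ᵀ‖²F + β ‖R22 − G2 S22 G2ᵀ‖²F
     + λ1 Tr(G1ᵀ L1 G1) + λ2 Tr(G2ᵀ L2 G2)
s.t. G1, G2, S11, S22 ≥ 0
```

where `G1 (m1 × k)` and `G2 (m2 × k)` locate `k` gene modules in the two
layers, the symmetric `S11`/`S22` carry module–module association strengths,
`α = m1/m2` and `β = (m1/m2)²` balance the three reconstruction terms, and
`Li = Di − Zi` is the graph Laplacian of a sparse p-nearest-neighbour
affinity graph `Zi` over layer *i*'s features. The trace penalties force
features that are neighbours in the affinity graph to stay close in the
factor space, so the factorization respects the geometry of the original
networks. The problem is solved by seeded multiplicative updates: every
factor stays non-negative and the objective never increases.

Downstream, each column of `G1`/`G2` is z-score normalized and the genes
with z ≥ 2 form one module; the largest module per layer is its *core
module*. Inside a core module, weak edges (|PCC| ≤ 0.8) are removed and each
gene `v` is ranked by the multimeasure score

```
MS(v) = DC(v) · BC(v) / EC(v)
```

(degree × betweenness / eccentricity): hub genes that sit on many shortest
paths and close to everything score highest and are reported as
*characteristic genes*.

Baselines with the same interface: plain `NMF` (`X ≈ UV`), `TriNMF`
(`X ≈ USV`) and `NetNMF` (the joint objective with λ = 0).

Who this is for: anyone integrating two feature-by-sample omics matrices
who wants correlated gene modules that agree across the layers, plus a
ranked list of hub genes per module — without hand-rolling the solvers.

## Worked example

```python
from nmfna import *

# paired synthetic layers with 3 planted, cross-layer-coupled modules
X1, X2, truth = generate_paired_omics(m1=120, m2=150, n=100, k_true=3,
                                      rho=0.75, sigma=0.25, seed=1)

R11 = pearson_network(X1, "within_layer1")
R22 = pearson_network(X2, "within_layer2")
R12 = cross_network(X1, X2)
reg1 = build_regularizer(R11, p=5)       # p-NN affinity + Laplacian
reg2 = build_regularizer(R22, p=5)

model = NMFNA(R11, R12, R22, k=3, regularizer1=reg1, regularizer2=reg2,
              lambda1=0.03, lambda2=0.03, seed=0)
res = model.fit()
print(res.summary())

ms1, ms2 = res.extract_modules(threshold=2.0)
print("layer-1 module sizes:", ms1.sizes())
print("layer-1 recovery:", evaluate_recovery(ms1, truth))

core = core_module(ms1)
table = score_network(filter_network(core.subnetwork, 0.8))
print(table.head(5).to_string(index=False))
print("top 3 characteristic genes:", top_characteristic_genes(table, 3))
```

prints

```
NMFNA factorization results
============================================
rank k:              3
iterations:          200
initial objective:   58258.4
final objective:     293.683
objective reduction: 99.4959%
relative recon error:0.4557
monotone descent:    True
seed:                0
factors:
  G1: 120x3  min=5.02e-16 max=0.999
  G2: 150x3  min=2.04e-15 max=1.02
  S11: 3x3  min=0.000422 max=1.36
  S22: 3x3  min=1.59e-05 max=1.29
layer-1 module sizes: [12, 12, 12]
layer-1 recovery: <RecoveryMetrics mean_jaccard=1.000 precision=1.000 recall=1.000>
gene_id   DC       BC  EC        MS  rank
me00015 11.0 1.242063 1.0 13.662698     1
me00017 11.0 1.242063 1.0 13.662698     2
me00023 11.0 1.242063 1.0 13.662698     3
me00021 10.0 0.964286 2.0  4.821429     4
me00018 10.0 0.563492 2.0  2.817460     5
top 3 characteristic genes: ['me00015', 'me00017', 'me00023']
```

Reading the output: the solver ran its default 200 multiplicative sweeps and
reduced the objective by 99.5% while descending monotonically; the residual
reconstruction error reflects the noise floor of the data, not a failed fit.
All three planted 12-gene modules in layer 1 are recovered exactly
(mean best-Jaccard 1.0). Inside the core module, the three genes that keep
degree 11 and positive betweenness after the |PCC| > 0.8 edge filter come
out as the top characteristic genes.

The same flow is available from the shell:

```sh
nmfna simulate --m1 120 --m2 150 --n 100 --k 3 --seed 1 --out sim/
nmfna run config.yaml          # full pipeline from a YAML config
nmfna score --network module.tsv --pcc-threshold 0.8 --top 10
```

`nmfna run` writes edge lists for the three networks, factor matrices, the
objective trace, modules in GMT format, ranked score tables and a JSON run
manifest that is sufficient to reproduce the run bit-for-bit from its seed.

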