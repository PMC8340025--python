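# Methods

This note documents the models, the numerical choices behind them, what the
synthetic generator does and does not emulate, and the known limitations.

## Networks

Within-layer networks are absolute Pearson correlations between feature
rows, `R[i,j] = |PCC(x_i, x_j)|`, with unit diagonal; the cross-layer
network is the rectangular analogue. Absolute values are the default because
every matrix entering the factorization must be non-negative and a strong
negative co-expression is still a strong interaction; `signed_mode="drop"`
zeroes negative correlations instead, for users who consider sign-flips
qualitatively different. Zero-variance feature rows have no defined
correlation and are dropped with a logged warning rather than imputed.
Estimating a correlation requires at least 3 samples; in practice far more
are needed for stable networks, and the package takes the matrices as given.

The graph regularizer is built from the within-layer network itself: each
node keeps its `p` strongest off-diagonal neighbours (stable sort, so ties
break toward the lowest index), the kept edges are symmetrized by union with
their similarity weights carried over, and `L = D − Z` with `D` the diagonal
of column sums. Default `p = 5`, the common choice in graph-regularized NMF:
large enough to connect module-mates, small enough to stay sparse and not
smooth across module boundaries. Heat-kernel reweighting is deliberately not
used; the |PCC| weights are already in [0, 1]. Self-loops are excluded
everywhere (`diag Z = 0`), and the within-network diagonal is kept at 1 for
factorization input but zeroed for all graph analyses, since self-loops
distort degree and betweenness.

## Solvers

All four solvers are multiplicative-update schemes from uniform(0, 1)
initialization (S-factors symmetrized at the draw), driven by a single seed;
there is no other source of randomness, so identical configurations produce
bit-identical trajectories. Every update denominator carries an additive
guard `eps = 1e-10` against 0/0 when a factor row collapses. The default
iteration budget is 200 sweeps with no early stopping — at the problem sizes
this package targets the objective is essentially flat well before that —
and an optional relative-change tolerance (`tol`) stops earlier when set.

* **NMF** `X ≈ UV`: the classical alternating multiplicative rules.
* **TriNMF** `X ≈ USV`: the default `update_rule="ls"` uses the
  least-squares tri-factorization rules (each factor's update is the
  two-factor rule with the other factors absorbed), which provably never
  increase `‖X − USV‖²F`. The orthogonal-style variant with denominators
  such as `U Uᵀ X Vᵀ Sᵀ` is kept as `update_rule="printed"`; without the
  square-root damping that usually accompanies it, it takes larger steps
  and can overshoot, which measurably breaks monotone descent on random
  instances — hence it is not the default.
* **NetNMF / NMFNA** share one update loop. Per sweep the order is G1, G2,
  S11, S22, each using the freshest values. The G-updates are

  ```
  G1 ← G1 ∘ (α R12 G2 + 2 R11 G1 S11 + 2 λ1 Z1 G1)
          ⁄ (2 G1 S11 G1ᵀG1 S11 + α G1 G2ᵀG2 + 2 λ1 D1 G1)
  G2 ← G2 ∘ (α R12ᵀ G1 + 2 β R22 G2 S22 + 2 λ2 Z2 G2)
          ⁄ (2 β G2 S22 G2ᵀG2 S22 + α G2 G1ᵀG1 + 2 λ2 D2 G2)
  ```

  The Laplacian enters split across numerator (Z) and denominator (D), the
  standard construction that preserves non-negativity. The λ2 terms carry
  the same factor 2 as the λ1 terms, which is what the gradient of
  `λ2 Tr(G2ᵀ L2 G2)` dictates; `strict_g2_update=True` drops that factor on
  the G2 side for users who want the asymmetric variant. The S-updates
  apply the multiplicative ratio to **all** entries of S11/S22 by default
  (`s_update="full"`); restricting the update to the diagonal
  (`s_update="diagonal"`) is available but breaks monotone descent and
  leaves off-diagonal associations frozen at their initialization, so it is
  not recommended.

With `λ1 = λ2 = 0` the NMFNA loop adds exact zero matrices and is therefore
bit-identical to NetNMF per iteration — this reduction is tested, as is the
fixed-point property that a perfect factorization is left unchanged (all
update ratios equal 1) up to the `eps` guard.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | required | factor rank = max number of modules per layer; must be `< min(m1, m2)` |
| `alpha` | `m1/m2` | weight of the cross-layer reconstruction term |
| `beta` | `(m1/m2)²` | weight of the layer-2 reconstruction term |
| `lambda1`, `lambda2` | 0 | manifold-penalty strengths; 0.03 is the reference working value, grid-searchable over [0, 0.1] |
| `max_iter` | 200 | multiplicative sweeps |
| `tol` | 0 | optional relative-change early stop |
| `seed` | 0 | initialization seed (sole randomness) |
| `eps` | 1e-10 | denominator guard |

`select_k_svd` offers a data-driven rank: it takes the descending singular
values of a network, computes second differences `d2_i = s_{i−1} − 2 s_i +
s_{i+1}` from the second position, treats `|d2| ≤ 1e-6·s_1` as zero, and
returns the first index whose curvature sign differs from the previous one
(starting from zero curvature) — the first inflection of the spectrum. An
exactly linear spectrum has no inflection and falls back to `rank/2` with a
warning. The pipeline applies it to `R11` when asked.

## Modules, TMS and λ selection

Each factor column is z-score normalized with the **population** standard
deviation (the column is the full population being standardized, not a
sample); genes with `z ≥ 2` form the column's module, so modules are the
~2% upper tail of each latent dimension. A gene may belong to several
modules; zero-variance columns and columns with no gene over the threshold
yield no module. The largest module per layer is the core module, ties going
to the lowest column index.

Total module similarity between two module sets sums
`|Mx ∩ My| / min(|Mx|, |My|)` over all ordered pairs. For λ selection the
package runs NMFNA per grid point from a shared seed and scores each run's
modules, per layer and summed, against the λ = 0 baseline run
(`mode="baseline"`): the measure is module *stability* as regularization is
introduced. Scoring consecutive grid points against each other is available
(`mode="consecutive"`). Ties resolve to the smaller λ. Note that including
0 in the grid makes the baseline compare with itself and trivially win;
a grid starting above 0 is the meaningful use.

## Gene scoring

The module subnetwork is filtered (edges with weight ≤ 0.8 removed, strictly
greater kept) and treated as an **unweighted** simple graph: DC is the raw
degree, BC the unnormalized shortest-path betweenness with even split over
equal-length paths, EC the eccentricity within the node's connected
component. Normalizing BC would rescale MS without changing ranks, so the
raw pair counts are kept and documented. Raw eccentricity sits in the
denominator of `MS = DC·BC/EC`, so low-eccentricity (central) genes score
higher, matching the hub-gene intent; `ec_mode="reciprocal"` inverts it for
the reading of "eccentricity centrality" as 1/eccentricity. A weighted mode
(distance = 1/weight, DC = strength) is available behind a flag. Isolated
nodes have no eccentricity and are excluded from the ranking with a log
entry; a fully filtered network yields an empty table rather than an error.
Rank ties break lexicographically by gene id, so output is deterministic.

## Synthetic data

The generator plants `k_true` disjoint modules per layer (default size 10%
of the layer's genes, minimum 5). Module pair `j` across the two layers
shares one latent sample factor `f_j ~ N(0,1)ⁿ`; a member row is
`ρ·f + (1−ρ)·η` with per-gene noise `η ~ N(0,1)ⁿ`, background rows are pure
noise, global measurement noise `σ·ξ` is added to every entry, and each row
is min-max rescaled to [0, 1] (a methylation-beta-like range — harmless,
since Pearson correlation is invariant to per-row affine maps). `ρ` therefore
sets within-module and cross-layer co-expression jointly; at the reference
scenario (`m1=120, m2=150, n=100, k_true=3, ρ=0.9, σ=0.1`) the full pipeline
recovers the planted modules with mean best-Jaccard above 0.9.

What the generator does **not** emulate: probe-level annotation structure,
tumor/normal composition, heavy-tailed or bounded-support marginals,
overlapping or nested modules, correlated background, and the 20k-feature
scale of real arrays. Passing tests therefore demonstrate correctness of the
machinery and recoverability under clean planted structure, not performance
on real cohorts.

Problem sizes used in the test-suite sweeps — (m1, m2, n, k) = (40, 50, 20, 4)
for solver properties, the reference scenario above for end-to-end recovery,
graphs of ≤ 30 nodes for the centrality oracle — are chosen so the full
suite and the acceptance script each complete in seconds while exercising
every code path at non-trivial rank.

## Degenerate inputs and tie-breaks

* Zero matrix into NMF: the first sweep zeroes the factors; the objective is
  0 from iteration 1.
* Constant factor columns lie in the Laplacian null space: the manifold
  penalty of a constant embedding is exactly 0.
* k-NN ties, core-module ties, MS ties, λ ties: all broken deterministically
  (lowest index / lexicographic / smaller λ) and logged where they matter.
* Matrices are validated on construction: negative entries, shape
  mismatches, misaligned sample ids and over-large `k` fail fast with typed
  exceptions.

## Known limitations

* Monotone descent for the joint solvers is an empirical property of these
  update rules (verified across broad seeded sweeps), not a theorem proved
  here; the NMF and least-squares TriNMF rules carry the classical
  guarantees.
* The multiplicative updates converge slowly near a minimum (they cannot
  turn an entry exactly zero back on); planted-factorization recovery to
  `1e-2` relative error needs a few thousand sweeps for TriNMF.
* Only two layers are supported; the objective does not generalize to three
  or more without re-deriving the updates.
* Module–module association matrices S11/S22 are reported but not further
  analyzed.
* `select_k_svd` reacts to the first curvature change of the spectrum, which
  on noisy real data tends to fire early; treat it as a starting point, not
  an oracle.
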