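# Methods

## Model

A G-component finite mixture whose components are simplified R-vine copula
densities with parametric margins:

    h(x; δ) = Σ_{g=1}^G π_g · h_g(x; α_g),      Σ π_g = 1,  0 < π_g < 1,

    h_g(x) = ∏_{j=1}^n f_gj(x_j; φ_gj)
           · ∏_{i=1}^{n−1} ∏_{e ∈ E_i} c_e( H_{e_m|D_e}, H_{e_k|D_e}; θ_e ).

The conditional cdf arguments H_{·|D_e} are built recursively from
h-functions (partial derivatives of the lower-tree pair-copula cdfs).  Only
the *simplified* form is implemented: a conditional pair-copula's family and
parameters do not depend on the value of the conditioning variables, which is
the standard tractable assumption for vines.

Pair-copula catalogue: independence, Gaussian, Student-t, Clayton, Gumbel,
Frank, Joe; Clayton/Gumbel/Joe additionally in 90/180/270-degree rotations so
negative and survival-type dependence is reachable.  Margin catalogue:
normal, log-normal, gamma (shape/rate), logistic, Student-t (location-scale);
positive-support families are offered only for strictly positive columns.

## Sparsity: pruning and truncation per cluster

*Pruning.*  Before a pair-copula is fitted to an edge, the empirical
Kendall's tau of its (conditional) pseudo-observations is tested with the
asymptotic normal test T = |τ̂|·√(9n(n−1)/(2(2n+5))) vs the (1−α/2) normal
quantile.  Non-rejected edges receive the independence copula.  Default
α = 0.05 (no level is canonical in the literature; configurable).

*Truncation.*  Trees are fitted incrementally.  After each tree the modified
BIC for vines is evaluated:

    mBICV = −2ℓ̂ + ϑ·ln T − 2 Σ_{i=1}^{n−1} [ q_i ln(ψ₀^i) + (n−i−q_i) ln(1−ψ₀^i) ],

with ℓ̂ the copula log-likelihood, ϑ the number of copula parameters, q_i the
count of non-independence pair-copulas in tree i, and ψ₀^i = ψ₀^i the
geometrically decaying prior probability that a tree-i edge is
non-independent (default ψ₀ = 0.9).  The search stops at the first level
whose criterion fails to improve; everything deeper is set to independence.
Each mixture component gets its own level — the point of the method: clusters
with genuinely deep conditional dependence keep their trees, simple clusters
collapse to (near-)Markov trees, and the total parameter count δ (margins +
pair-copulas + G−1 weights) drops accordingly.

## Estimation pipeline

1. k-means (10 restarts, standardized data) partitions the data.
2. Per cluster: margins by (weighted) MLE with AIC family selection; the
   probability integral transform yields copula data (two-stage "inference
   functions for margins" estimation).
3. Per cluster: greedy structure selection — maximum spanning tree on
   |τ̂| per tree, restricted to proximity-admissible pairs from tree 2 on —
   with pruning at each edge, AIC pair-copula family choice, and mBICV
   truncation.
4. ECM until the observed log-likelihood's relative change falls below
   `tol = 1e-4` (at most `max_iter = 100` iterations):
   * E-step: responsibilities in log space (log-sum-exp);
   * CM-1: π_g = Σ_t r_tg / T (closed form);
   * CM-2: per-component, per-variable Nelder-Mead update of the margin
     parameters against the full weighted component log-likelihood — the
     margins enter the copula arguments, so the vine term is part of the
     objective.  One coordinate pass per iteration; an update is kept only if
     it improves the objective (conditional ascent is all ECM needs);
   * CM-3: weighted sequential per-edge MLE through each cluster's trees,
     with copula data refreshed from the updated margins; families,
     structures, pruned edges and truncation levels stay frozen.  Reverted
     per component if the weighted log-likelihood would decrease (sequential
     estimation is not exactly joint maximization).
   These guards make the observed log-likelihood non-decreasing across
   iterations, which the tests assert on every run.
5. Hard assignment by maximum responsibility (ties to the lower index).
6. Final refit: margins, structure, pruning and truncation re-selected per
   hard cluster.  The reported BIC is −2ℓ + δ·ln T for the final model.

Degenerate cases: empty or tiny initial clusters trigger re-initialization
with a new k-means seed (bounded retries); a component receiving zero total
responsibility raises a descriptive error rather than silently collapsing.

## Numerical choices

* Pseudo-observations and cdf values are clipped to [1e-10, 1−1e-10] before
  copula evaluations; this prevents infinite tail densities at the boundary.
* h-function convention: h(u|v) = ∂C(u,v)/∂v ("conditioning on the second
  argument"); the convention is documented because the literature rarely
  states one.  Inverses are closed-form where available (Gaussian, Student-t,
  Clayton, Frank) and 60-step monotone bisection otherwise (error < 1e-12).
* Student-t copula df is bounded to [2.05, 30] and estimated jointly with the
  correlation by bounded quasi-Newton from a tau-inversion start; unbounded
  df is practically unidentifiable from moderate samples.
* One-parameter copula MLEs use bounded scalar minimization (tolerance 1e-6)
  from the tau-inversion start; Kendall tau maps are closed-form except
  Frank (Debye-function integral) and Joe (rapidly converging series).
* MST ties are broken by lexicographic edge order, and every random step is
  seeded, so identical inputs give identical models.
* Sampling uses the inverse-Rosenblatt transform organized by a peeling
  decomposition of the vine: variables are removed leaf-by-leaf from the top
  tree, and re-added in reverse during simulation, pushing each uniform
  driver back through the h-function chain of its edges.  Structurally
  truncated models are completed with independence trees first (any valid
  completion yields the same distribution).

## The synthetic-data generator

`synthetic.default_scenario()` emulates a two-cluster, 6-dimensional design
with 300 (or 500) observations per cluster.  Margins per cluster:

| var | cluster 1        | cluster 2             |
|-----|------------------|-----------------------|
| 1   | Normal(1, 0.4)   | Normal(1.5, 0.2)      |
| 2   | Normal(10, 4)    | Gamma(1.5, 0.5)       |
| 3   | Normal(1.2, 0.2) | Normal(1, 0.3)        |
| 4   | Gamma(0.9, 0.9)  | Gamma(1.5, 0.25)      |
| 5   | Normal(1.2, 0.45)| Normal(1.3, 0.3)      |
| 6   | Normal(0.8, 0.8) | Log-normal(1.2, 0.25) |

Cluster 1 follows a D-vine (path) structure, cluster 2 a C-vine (star), both
truncated at tree 2, with one pruned (independence) pair in tree 2 of each —
so the generator exercises exactly the structure the method is built to
recover.  The pair-copula table (see
`src/vinemix/scenarios/two_cluster_6d_synthetic.json`) is a synthetic
stand-in fixed once for this package: families span symmetric (Gaussian,
Frank, Student-t) and asymmetric (Clayton, Gumbel, Joe, rotations) shapes
with tree-1 Kendall taus between 0.41 and 0.56 and weaker tree-2 dependence
(|τ| ≈ 0.2–0.43) — moderate-to-strong dependence typical of applied copula
studies.

What the generator does **not** emulate: measurement noise or outliers,
ties/discreteness, margins outside the package's catalogue, non-simplified
conditional dependence, and cluster overlap beyond what the margin table
implies.  Passing tests therefore demonstrate correctness of the machinery
and recoverability under the stated design, not robustness to arbitrary real
data.

On this design, k-means (which ignores margins and dependence) misclassifies
around 7–9% of observations, the Gaussian mixture a fraction of a percent,
and the truncated vine mixture essentially none — the ordering, and the
magnitudes, one expects when cluster differences live in margins and
dependence shape rather than in mean separation alone.

## Design decisions that were genuinely open

* **Pruning before family selection** at each edge: cheaper, and consistent
  with treating weak-dependence pairs as independent wholesale.
* **Selection-then-test interplay:** the MST picks the strongest |τ̂| pairs,
  so tested edges are extremes of several candidates and reject independence
  more often than the nominal α on null data; the type-I level is asserted
  for the test itself, sparsity (not nominal calibration) for the pipeline.
* **ECM refreshes copula data every iteration** from the updated margins:
  the margin parameters enter the component density through the PIT, so the
  conditional-maximization objective is only coherent if the transforms
  track the margins.
* **Fvcmm variant via configuration** (`truncation=1, final_truncation="none",
  prune_alpha=0`): fixed Markov-tree initial fits with a full final refit,
  kept as a configuration rather than a separate code path.
* **G is assumed known.**  BIC is reported so users can scan G externally.
* **Gamma margins are (shape, rate)**; switchable to (shape, scale).

## Problem sizes used in the shipped studies

The replicate studies run 10 replicates per sample-size variant (300 and 500
observations per cluster), 50 replicates for the truncation-recovery
property, and 1000 replicates for the type-I-error property — sizes chosen to
keep Monte-Carlo standard errors small relative to the assertions they feed.

## Known limitations

* Greedy (Dissmann-style) structure selection does not always recover a true
  D-vine path when induced marginal dependence rivals direct dependence; in
  that case extra trees absorb the mismatch and the selected truncation level
  can exceed the generating one (observed for the D-vine cluster of the
  default scenario: level 3 instead of 2).  Density fit and clustering
  quality are barely affected — this is a property of all greedy vine
  selection, not of the mixture layer.
* Margins and pair-copulas are parametric only; no empirical/kernel variants.
* The ECM ascent guarantee is conditional ascent per step, not global
  optimality; different k-means seeds can reach different local optima.
* Weighted Kendall's tau (used when structure selection is run with soft
  weights) costs O(T²); the main pipeline only selects structures on
  hard-assigned clusters, where the O(T log T) estimator applies.
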