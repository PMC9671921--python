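# vinemix

Model-based clustering with finite mixtures of **pruned, truncated R-vine
copulas**.

## The problem

Classical model-based clustering (e.g. Gaussian mixtures) ties every cluster
to one parametric shape: elliptical contours, normal margins, linear
dependence.  Real multivariate data — biomarker panels, morphometric
measurements, spectral features — routinely mix skewed margins with
asymmetric, tail-heavy dependence that differs between clusters.  Vine copula
mixtures remove both restrictions: each cluster g has its own weight π_g, its
own parametric margin per variable, and its own regular-vine (R-vine) copula
built from bivariate pair-copulas, so the component density is

    h_g(x) = ∏_j f_gj(x_j; φ_gj) · ∏_{trees i} ∏_{edges e}
             c_{e_m,e_k|D_e}( F(x_{e_m}|x_{D_e}), F(x_{e_k}|x_{D_e}); θ_e )

and the mixture is h(x) = Σ_g π_g h_g(x), with Σ π_g = 1, 0 < π_g < 1.

The price of this flexibility is a parameter count that grows quadratically
with dimension.  `vinemix` attacks that per cluster, with two devices:

* **Pruning** — every candidate edge is screened with the asymptotic
  Kendall's-tau independence test (statistic |τ̂|·√(9n(n−1)/(2(2n+5)))); edges
  that fail to reject get the independence copula.
* **Truncation** — trees are added one at a time and a modified BIC for
  vines, mBICV = −2ℓ + ϑ·ln T − 2·Σ_i [q_i ln ψ₀^i + (n−i−q_i) ln(1−ψ₀^i)],
  selects the tree depth individually for each cluster; all deeper trees are
  set to independence.

Estimation is ECM: the E-step computes responsibilities r_tg; CM-steps update
the weights (closed form), the marginal parameters (numerically, through the
full component density), and the pair-copula parameters (weighted sequential
MLE through the trees), holding families, structures, pruned edges and
truncation levels fixed.  A final step re-selects everything on the
hard-assigned clusters.

## Worked example

```python
import numpy as np
from vinemix import VineCopulaMixture, default_scenario, simulate_mixture, misclassification_rate

spec = default_scenario()                  # two clusters, 6 dims, 300 each
X, y = simulate_mixture(spec, seed=11)     # (600, 6) data + true labels

est = VineCopulaMixture(n_components=2, random_state=0).fit(X)
print("misclassification:", misclassification_rate(y, est.labels_))
print("truncation levels:", est.truncation_levels_)
print("parameters:", est.n_parameters_, " BIC:", round(est.bic_, 1))
```

Output from this exact run:

```
misclassification: 0.0
truncation levels: [3, 3]
parameters: 43  BIC: 5732.3
```

All 600 observations are assigned to the correct cluster; the two clusters
were given individual truncation levels, and the whole two-component model
needs only 43 parameters (margins + pair-copulas + one free weight).  A
6-dimensional two-component mixture with full vines and no pruning would
carry up to 2·(12+15·2)+1 ≈ 85.

The same pipeline is available from a shell:

```bash
vinemix simulate --out-prefix sim --seed 1            # data/labels/scenario files
vinemix fit --data sim_data.csv --g 2 --out-prefix fit
vinemix benchmark --methods tvcmm,fvcmm,gmm,kmeans --replicates 10 \
        --seed 1 --out-prefix bench
```

`VineCopulaMixture` follows scikit-learn conventions (`fit`, `predict`,
`predict_proba`, `get_params`/`set_params`, trailing-underscore fitted
attributes), so it composes with sklearn model-selection tooling.  The
functional layer (`fit_tvcmm`, `fit_rvine`, `fit_bicop`, `fit_margin`,
`select_truncation_mbicv`, ...) exposes every stage separately.

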