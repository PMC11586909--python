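# fsgc — functional PCA for mixed-scale curves via a Gaussian copula

Mobile-health and ecological-momentary-assessment studies record repeated
within-day measurements on very different scales: step counts or activity
levels (continuous but non-Gaussian), pain ratings with a mass at "no
pain" (truncated), Likert mood items (ordinal) and event occurrences
(binary).  Indexed by time of day these are functional data, but classical
functional principal component analysis (FPCA) assumes continuous,
roughly Gaussian curves.

`fsgc` implements a functional **s**emiparametric **G**aussian-**c**opula
FPCA that treats all four scales in one framework.  Each observed curve
`X_i(t)` is modelled as a pointwise deformation of a latent Gaussian
process `V_i(t)` with correlation surface `C(s,t)` and unit variance:

* continuous: `X(t) = h_t(V(t))` for an unknown monotone `h_t`,
* truncated:  `X(t) = h_t(V(t)) · 1{V(t) ≥ Δ(t)}`,
* ordinal:    `X(t) = k` when `Δ_k(t) ≤ V(t) < Δ_{k+1}(t)`,
* binary:     `X(t) = 1{V(t) > Δ(t)}`.

Estimation is rank-based and therefore invariant to the unknown monotone
deformations:

1. **Kendall's τ** is computed for every pair of grid points (restricted
   to pairwise-complete subjects under sparse designs).
2. A type-specific, cutoff-dependent **bridging function** `F` links the
   population τ to the latent correlation, `τ_{jj'} = F(C(t_j, t_{j'}))`;
   cutoffs are estimated pointwise by the method of moments.
3. The surface is modelled as a symmetric tensor-product cubic B-spline
   through the inverse Fisher link,
   `C(s,t) = tanh(½ Σ_kl u_kl B_k(s) B_l(t))`, and the coefficients are
   fitted by **Gauss–Newton nonlinear least squares** on the bridged τ̂.
   The basis dimension can be chosen by BIC.
4. Latent curves are predicted by `E(V|X)` (expectation propagation for
   coarsened scales, with a Gibbs exact mode as oracle), and the latent
   eigenfunctions `ψ_k`, eigenvalues `λ_k` and subject scores
   `ζ_ik = Σ_j w_j V̂_i(t_j) ψ_k(t_j)` follow from the quadrature
   eigenproblem of the fitted surface.

A latent-process simulator, the comparator estimators used in the
simulation study (pointwise bridge inversion without smoothing; the
nonparanormal rank estimator that pretends the data are continuous; naive
FPCA of the raw values) and a Monte-Carlo benchmark driver are included.

## Worked example

```python
import numpy as np
from fsgc import GaussianCopulaFPCA, scenario_preset, simulate_glnpp
from fsgc.benchmark import ise
from fsgc.simulate import kernel_matrix

spec = scenario_preset("A", n=500, m=50, seed=1)   # binary curves
ds = simulate_glnpp(spec)

est = GaussianCopulaFPCA(kind="binary", n_basis=7).fit(ds)
C_true = kernel_matrix(spec.grid, spec.kernel)
print("ISE x 1e3:", round(1e3 * ise(C_true, est.correlation_.matrix,
                                    spec.grid), 2))
print("variance explained:",
      np.round(est.explained_variance_ratio_[:3], 3))
print("scores shape:", est.scores_.shape)
```

prints

```
ISE x 1e3: 1.54
variance explained: [0.598 0.264 0.08 ]
scores shape: (500, 20)
```

The fitted latent correlation misses the true simulation kernel by an
integrated squared error of about 0.0015 — from curves observed only as
0/1 indicators — and the first latent component carries ~60% of the
latent variance, with 20 components needed to cover the default 99%.  `est.transform(X_new)` maps further curves to score
space; `LatentPointwiseFPCA`, `NonparanormalCorrelation` and `NaiveFPCA`
expose the comparators with the same interface.

A `fsgc` command-line tool wraps the library:

```sh
fsgc simulate --scenario B --n 500 --seed 1 --out data.csv
fsgc fit --in data.csv --d 7 --out model.json
fsgc fpca --in data.csv --out scores.csv
fsgc predict --in data.csv --subject 12 --times 0.25,0.5,0.75 --out pred.csv
fsgc benchmark --scenario A --n 500 --reps 25 --seed 1
```

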