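# Methods

## Model

Curves `X_i(t)`, `t ∈ [0,1]`, of one declared scale (continuous,
truncated, ordinal with `l` levels, or binary) are modelled as pointwise
transforms of a latent process.  For any finite grid the latent vector
`(V(t_1), …, V(t_m))` is multivariate normal with mean zero, unit
variances and correlation matrix `C(t_j, t_{j'})`; observed values arise
by applying an unknown monotone map (continuous), censoring below a
cutoff (truncated), binning between cutoffs (ordinal) or thresholding
(binary).  The copula formulation separates the dependence structure
(`C`) from the margins (monotone maps and cutoff processes `Δ(t)`), so
only `C`, the cutoffs and — where needed for latent prediction — the
margins have to be estimated, and everything is invariant to monotone
re-scalings of the observed axis.

## Estimation pipeline

**Kendall's τ.** `τ̂_{jj'}` averages concordance signs over subject pairs
observed at both grid points (all pairs under a dense design).  Ties
count as zero (τ-a); no tie correction is applied because ties are
informative here — the bridging functions model them through the
cutoffs.  Under sparse designs, pairs of grid points with at most
`c0 = 5` complete subject pairs are dropped from the fit.

**Bridging.** For a same-type pair with latent correlation `r` the
population τ is a strictly increasing function `F(r; cutoffs)`:

* continuous–continuous: `(2/π) arcsin r`;
* binary–binary: `2(Φ₂(Δ_j, Δ_{j'}; r) − Φ(Δ_j)Φ(Δ_{j'}))`;
* ordinal–ordinal: the exact double sum
  `Σ sgn(a−a′) sgn(b−b′) p_{ab} p_{a′b′}` over bivariate-normal cell
  probabilities of the cutoff grid;
* truncated–truncated: τ of the censored pair `(max(V₁,Δ_j),
  max(V₂,Δ_{j'}))`, decomposed exactly into quadrant-probability products
  plus two 1-D integrals (one pair below its cutoff) and one 2-D integral
  (all four latent draws above), evaluated by deterministic quadrature in
  probability-transformed coordinates.

The bivariate normal CDF is computed from Owen's T function, vectorised
over points and correlations; this is what makes the truncated and
ordinal fits fast.  Every bridge is certified in the test-suite against
an independent Monte-Carlo oracle (10⁶ simulated pair couples, agreement
within four standard errors) and against `scipy`'s multivariate normal
CDF.  Truncation is *not* odd-symmetric in `r` (the zero atom is
one-sided), unlike the other bridges with symmetric cutoffs; the tests
encode this.

**Surface model and fit.**  `C(s,t) = g(Σ_{k,l} u_kl B_k(s) B_l(t))`
with `g(x) = tanh(x/2)` (inverse Fisher link), cubic B-splines with
equispaced knots, symmetric coefficient matrix `U`, and `d` basis
functions per direction (`d < m`; default `d = 7`, selectable by BIC).
`U` minimises `Σ (τ̂_{jj'} − F(C(t_j,t_{j'})))²` over unmasked pairs by
Gauss–Newton with a step-halving line search (analytic `dF/dr` except for
the truncated bridge, which uses central differences on its tabulated
form), convergence at relative objective decrease `< 1e-10` or step norm
`< 1e-8`, at most 200 iterations.  The warm start inverts the bridge
pointwise per pair and solves the linear least-squares problem on the
`g⁻¹` scale, which typically leaves only a handful of Gauss–Newton
steps.  During a fit, the truncated bridge is tabulated per pair by a
degree-20 Chebyshev polynomial in the arcsine-warped variable
`r = sin(πs/2)` (exactly linear for the continuous bridge; interpolation
error ≈ 5·10⁻⁵, well below sampling noise), so the iterative fit costs
the same as the analytic bridges.

**Marginals.**  Cutoffs are standard-normal quantiles of empirical
category proportions, estimated pointwise per grid point (no smoothness
imposed — observed processes may be rough; an optional spline
post-smoother exists but is off by default).  Proportions of 0 or 1 give
infinite cutoffs; such grid points are treated as uninformative and their
pairs dropped from the fit rather than clamped, since clamping would
inject arbitrary correlation.  The monotone transform for continuous and
truncated data is `f̂_t = Φ⁻¹ ∘ Ĝ_t` with the empirical CDF rescaled by
`1/(n_t+1)`, which keeps it finite; for truncated data the zeros count in
`Ĝ_t` but the transform is only defined on the positive part.

**PSD repair.**  The evaluated spline surface need not be positive
semidefinite; eigenvalues below `1e-8` are clipped and the matrix is
rescaled to unit diagonal.  The operation is flagged and is a no-op on
already-PSD input.

**Latent prediction.**  `E(V|X)` has no closed form for coarsened data.
Each observed cell is an interval constraint on one latent coordinate;
the posterior mean under the fitted correlation is computed by damped
parallel expectation propagation (Gaussian site factors moment-matched to
the cavity-tilted truncated normal; damping 0.7, convergence `1e-12`,
batched over subjects sharing an observation pattern).  EP is exact under
an identity correlation — a single pass reproduces the univariate
truncated-normal mean, e.g. `√(2/π)` for a balanced binary observation —
and agrees with exact quadrature to ≈ 4·10⁻⁴ on a compound-symmetry
test case (`m = 5`, `ρ = 0.6`).  A simpler one-pass linear smoother was
considered and rejected: it either distorts the identity-correlation
case or mis-predicts discordant observation patterns by an order of
magnitude more than EP.  A Gibbs sampler restricted to the observed
rectangle provides an exact-mode oracle for small grids.  Positive
truncated and continuous values pin their latent coordinate through
`f̂_t` and enter EP by exact Gaussian conditioning.

**Curve prediction and FPCA.**  Prediction at new time points is the
Gaussian conditional mean `ℂ_{N,O} ℂ_{O,O}⁻¹ V̂_O` (the spline model
evaluates anywhere in `[0,1]`), with conditional covariance reported and
observed-scale values recovered through the cutoffs / inverse transform.
Latent eigenfunctions solve the quadrature eigenproblem
`W^{1/2} ℂ̂ W^{1/2}` with trapezoid weights, are normalised to
quadrature-orthonormality, and signs are fixed so each eigenfunction has
a nonnegative sum (deterministic output).  Scores integrate the latent
BLUPs against the eigenfunctions; components are retained up to 99%
variance explained by default.  Under trapezoid weights an identity
correlation has eigenvalues equal to the weights themselves (endpoints
halved) — a quadrature artifact the tests document.

**BIC.**  `BIC(d) = n log|ℂ̂| + Σ_i V̂_iᵀ ℂ̂⁻¹ V̂_i + n m log 2π +
½ d(d+1) log n`, with the latent BLUPs supplying the likelihood term.
For sparse designs each subject contributes through its own observed
subvector's prior mean-zero completion (missing latent values enter as
zero, their prior mean) — a conservative extension of the dense formula.

## Synthetic data

The simulator draws latent Gaussian curves on an equispaced `m`-point
grid (eigenvalue square root of the kernel matrix, eigenvalues below
`−1e-8` rejected, small negatives clipped) and applies one of the
benchmark observation maps: thresholding at `0.5` (binary), binning at
`(−0.6, 0.1, 0.6)` into four levels (ordinal), censoring below `0.5`
(truncated), cubing (continuous non-Gaussian) or the identity.  A sparse
design keeps a uniformly random 40% of grid points per curve.  Each
subject has its own counter-based random stream derived from the seed and
subject index, so enlarging `n` extends a sample without reshuffling
earlier subjects.

Two kernels are provided.  The stationary kernel is a Matérn correlation
with `σ² = 1`, `ν = 3.5` and range parameter quoted in grid-index units
of the 50-point benchmark grid — 17 steps (dense) and 12 steps (sparse),
i.e. `17/49` and `12/49` on the unit interval.  This reading is the
package's own resolution of an ambiguous printed value: it is the only
one under which the benchmark's reference error levels are jointly
reproducible — a literal range of 17 on `[0,1]` makes the correlation
degenerate (≈ 1 everywhere), and a range of `1/7` makes the comparator
errors two to four times too large while inflating the spline
representation bias.  The non-stationary kernel is the correlation
normalisation of `0.052² sin(πs)sin(πt) + 0.092² cos(πs)cos(πt) +
0.01² 1{s=t}` (amplitudes read as squared coefficients).

The generator emulates the benchmark's study conditions, not real
mHealth data: margins are exactly Gaussian-copula, cutoffs are constant
in time, sampling within the sparse design is uniform rather than
diurnal, and there is no day-level nesting or measurement error beyond
the coarsening itself.  Passing tests therefore demonstrate correctness
of the estimation machinery under the model, not robustness to model
misspecification.

## Benchmark and comparators

Accuracy is the integrated squared error
`∫∫ (C_T − Ĉ)² ds dt` (trapezoid rule over the full unit square,
reported ×10³) against the true simulation kernel, averaged over
Monte-Carlo replicates with seeds `seed + r`.  Comparators:

* **pointwise inversion** (`fsgc_latent` / `LatentPointwiseFPCA`): the
  type-correct bridge inverted per pair with no spline smoothing, PSD
  repair, then FPCA — isolates the value of smoothing;
* **nonparanormal rank estimator** (`npn`): normal scores
  `Φ⁻¹(rank/(n+1))` per column followed by Pearson correlation — the
  continuous-data estimator deliberately misapplied to coarsened data.
  The arcsine variant `sin(πτ̂/2)` is also available
  (`NonparanormalCorrelation(method="arcsin")`); the normal-scores form
  is the default because it is what the standard comparator software
  actually computes, and the two differ drastically on binary data;
* **naive FPCA**: covariance of the raw observed values — reported for
  qualitative contrast only, as it estimates a different (observed-scale)
  object.

Desk-scale problem sizes were chosen as `n = 500`, `m = 50`, `d = 7`,
25 replicates per scenario (a full-scale run would use 100); at these
sizes the full four-scenario benchmark completes in about five minutes
on one CPU, dominated by the truncated scenario's quadrature bridge.

## Known limitations

* Same-type pairs only; multivariate mixed-type designs and multilevel
  (subject-day) nesting are out of scope.
* No uncertainty quantification for cutoffs, transforms or the fitted
  surface; the estimated cutoffs entering the bridges are treated as
  fixed.
* No roughness penalty — smoothness is controlled solely by the basis
  dimension.
* The truncated bridge is quadrature-based (absolute accuracy ≈ 3·10⁻⁵,
  certified to ≈ 10⁻³ at extreme correlations |r| > 0.999); exact
  analytic forms via 4-dimensional normal orthants would be slower by
  orders of magnitude in the fit loop.
* Ultra-dense designs (m in the thousands) are impractical: Kendall's τ
  costs O(n² m²) as implemented (subject-pair blocking), and the NLS has
  m(m−1)/2 residuals.
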