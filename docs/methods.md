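# Methods

## Model and assumptions

The observed sample `X1, …, Xn` is i.i.d. from `F0 = (1-α0) Fb + α0 Fs` with
`Fb` a fully known continuous, strictly increasing CDF and `Fs` an unknown
continuous signal CDF whose support is strictly inside that of `Fb`. The
support restriction makes `α0` identifiable: on the signal-free side of the
changepoint `a0`, `F0/Fb` (or its survival analogue) equals the constant
`1 - α0`. Two orientations are supported — a right-supported signal on
`[a0, ∞)` and a left-supported signal on `(-∞, a0]` (p-values); the two are
related exactly by mirroring `x ↦ -x`, and the implementation is tested for
this equivariance.

All estimators require a user bound `κ0` inside the signal-free region.
Ideally it comes from subject-matter knowledge; otherwise the grid search
below supplies one.

## Exact extrema on candidate sets

The ratio `Fn/Fb` is piecewise monotone: between data points the numerator is
frozen while the continuous denominator moves. Every infimum and supremum
used here is therefore computed exactly over a finite candidate set —
interval endpoints, data points, and left limits at data points, plus the
tail limit 1 for unbounded regions. Grids appear only in test oracles. This
matters because the estimator is defined as a true infimum: a grid of step h
introduces an O(h) bias, visible at the fourth decimal for typical grids.

## Estimators

* Mixing proportion: `α̂n = 1 - inf` of the constrained ratio; deterministic
  given the data, in `[0,1]` by construction, and `√n`-consistent.
* Support endpoint: `â_n` is the outermost data point at which the centred
  ECDF `Fn - (1-α̂n)Fb` (or its mirror) still sits below the threshold
  `t = α̂n·bn/√n`. The default `bn = log log n` (with fallback 0.1 for n ≤ 2
  where the expression is non-positive) follows the rate analysis: the
  estimation error is of order `bn/√n` divided by the signal density at the
  endpoint, so the constant `1/fs(a0)` is checked by a dedicated rate test.
  Inside the threshold `α̂n` is clipped to `(0,1]` so `t > 0`; if `α̂n ≤ t`
  (only possible when `bn ≥ √n`) the qualifying set is unbounded and an error
  is raised; when no data point qualifies the bound `κ0` itself is returned
  with `attained=False`.
* Limit law: `√n(α̂n - α0)` converges to `-inf` over the signal-free window
  of a Brownian bridge composed with `F0`, scaled by `Fb` (survival versions
  mirrored). The bridge is simulated by the uniform-ECDF surrogate
  `√N(G_N(t) - t)` with `N = n` by default; plug-in mode composes with the
  sample ECDF over `[â_n, κ0]` (exact candidate-set infimum), oracle mode
  with a known `F0` on a 2048-point grid. Confidence intervals invert the
  empirical quantiles of `M = 1000` draws (default) and are clipped to
  `[0,1]`.

## Testing a bound and searching the grid

Under the null that `κ0` is valid, the ratio is flat on the signal-free side
of `κ0`, so the `√n`-scaled sup-distance of the ratio from its anchored value
over a window has a pivotal bridge limit. Critical values are Monte-Carlo
quantiles of the surrogate-bridge statistic; the quantile is the
`ceil((1-β)(M+1))` order statistic, the standard conservative convention for
simulated tests.

Two compositions of the surrogate are implemented:

* `ecdf`: the bridge is composed with the sample ECDF — the direct plug-in,
  used by the standalone validity test. Asymptotically exact under the null.
* `null`: the bridge is composed with the fitted null mixture CDF, i.e. the
  background rescaled to the ratio level observed at a reference point deep
  in the signal-free region. Under the null both agree; under the
  alternative, the ECDF composition inflates the critical value (the window
  then carries signal mass, roughly doubling the simulated dispersion in our
  measurements), which costs power precisely where the test must reject. The
  grid search therefore uses the null composition, with the reference level
  read at the outermost grid point.

Grid-search selection is orientation-aware. For a left-supported signal the
scan moves outward from inside the signal region and the estimate is the
smallest accepted point. For a right-supported signal the scan starts inside
the valid region, so isolated late rejections are uninformative; the estimate
is the endpoint of the initial run of acceptances. Selecting instead the
plain extremum of all accepted points is fragile in both directions — a
single false acceptance far inside the signal region, or a single chance
rejection inside the valid region, would dominate the estimate. Windows that
leave the interior of the background support are marked untestable and never
accepted; if nothing is accepted a diagnostic error carries all per-point
results. The same `M` surrogate samples are reused across grid points within
one search: quantiles are per-window functionals of exchangeable draws, and
this is ~|grid|× faster.

## Shape-constrained signal densities

All three fits target the mixed density `f0`; the signal density is the
truncated plug-in transform `f̂s = ((f̂ - 1 + α̂)/α̂) ∨ 0` (uniform
background) — non-negative everywhere but not renormalised, since the
transform of a density estimate need not integrate to one.

* Monotone: the Grenander estimator, computed as the left derivative of the
  least concave majorant of the ECDF by a monotone-chain hull scan on the
  unique points (ties merged into jump sizes); exact and O(n log n). The fit
  is a mixture of uniform blocks (weights `ci(τi - τi-1)`), which is also how
  it is resampled.
* Convex decreasing: the least-squares estimator over mixtures of triangular
  kernels `2(τ-x)+/τ²`, solved by support reduction: start from the best
  single kernel, repeatedly add the candidate with the most negative
  directional derivative, re-solve the restricted non-negative quadratic
  programme exactly (Cholesky + NNLS), drop zero-weight kernels, stop at
  directional-derivative gap ≤ 1e-8. Candidates are the data plus a 256-point
  refinement grid; the grid's upper end extends adaptively beyond the data
  maximum because the estimator only integrates to one on an unconstrained
  support cone (capping the support at the data maximum loses mass — we
  measured Σc ≈ 0.67 for uniform-ish data with a capped grid vs 1.0 ± 1e-5
  uncapped).
* Log-concave (Gaussian background): the weighted MLE of `ψ = log fs`
  maximises `Σ wi ψ(Xi) - ∫ e^ψ` over concave `ψ`. Concave piecewise-linear
  functions are parametrised as `a + b(x - z1) - Σ βk (x - zk)+`, `βk ≥ 0`,
  turning the problem into a smooth concave programme with sign constraints,
  solved by the same support-reduction pattern with damped Newton inner
  steps and exact segment-wise integrals of `exp(linear)` (stable forms
  factored from the larger endpoint). The returned `ψ` is shifted by
  `-log ∫ e^ψ`: this is the optimal move along the unconstrained constant
  direction, so it never decreases the objective and makes the
  normalisation exactly one. The outer loop stops at gap ≤ 1e-7 or when two
  successive additions fail to improve the objective beyond 1e-11 (nearly
  collinear hinge candidates can promise ~1e-4 gains that are not
  numerically realisable; the effect on the density is below 1e-3 in L1).
  The mixture version holds `α̂n` fixed and alternates background
  responsibilities (E-step) with the weighted MLE (M-step, warm-started from
  the previous fit), stopping at `max |Δγ| < 5e-6` or 250 iterations. The
  signal estimate is initialised as the Gaussian matching the sample
  moments — a deterministic start chosen over a random two-component
  initialiser for reproducibility.

## Pointwise confidence intervals

* Strictly decreasing case (monotone): cube-root asymptotics with the
  Chernoff limit (argmax of two-sided Brownian motion minus a parabola).
  Quantiles ship as a lookup table at full precision; a discretised-argmax
  simulator exists to validate the table (grid `[-2.5, 2.5]`, step 0.01) and
  reproduces the 0.95 quantile to ~0.01 at 5·10⁴ draws. Two-sided intervals
  use the `(1+level)/2` row by symmetry. The local derivative of `f0` is
  estimated from the fitted step function by a symmetric difference quotient
  with bandwidth `c(log n)^{2/3} n^{-1/3}`, `c = 0.5` by default; a zero
  slope raises an error directing to the bootstrap (flat-region regime).
* Strictly convex case: `n^{2/5}` asymptotics with the limit given by the
  second derivative at zero of the convex envelope of integrated Brownian
  motion plus `t⁴`; quantiles ship as a table (asymmetric: lower offset
  |q(0.025)| ≈ 2.437, upper q(0.975) ≈ 2.337) and are validated by a scaled
  simulator that fits the convex LSE of the quadratic-decay density
  `3(1-x)²` at its midpoint. Curvature is a second-order difference quotient
  with bandwidth `c(log n)^{2/5} n^{-1/5}`.
* Flat/linear regimes and anything in between: the m-out-of-n bootstrap.
  `B` resamples of size `mn` are drawn from the fitted mixed density (exact
  mixture resampling), each re-estimating the proportion at the same `κ0`,
  refitting the shape and evaluating the transformed signal density;
  quantiles of `√mn (f*s - f̂s)` are inverted on the `√n` scale. Defaults
  `mn = ⌊n^{2/3}⌋` (monotone) and `⌊n^{4/5}⌋` (convex). Consistency of this
  bootstrap in the flat monotone case is conjectural; it is exercised
  through coverage tests and should be treated as experimental.

## Comparator

The distance-based comparator computes, for each `γ` on a 0.001-step grid,
the naive signal CDF `(Fn - (1-γ)Fb)/γ` at the order statistics and its
bounded isotonic projection (PAVA then clipping — exact for box constraints),
and returns the smallest `γ` whose scaled empirical L2 distance drops below
`cn/√n`, `cn = 0.1 log log n`. The grid discretises a continuum infimum;
the induced error is at most one step. Its cross-validated tuning variant is
out of scope (prohibitively slow and comparison-only).

## Synthetic scenarios

Nine benchmark mixtures cover the three shape classes and both orientations:
uniform background with uniform, triangular-mixture (density `3-4x` on
`[0, 1/2]`), and rescaled Beta(1,2)/Beta(1,3) signals (left-supported,
`α0 ∈ {0.6, 0.8}`, `a0 ∈ {0.5, 0.6, 0.7}`); Gaussian background with
Gamma(2,1), Exp(1) and Gamma(1/2,1) signals (right-supported, `a0 = 0`,
`α0 = 0.8`). Every scenario exposes exact CDF/density evaluators, checked
pointwise against the mixture identity and by KS tests on large samples.
These generators emulate the independence, exact-background and
sharp-changepoint assumptions of the model; real screening data typically
violate independence (correlated tests) and may have a misspecified null,
so passing benchmarks here says nothing about robustness to those failures.

## Problem sizes in the default test run

The suite replicates the benchmark design points at reduced scale, chosen so
the whole run completes in a few minutes while keeping every comparison
within ~3 combined Monte-Carlo standard errors of the published values:
200 replications for the endpoint table (vs 1000), 100 for the grid search
and proportion comparisons (as published), 100 coverage replications with
`B = 500` bootstrap resamples, 5·10⁴ argmax draws for the cube-root
quantile, and `N = 5000, M = 300` for the scaled convex-limit simulation
(vs `N = 10⁵, M = 1000`), whose wider bracket (±0.25 on the 0.95 quantile)
reflects the `N^{2/5}` convergence of the scaled statistic. Parameter
recovery runs all nine scenarios at `n = 10⁵` with 50 replications. The
endpoint summaries reproduce the published protocol of retaining a random
90% of the passing replications.

## Known limitations

* The grid search has no multiplicity control across grid points (by
  design); its behaviour when the signal density vanishes smoothly at the
  endpoint degrades at the published polynomial rates (endpoint-recovery
  tolerances 0.12–0.2 at `n = 10⁵` for those scenarios).
* Monotone/convex machinery presumes a uniform background on `[0,1]`; the
  log-concave EM presumes a standard Gaussian background.
* The pointwise limit theory for the log-concave signal estimate is not
  established; no analytic CI is offered there.
* Backgrounds must be continuous with strictly increasing CDFs; discrete
  backgrounds are out of scope.
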