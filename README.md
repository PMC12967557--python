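# semimix

Estimation and inference for two-component mixtures with a **known background
component** and a signal whose support is **strictly inside** the background
support:

```
F0 = (1 - α0) · Fb + α0 · Fs
```

`Fb` is completely known (e.g. the uniform null distribution of p-values in a
multiple-testing screen, or a standard Gaussian for test statistics); the
mixing proportion `α0` and the signal distribution `Fs` are unknown. The key
structural assumption is that the signal is absent on one side of an unknown
changepoint `a0` — the signal lives on `[a0, ∞)` (right-supported) or on
`(-∞, a0]` (left-supported, the p-value case, where `1 - α0` is the null
proportion π₀).

This package is for statisticians and computational biologists who need the
null/signal proportion and the signal density from such data — typically
large vectors of p-values or test statistics from genomics-scale screens.

## What it computes

Given a user bound `κ0` known to lie in the signal-free region
(`κ0 ≤ a0` / `κ0 ≥ a0`), the mixing proportion is estimated by the
constrained ECDF-ratio

```
α̂n = 1 - inf_{x ≥ κ0} Fn(x)/Fb(x)            (right-supported signal)
α̂n = 1 - inf_{x ≤ κ0} (1-Fn(x))/(1-Fb(x))    (left-supported signal)
```

which converges at the parametric rate `1/√n`, with the limiting law of
`√n(α̂n - α0)` equal to the negative infimum of a Brownian bridge composed
with `F0` over the signal-free window, rescaled by `Fb`. The package

* computes these infima **exactly** on the finite candidate set where the
  piecewise ratio can attain its extremes (no grids);
* estimates the support endpoint `a0` by thresholding the centred ECDF at
  `α̂n·bn/√n` with `bn = log log n`;
* **tests** whether a proposed `κ0` is valid (the ratio is flat on the
  signal-free side) with Monte-Carlo critical values from a uniform-ECDF
  surrogate Brownian bridge, and **searches a grid** for the boundary when no
  `κ0` is known;
* simulates the limit law to give confidence intervals for `α0`;
* estimates the signal density under shape constraints: **monotone**
  (Grenander / least-concave-majorant), **convex decreasing** (least-squares
  via support reduction over triangular mixtures), and **log-concave**
  (weighted MLE inside a pseudo-EM for Gaussian backgrounds), with pointwise
  confidence intervals from cube-root (Chernoff) and `n^{2/5}` limit
  quantiles, or from the m-out-of-n bootstrap in the non-standard flat/linear
  regimes;
* includes the distance-based comparator estimator (naive signal CDF vs. its
  bounded isotonic projection, thresholded at `cn/√n`) for benchmarking.

## Worked example

```python
import numpy as np
from semimix import (background, estimate_alpha, estimate_a0, search_kappa,
                     grenander_fit, signal_density, sample_setting)

# a benchmark mixture: 40% U(0,1) background + 60% U(0,0.6) signal
pvals = sample_setting("1a", n=5000, seed=42)
bg = background("uniform")

# find a valid search bound on a grid, then estimate
est = search_kappa(pvals, bg, np.arange(0.2, 0.81, 0.05), h0=0.05,
                   problem="left_support", seed=1)
alpha = estimate_alpha(pvals, bg, est.kappa_hat, "left_support")
endpoint = estimate_a0(pvals, bg, est.kappa_hat, alpha)
f_s = signal_density(grenander_fit(pvals), alpha.alpha_hat)
print(f"kappa_hat = {est.kappa_hat:.2f}, alpha_hat = {alpha.alpha_hat:.4f}, "
      f"a_hat = {endpoint.a_hat:.4f}, f_s(0.3) = {float(f_s(0.3)):.3f}")
```

prints

```
kappa_hat = 0.60, alpha_hat = 0.6155, a_hat = 0.5830, f_s(0.3) = 1.679
```

The searched bound lands at the true endpoint `a0 = 0.6`; the proportion
estimate is within 0.016 of the true `α0 = 0.6` (the theoretical standard
error at this `n` is about 0.013); the monotone signal-density estimate at
0.3 is close to the true uniform height `1/0.6 ≈ 1.667`.

The same workflow runs from the shell:

```
semimix simulate --setting 1a --n 5000 --seed 42 --out pvals.csv
semimix find-kappa --data pvals.csv --grid 0.2:0.8:0.05 --problem left
semimix estimate --data pvals.csv --kappa0 0.6 --problem left --level 0.95
semimix fit-signal --data pvals.csv --shape monotone --kappa0 0.6 --x0 0.3
```

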