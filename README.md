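# modhill

Models and fitting tools for cooperative ligand-binding curves, built
around the oxyhemoglobin dissociation curve (ODC): the sigmoid
relationship between oxygen partial pressure *p* (mm Hg) and
fractional hemoglobin saturation *y*.

The package is aimed at physiologists and biophysicists who fit
saturation curves and want more than a single Hill coefficient: it
implements, alongside the classic Hill and Adair equations, a Hill
equation whose cooperativity coefficient is itself a bell-shaped
function of log oxygen pressure.

## The models

Classic Hill, with constant cooperativity *h*:

    y(p) = p^h / (p50^h + p^h)

Adair (Adair–Klotz), the four-step sequential-binding polynomial with
macroscopic association constants K1..K4:

    y(p) = (K1 p + 2 K2 p^2 + 3 K3 p^3 + 4 K4 p^4)
           / (4 (1 + K1 p + K2 p^2 + K3 p^3 + K4 p^4))

Modulated Hill (Hill/G and Hill/L): the Hill form evaluated with a
pressure-dependent coefficient that peaks at a pressure p_max and
decays to 1 (no cooperativity) at both extremes,

    h(p) = 1 + (h_max − 1) · G(x),   x = (ln p − ln p_max) / s

with G a Gaussian `exp(−x²)` (Hill/G) or Lorentzian `1/(1 + x²)`
(Hill/L) profile. Each modulated model has four fitting parameters:
p50, h_max − 1, ln p_max and the width s. Half-saturation at p50 is
preserved exactly for any profile.

From a fitted modulated model the package derives: h_max, the grid
mean h̄ and dispersion Δh = h_max − h̄; the saturation reached at
p_max; the shift Δp_maxO2 = p_max − p50; the relative subunit
cooperativity θ(n) = (h_max − 1)/(n − 1); and the pressure band
[pO2_low, pO2_high] inside which the excess cooperativity h(p) − 1
stays above a fraction ω of its peak (ω = 0.5 is the HWHM).

Fitting is bounded multi-start nonlinear least squares on the
saturation scale (scipy trust-region reflective), with r², a
Gauss–Newton parameter covariance, and pointwise delta-method
confidence/prediction bands at a configurable significance level.
A seeded generator produces synthetic ODC datasets from any model,
emulating classic whole-blood measurements.

## Worked example

Derived parameters from published Gauss-profile estimates of the
Severinghaus whole-blood curve (p50 = 26.82 mm Hg, h_max − 1 = 1.82,
p_max = 80.85 mm Hg, s = 3.59):

```sh
$ modhill derive --p50 26.82 --hmax-minus1 1.82 --pmax 80.85 \
                 --s 3.59 --profile gauss --omega 0.99
{
  "delta_pO2": 59.46073585,
  "h_max": 2.82,
  "pO2_high": 115.8733727,
  "pO2_low": 56.41263688,
  "sat_at_pmax_percent": 95.73737067,
  "theta": 0.6066666667,
  ...
}
```

Cooperativity peaks at h_max = 2.82 (θ = 0.61 of the tetramer
maximum) at 80.85 mm Hg, where the blood is already 95.7% saturated;
the band in which the excess cooperativity stays within 1% of its
peak spans 56.4–115.9 mm Hg.

Simulate a realistic noisy curve and fit it back:

```sh
$ modhill simulate --style winslow_like --seed 7 --out odc.csv
$ modhill fit --data odc.csv --model hill-lorentz --seed 7
{
  "model_kind": "hill_lorentz",
  "params": {"p50": 29.35741444, "hmax_minus1": 1.711595575,
             "pmax": 44.84247543, "s": 1.710166999, ...},
  "r2": 0.9999059503,
  "converged": true
}
```

The generating truth was p50 = 29.11 mm Hg, h_max − 1 = 1.68,
p_max = 47.82 mm Hg, s = 1.80 with 0.005 saturation noise; the fit
recovers each parameter to a few percent at r² = 0.99991. Other
subcommands: `compare` (rank all four models by r²), `bands`
(confidence/prediction band CSV), and `--help` on any of them.

The same functionality is available as a library:

```python
from modhill import ModulatedHillParams, derive_all
import numpy as np

params = ModulatedHillParams(26.82, 1.82, np.log(80.85), 3.59, "gauss")
print(derive_all(params, omega=0.99).pO2_low)  # 56.41263688194238
```

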