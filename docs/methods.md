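# Methods

## Model family

All four models describe fractional saturation y ∈ (0, 1) of a
four-site carrier as a function of ligand partial pressure p > 0
(mm Hg, no unit conversion layer).

The classic Hill equation treats binding as effectively concerted
with a single empirical cooperativity exponent h. The Adair–Klotz
polynomial resolves the four sequential binding steps through
macroscopic association constants K1..K4 (K_i ≥ 0, K4 > 0 so the
tetramer saturates); its fractional occupancy equals the
Boltzmann-weighted mean occupancy over the five ligation states with
weights {1, K1 p, K2 p², K3 p³, K4 p⁴}, which the test suite uses as
an independent oracle.

The modulated Hill models keep the Hill functional form but let the
coefficient vary with pressure:

    h(p) = 1 + (h_max − 1) · G((ln p − ln p_max)/s),

with G Gaussian or Lorentzian. The additive 1 encodes the physical
floor of no cooperativity; h(p) → 1 at both pressure extremes and
attains h_max exactly at p_max. Because the coefficient multiplies
the log-distance from p50 inside a logistic, y(p50) = 1/2 holds for
every profile and parameter set. The fitted parameter is ln p_max
(not p_max), which keeps p_max positive without an explicit
constraint.

Monotonicity caveat: for large excess cooperativity combined with a
narrow width the modulated saturation can dip slightly just above
x = 1 (the term h(p)·ln(p/p50) is not monotone for every parameter
combination). On the physiological parameter sets shipped with the
package the curves are monotone on a dense grid over 10⁻³–10³ mm Hg,
and the suite checks exactly that.

## Fitting

Plain (unweighted) least squares on the fraction scale; weighting and
heteroscedastic schemes are out of scope. Saturations are fitted as
fractions — with an unweighted quadratic loss, fitting percent would
only rescale the objective.

The solver is scipy's bounded trust-region reflective
`least_squares`. Default bounds are a generous physiological
envelope: p50 ∈ [0.1, 500] mm Hg, h ∈ [0.5, 6], h_max − 1 ∈ [0, 5],
ln p_max ∈ [ln 0.5, ln 500], s ∈ [0.05, 20], K_i ∈ [0, 10⁶] in their
own units; all overridable per fit. Multi-start (default 8): one
data-driven start (p50 interpolated from the curve at y = 0.5, a
mid-range cooperativity guess) plus seeded draws, log-uniform for
scale-like parameters (p50, p_max, s, K_i — floored at 10⁻⁸ where the
lower bound is 0) and uniform otherwise. The best local solution by
objective wins; adding starts can only improve the kept objective.
Convergence tolerances default to 10⁻¹² on ftol/xtol/gtol.

The parameter covariance is the Gauss–Newton estimate
σ̂² (JᵀJ)⁻¹ with σ̂² = SS_res/(n − k); if JᵀJ is singular the
covariance is reported unavailable and the fit is still returned.
r² = 1 − SS_res/SS_tot; constant observations make it undefined and
the package reports `None` rather than a number.

`compare_models` ranks by r² descending, breaking ties toward fewer
parameters then kind name; non-converged fits rank last. Note the
Adair polynomial is not nested in the Lorentz-modulated family: on a
noiseless Lorentz-generated curve its best achievable 1 − r² is of
order 10⁻⁵, so near-machine-perfect recovery is asserted only for the
generating family.

## Derived parameters

From a modulated-Hill parameter set: h_max = (h_max − 1) + 1; the
mean coefficient h̄ as the arithmetic mean of h(p) on a uniformly
spaced pressure grid (default 1–150 mm Hg, 1000 points — the
averaging range and density are conventions, so h̄ is reported
together with its grid and checked for quadrature stability, not
against a universal value); Δh = h_max − h̄; the saturation at p_max
and its excess over 1/2; Δp_maxO2 = p_max − p50; and
θ(n) = (h_max − 1)/(n − 1) with n = 4 subunits by default.

The ω-band bounds are closed forms on the log-pressure axis:

* Gaussian: exp(ln p_max ∓ s·√(−ln ω))
* Lorentzian: exp(ln p_max ∓ s·√(1/ω − 1))

At these bounds h(p) − 1 equals ω·(h_max − 1) exactly (round-trip
tested to 10⁻¹⁰ relative). Default ω = 0.99; ω = 0.5 gives the HWHM.
Caveat: the published Lorentz-profile band values for the two
whole-blood datasets are not consistent with these closed forms at
ω = 0.99 (they correspond to ω ≈ 0.977); the package always evaluates
the closed forms, and only the Gaussian-profile band values are used
as numeric anchors in the tests.

## Uncertainty bands

First-order delta-method pointwise bands with Student-t quantiles:
confidence half-width t(1 − α/2, n − k)·√(gᵀCg) and prediction
half-width t·√(σ̂² + gᵀCg), where g is the finite-difference gradient
of the model in its parameters (central differences, relative step
10⁻⁶) and C the Gauss–Newton covariance. Default α = 10⁻⁴ (99.99%
pointwise intervals). Bands are pointwise, not simultaneous.
Saturation bounds are clipped to [0, 1] only at serialization; raw
values are kept internally. The delta-method core is validated
against the closed-form simple-linear-regression band formulas on a
model that is linear in its parameters. Monte-Carlo (parametric
bootstrap) bands would be a natural alternative but are not
implemented.

## Synthetic data

The generator emulates whole-blood oxygen-equilibrium measurements:
log-spaced pressure designs (default 30 points over 0.5–150 mm Hg,
mirroring the denser low-pressure coverage of real ODC tables),
saturations from any of the four models plus additive homoscedastic
Gaussian noise on the saturation scale (default SD 0.005, a
plausible instrument-level error for oximetric saturation readings),
optionally clipped to [0, 1]. The two named styles use the published
Lorentz-profile estimates for the Winslow and Severinghaus datasets
as generating truths. Everything is driven by an explicit integer
seed and is bit-reproducible.

What the synthetic data does not emulate: the true (unpublished)
pressure designs and replicate structure of the source measurements,
pressure read-out error, heteroscedastic or systematic saturation
error, and inter-sample physiological variation (pH, temperature,
2,3-DPG). Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the stated noise model, not field
performance on arbitrary real data.

## Problem sizes and numerical choices

Default test-suite problem sizes: 25–30 point curves, 20 replicate
recovery runs, 6–12 starts per fit, 1000-point evaluation grids —
sizes at which every result above is stable and the whole suite runs
in seconds. Degenerate inputs are rejected with explicit errors
(non-positive pressures where a log is taken, under-determined
datasets, ω outside (0, 1), fewer than 2 subunits for θ). JSON
reports round floats to 10 significant digits so identical runs are
byte-identical.
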