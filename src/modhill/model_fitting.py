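"""Bounded multi-start nonlinear least-squares fitting of binding models.

The objective is the plain (unweighted) sum of squared residuals on
the fractional-saturation scale.  Each fit runs a trust-region
reflective solver (:func:`scipy.optimize.least_squares`) from several
start points sampled log-uniformly (scale-like parameters) or
uniformly within the bounds, plus one data-driven heuristic start, and
keeps the best local solution.  The parameter covariance is the
Gauss-Newton estimate ``sigma^2 (J^T J)^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .binding_models import (
    AdairParams,
    HillClassicParams,
    ModulatedHillParams,
    ODCDataset,
    adair_saturation,
    hill_classic_saturation,
    modulated_hill_saturation,
)

__all__ = [
    "MODEL_KINDS",
    "FitOptions",
    "FitResult",
    "fit_model",
    "r_squared",
    "compare_models",
    "predict",
]

MODEL_KINDS = ("hill_classic", "adair", "hill_gauss", "hill_lorentz")

# Generous physiological envelope; overridable through FitOptions.bounds.
DEFAULT_BOUNDS = {
    "hill_classic": [(0.1, 500.0), (0.5, 6.0)],  # p50, h
    "adair": [(0.0, 1e6)] * 4,  # K1..K4
    # p50, hmax_minus1, ln_pmax, s
    "hill_gauss": [
        (0.1, 500.0),
        (0.0, 5.0),
        (np.log(0.5), np.log(500.0)),
        (0.05, 20.0),
    ],
}
DEFAULT_BOUNDS["hill_lorentz"] = DEFAULT_BOUNDS["hill_gauss"]

# Parameters spanning orders of magnitude get log-uniform start sampling.
_LOG_SCALE = {
    "hill_classic": (True, False),
    "adair": (True, True, True, True),
    "hill_gauss": (True, False, False, True),
    "hill_lorentz": (True, False, False, True),
}

_N_PARAMS = {"hill_classic": 2, "adair": 4, "hill_gauss": 4, "hill_lorentz": 4}


class InsufficientDataError(ValueError):
    """Dataset has too few points to determine the model parameters."""


@dataclass(frozen=True)
class FitOptions:
    """Solver configuration shared by all model kinds.

    ``bounds`` overrides the per-model defaults (a list of
    ``(lower, upper)`` pairs in the model's parameter order).  ``seed``
    drives the start-point sampler only; the solver itself is
    deterministic.
    """

    n_starts: int = 8
    bounds: Optional[Sequence[tuple]] = None
    seed: int = 0
    tolerance: float = 1e-12
    max_iterations: int = 2000

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bounds is not None:
            for lo, hi in self.bounds:
                if not lo < hi:
                    raise ValueError("each bound must satisfy lower < upper")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance and max_iterations must be positive")


@dataclass(frozen=True)
class FitResult:
    model_kind: str
    params: object
    r2: Optional[float]
    residuals: np.ndarray
    covariance: Optional[np.ndarray]
    converged: bool
    n_starts_used: int
    best_objective: float
    theta: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model_kind]


def r_squared(observed, predicted) -> Optional[float]:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Returns ``None`` when the observed values are constant (zero total
    variance makes the ratio undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _model_fn(kind: str):
    if kind == "hill_classic":
        return lambda p, th: hill_classic_saturation(p, HillClassicParams(*th))
    if kind == "adair":
        return lambda p, th: adair_saturation(p, AdairParams(*th))
    profile = "gauss" if kind == "hill_gauss" else "lorentz"
    return lambda p, th: modulated_hill_saturation(
        p, ModulatedHillParams(*th, profile=profile)
    )


def _pack_params(kind: str, theta: np.ndarray):
    if kind == "hill_classic":
        return HillClassicParams(*theta)
    if kind == "adair":
        # the solver may park a constant exactly at the lower bound 0;
        # K4 = 0 is unphysical, so nudge it to a tiny positive value
        th = np.maximum(theta, [0, 0, 0, 1e-300])
        return AdairParams(*th)
    profile = "gauss" if kind == "hill_gauss" else "lorentz"
    return ModulatedHillParams(*theta, profile=profile)


def predict(fit: FitResult, pressures) -> np.ndarray:
    """Evaluate the fitted model on new pressures."""
    return np.asarray(_model_fn(fit.model_kind)(pressures, fit.theta))


def _heuristic_start(kind: str, data: ODCDataset, bounds) -> np.ndarray:
    """Data-driven start: p50 from interpolating the curve at y = 0.5."""
    p, y = data.pressures, data.saturations
    if np.any(y >= 0.5) and np.any(y <= 0.5):
        p50 = float(np.interp(0.5, y, p))
    else:
        p50 = float(np.median(p))
    p50 = float(np.clip(p50, 0.5, 400.0))
    if kind == "hill_classic":
        start = [p50, 2.5]
    elif kind == "adair":
        k = 1.0 / p50
        start = [4 * k, 6 * k**2, 4 * k**3, k**4]
    else:
        start = [p50, 1.5, np.log(1.6 * p50), 2.0]
    lo, hi = np.array(bounds).T
    eps = 1e-9 * (hi - lo)
    return np.clip(start, lo + eps, hi - eps)


def _sample_starts(kind: str, bounds, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = np.array(bounds, dtype=float).T
    log_mask = np.array(_LOG_SCALE[kind])
    starts = np.empty((n, lo.size))
    u = rng.random((n, lo.size))
    # log-uniform needs a positive lower edge; floor zero bounds well
    # below any physiological constant
    lo_pos = np.where(lo > 0, lo, np.minimum(1e-8, hi * 1e-12))
    starts[:, log_mask] = np.exp(
        np.log(lo_pos[log_mask])
        + u[:, log_mask] * (np.log(hi[log_mask]) - np.log(lo_pos[log_mask]))
    )
    starts[:, ~log_mask] = lo[~log_mask] + u[:, ~log_mask] * (hi - lo)[~log_mask]
    return starts


def fit_model(data: ODCDataset, model_kind: str, options: FitOptions = FitOptions()) -> FitResult:
    """Fit one model to a dataset by multi-start bounded least squares.

    Requires at least one more observation than the model has
    parameters.  Deterministic for a fixed ``(data, options)`` pair.
    If no start converges the result carries ``converged = False`` and
    the least-bad solution instead of raising.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    k = _N_PARAMS[model_kind]
    n = len(data)
    if n < k + 1:
        raise InsufficientDataError(
            f"{model_kind} has {k} parameters; need at least {k + 1} points, got {n}"
        )

    bounds = options.bounds if options.bounds is not None else DEFAULT_BOUNDS[model_kind]
    if len(bounds) != k:
        raise ValueError(f"{model_kind} needs {k} (lower, upper) bound pairs")
    lo, hi = np.array(bounds, dtype=float).T
    model = _model_fn(model_kind)
    p, y = data.pressures, data.saturations

    def resid(theta):
        return model(p, theta) - y

    rng = np.random.default_rng(options.seed)
    starts = [_heuristic_start(model_kind, data, bounds)]
    if options.n_starts > 1:
        starts.extend(_sample_starts(model_kind, bounds, options.n_starts - 1, rng))

    best = None
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=options.tolerance,
                xtol=options.tolerance,
                gtol=options.tolerance,
                max_nfev=options.max_iterations,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        any_success = any_success or sol.success

    if best is None:  # every start raised; synthesize a null solution
        theta = starts[0]
        res = resid(theta)
        return FitResult(model_kind, _pack_params(model_kind, theta), r_squared(y, y + res),
                         res, None, False, len(starts), float(np.sum(res**2)), np.asarray(theta))

    theta = best.x
    res = best.fun
    ssr = float(2.0 * best.cost)
    cov = _gauss_newton_covariance(best.jac, ssr, n, k)
    return FitResult(
        model_kind=model_kind,
        params=_pack_params(model_kind, theta),
        r2=r_squared(y, y + res),
        residuals=-res,  # observed - predicted
        covariance=cov,
        converged=bool(any_success),
        n_starts_used=len(starts),
        best_objective=ssr,
        theta=np.asarray(theta),
    )


def _gauss_newton_covariance(jac: np.ndarray, ssr: float, n: int, k: int) -> Optional[np.ndarray]:
    if n <= k:
        return None
    jtj = jac.T @ jac
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(inv)):
        return None
    sigma2 = ssr / (n - k)
    return sigma2 * inv


def compare_models(data: ODCDataset, kinds: Sequence[str], options: FitOptions = FitOptions()) -> list:
    """Fit several models and rank them by descending r-squared.

    Ties break toward fewer parameters, then by kind name; fits that
    fail to converge rank last.
    """
    results = [fit_model(data, kind, options) for kind in kinds]

    def key(fr: FitResult):
        r2 = fr.r2 if (fr.converged and fr.r2 is not None) else -np.inf
        return (not fr.converged, -r2, fr.n_params, fr.model_kind)

    return sorted(results, key=key)
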