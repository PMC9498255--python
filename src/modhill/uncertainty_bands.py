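"""Pointwise confidence and prediction bands for fitted binding models.

First-order (delta-method) bands: at each grid pressure the fitted
curve's variance is ``g' C g`` with ``g`` the gradient of the model in
its parameters and ``C`` the Gauss-Newton parameter covariance; the
confidence half-width is a Student-t quantile times that standard
error, and the prediction half-width additionally carries the residual
variance of a new observation.  Bands are pointwise, not family-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binding_models import ODCDataset
from .model_fitting import FitResult, _model_fn

__all__ = ["BandSet", "compute_bands", "delta_method_bands"]

_REL_STEP = 1e-6  # relative finite-difference step for parameter gradients


class BandsUnavailableError(RuntimeError):
    """Raised when a fit lacks the covariance needed for bands."""


@dataclass(frozen=True)
class BandSet:
    """Fitted curve with pointwise confidence and prediction bounds."""

    grid: np.ndarray
    fitted: np.ndarray
    conf_low: np.ndarray
    conf_high: np.ndarray
    pred_low: np.ndarray
    pred_high: np.ndarray
    alpha: float

    def clipped(self) -> "BandSet":
        """Copy with all saturation bounds clipped to [0, 1] for reporting."""
        c = lambda a: np.clip(a, 0.0, 1.0)
        return BandSet(
            self.grid, c(self.fitted), c(self.conf_low), c(self.conf_high),
            c(self.pred_low), c(self.pred_high), self.alpha,
        )


def _gradients(model, theta: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Central finite-difference gradient of model(grid) in theta, (m, k)."""
    k = theta.size
    grads = np.empty((grid.size, k))
    for j in range(k):
        step = _REL_STEP * max(abs(theta[j]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        grads[:, j] = (np.asarray(model(grid, tp)) - np.asarray(model(grid, tm))) / (2 * step)
    return grads


def delta_method_bands(
    model, theta: np.ndarray, covariance: np.ndarray, sigma2: float,
    dof: int, grid: np.ndarray, alpha: float,
) -> BandSet:
    """Generic delta-method bands for any parametric curve.

    ``model(grid, theta)`` evaluates the curve; ``covariance`` is the
    parameter covariance, ``sigma2`` the residual variance estimate and
    ``dof`` the residual degrees of freedom for the t quantile.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if dof < 1:
        raise ValueError("need at least one residual degree of freedom")
    grid = np.asarray(grid, dtype=float)
    fitted = np.asarray(model(grid, theta), dtype=float)
    g = _gradients(model, np.asarray(theta, dtype=float), grid)
    var_mean = np.einsum("ij,jk,ik->i", g, covariance, g)
    var_mean = np.maximum(var_mean, 0.0)
    t = stats.t.ppf(1.0 - alpha / 2.0, dof)
    conf_hw = t * np.sqrt(var_mean)
    pred_hw = t * np.sqrt(sigma2 + var_mean)
    return BandSet(
        grid=grid,
        fitted=fitted,
        conf_low=fitted - conf_hw,
        conf_high=fitted + conf_hw,
        pred_low=fitted - pred_hw,
        pred_high=fitted + pred_hw,
        alpha=alpha,
    )


def compute_bands(
    fit: FitResult, data: ODCDataset, grid, alpha: float = 0.0001
) -> BandSet:
    """Delta-method bands for a converged fit on a pressure grid.

    The default significance level 1e-4 gives 99.99% pointwise
    intervals.  Raw (unclipped) bounds are returned; use
    :meth:`BandSet.clipped` when serializing saturations.
    """
    if not fit.converged:
        raise BandsUnavailableError("fit did not converge; bands undefined")
    if fit.covariance is None:
        raise BandsUnavailableError("parameter covariance unavailable")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid pressures must be positive")
    n, k = len(data), fit.n_params
    if n <= k:
        raise BandsUnavailableError("no residual degrees of freedom")
    sigma2 = fit.best_objective / (n - k)
    model = _model_fn(fit.model_kind)
    return delta_method_bands(model, fit.theta, fit.covariance, sigma2, n - k, grid, alpha)
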