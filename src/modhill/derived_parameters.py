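"""Derived cooperativity descriptors of a modulated-Hill fit.

From the four fitted parameters (p50, h_max - 1, ln p_max, s) a set of
secondary quantities characterizes the oxygenation curve: the peak
Hill coefficient h_max and its grid average h_bar, the pressure of
maximal cooperativity p_max and the saturation reached there, the
relative subunit cooperativity theta(n) defined through
``h_max = theta (n - 1) + 1``, and the pressure band
``[pO2_low, pO2_high]`` inside which the excess cooperativity
``h(p) - 1`` stays above a fraction ``omega`` of its peak value.

Band bounds are closed forms on the log-pressure axis: the Gaussian
profile gives ``exp(ln p_max -/+ s sqrt(-ln omega))``, the Lorentzian
``exp(ln p_max -/+ s sqrt(1/omega - 1))``.  ``omega = 0.5`` gives the
half-width at half-maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .binding_models import (
    ModulatedHillParams,
    hill_coefficient,
    modulated_hill_saturation,
)

__all__ = [
    "DerivedParams",
    "h_max_from_fit",
    "theta_relative_cooperativity",
    "cooperativity_band",
    "mean_hill_coefficient",
    "derive_all",
    "DEFAULT_GRID",
    "DEFAULT_OMEGA",
    "DEFAULT_N_SUBUNITS",
]

# h_bar averages over a uniform pressure grid; this fallback range
# covers the physiological span when no dataset supplies one.
DEFAULT_GRID = (1.0, 150.0, 1000)
DEFAULT_OMEGA = 0.99
DEFAULT_N_SUBUNITS = 4


@dataclass(frozen=True)
class DerivedParams:
    """All secondary descriptors computed from one modulated-Hill fit."""

    h_max: float
    h_bar: float
    delta_h: float
    p_max: float
    sat_at_pmax: float
    delta_sat: float
    delta_pmax_o2: float
    omega: float
    pO2_low: float
    pO2_high: float
    delta_pO2: float
    theta: float
    n_subunits: int

    def __post_init__(self):
        if not self.pO2_low <= self.p_max <= self.pO2_high:
            raise ValueError("band must bracket p_max")
        if self.h_bar > self.h_max + 1e-12:
            raise ValueError("h_bar cannot exceed h_max")


def h_max_from_fit(params: ModulatedHillParams) -> float:
    """Peak Hill coefficient ``h_max = (h_max - 1) + 1``."""
    return params.hmax_minus1 + 1.0


def theta_relative_cooperativity(h_max: float, n: int = DEFAULT_N_SUBUNITS) -> float:
    """Relative cooperativity ``theta = (h_max - 1)/(n - 1)`` of an n-mer.

    theta = 1 means fully concerted subunits (h_max = n), theta = 0
    means independent binding (h_max = 1).
    """
    if n < 2:
        raise ValueError("theta requires at least 2 subunits")
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    return (h_max - 1.0) / (n - 1.0)


def cooperativity_band(
    params: ModulatedHillParams, omega: float = DEFAULT_OMEGA
) -> Tuple[float, float, float]:
    """Pressure band where the excess cooperativity exceeds ``omega`` of its peak.

    Returns ``(pO2_low, pO2_high, delta_pO2)`` in mm Hg.  At the two
    bounds ``h(p) - 1`` equals exactly ``omega * (h_max - 1)``.
    """
    if not 0.0 < omega < 1.0:
        raise ValueError("omega must lie strictly between 0 and 1")
    if params.profile == "gauss":
        half = params.s * np.sqrt(-np.log(omega))
    else:
        half = params.s * np.sqrt(1.0 / omega - 1.0)
    lo = float(np.exp(params.ln_pmax - half))
    hi = float(np.exp(params.ln_pmax + half))
    return lo, hi, hi - lo


def mean_hill_coefficient(
    params: ModulatedHillParams, grid: Tuple[float, float, int] = DEFAULT_GRID
) -> float:
    """Arithmetic mean of h(p) over a uniformly spaced pressure grid."""
    lo, hi, count = grid
    if not (lo > 0 and hi > lo and count >= 2):
        raise ValueError("grid must be (lo > 0, hi > lo, count >= 2)")
    p = np.linspace(lo, hi, int(count))
    return float(np.mean(hill_coefficient(p, params)))


def derive_all(
    params: ModulatedHillParams,
    omega: float = DEFAULT_OMEGA,
    n: int = DEFAULT_N_SUBUNITS,
    grid: Tuple[float, float, int] = DEFAULT_GRID,
) -> DerivedParams:
    """Compute the full descriptor set; a pure function of its inputs."""
    h_max = h_max_from_fit(params)
    h_bar = mean_hill_coefficient(params, grid)
    p_max = params.pmax
    sat = float(modulated_hill_saturation(p_max, params))
    lo, hi, width = cooperativity_band(params, omega)
    return DerivedParams(
        h_max=h_max,
        h_bar=h_bar,
        delta_h=h_max - h_bar,
        p_max=p_max,
        sat_at_pmax=sat,
        delta_sat=sat - 0.5,
        delta_pmax_o2=p_max - params.p50,
        omega=omega,
        pO2_low=lo,
        pO2_high=hi,
        delta_pO2=width,
        theta=theta_relative_cooperativity(h_max, n),
        n_subunits=n,
    )
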