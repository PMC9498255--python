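"""Saturation models for cooperative ligand binding.

Four models of the fractional saturation ``y(p)`` of a tetrameric
carrier (hemoglobin is the motivating case) as a function of ligand
partial pressure ``p`` (mm Hg):

* classic Hill: ``y = p^h / (p50^h + p^h)`` with a constant Hill
  coefficient ``h``;
* Adair (Adair-Klotz): the four-step sequential-binding polynomial
  with macroscopic association constants ``K1..K4``;
* modulated Hill (Gauss or Lorentz): the Hill form evaluated with a
  pressure-dependent coefficient ``h(p) = 1 + (h_max - 1) * G(x)``
  where ``x = (ln p - ln p_max) / s`` and ``G`` is a Gaussian
  ``exp(-x^2)`` or Lorentzian ``1 / (1 + x^2)`` peak profile.

All functions are pure, accept scalars or array-likes, and return
numpy scalars/arrays of matching shape.  Saturations are fractions in
[0, 1]; percent is an I/O concern handled at the package boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ODCDataset",
    "HillClassicParams",
    "AdairParams",
    "ModulatedHillParams",
    "hill_classic_saturation",
    "hill_macroscopic_constant",
    "adair_saturation",
    "hill_coefficient",
    "modulated_hill_saturation",
]

Profile = Literal["gauss", "lorentz"]


class DomainError(ValueError):
    """Raised when an input lies outside a model's physical domain."""


def _as_pressure(p, *, allow_zero: bool) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("pressure must be finite")
    if allow_zero:
        if np.any(arr < 0):
            raise DomainError("pressure must be >= 0")
    elif np.any(arr <= 0):
        raise DomainError("pressure must be > 0")
    return arr


@dataclass(frozen=True)
class ODCDataset:
    """Paired (pressure, saturation) observations of a dissociation curve.

    Pressures are mm Hg, saturations are fractions in [0, 1].  The
    constructor sorts the points by pressure; duplicate pressures are
    allowed (replicate measurements).
    """

    pressures: np.ndarray
    saturations: np.ndarray
    label: str = ""

    def __init__(self, pressures: Sequence[float], saturations: Sequence[float], label: str = ""):
        p = np.asarray(pressures, dtype=float)
        y = np.asarray(saturations, dtype=float)
        if p.ndim != 1 or y.ndim != 1 or p.shape != y.shape:
            raise ValueError("pressures and saturations must be equal-length 1-D sequences")
        if p.size == 0:
            raise ValueError("dataset is empty")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in dataset")
        if np.any(p <= 0):
            raise ValueError("all pressures must be positive")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("all saturations must lie in [0, 1]")
        order = np.argsort(p, kind="stable")
        object.__setattr__(self, "pressures", p[order])
        object.__setattr__(self, "saturations", y[order])
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return self.pressures.size


@dataclass(frozen=True)
class HillClassicParams:
    """Classic Hill parameters: half-saturation pressure and coefficient."""

    p50: float
    h: float

    def __post_init__(self):
        if not (np.isfinite(self.p50) and self.p50 > 0):
            raise ValueError("p50 must be positive and finite")
        if not (np.isfinite(self.h) and self.h > 0):
            raise ValueError("h must be positive and finite")


@dataclass(frozen=True)
class AdairParams:
    """Macroscopic association constants of the four-step Adair scheme.

    Units: K1 in mmHg^-1 ... K4 in mmHg^-4.  K4 must be strictly
    positive so the tetramer saturates.
    """

    K1: float
    K2: float
    K3: float
    K4: float

    def __post_init__(self):
        ks = (self.K1, self.K2, self.K3, self.K4)
        if not all(np.isfinite(k) and k >= 0 for k in ks):
            raise ValueError("Adair constants must be finite and non-negative")
        if self.K4 <= 0:
            raise ValueError("K4 must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.K3, self.K4])


@dataclass(frozen=True)
class ModulatedHillParams:
    """Parameters of the Hill model with a peaked, pressure-dependent coefficient.

    ``hmax_minus1`` is the excess cooperativity at the peak
    (``h_max - 1``), ``ln_pmax`` the natural log of the pressure of
    maximal cooperativity, and ``s`` the peak width on the log-pressure
    axis.  ``profile`` selects the Gaussian or Lorentzian peak shape.
    """

    p50: float
    hmax_minus1: float
    ln_pmax: float
    s: float
    profile: Profile = "lorentz"

    def __post_init__(self):
        if not (np.isfinite(self.p50) and self.p50 > 0):
            raise ValueError("p50 must be positive and finite")
        if not (np.isfinite(self.hmax_minus1) and self.hmax_minus1 >= 0):
            raise ValueError("hmax_minus1 must be non-negative and finite")
        if not np.isfinite(self.ln_pmax):
            raise ValueError("ln_pmax must be finite")
        if not (np.isfinite(self.s) and self.s > 0):
            raise ValueError("s must be positive and finite")
        if self.profile not in ("gauss", "lorentz"):
            raise ValueError("profile must be 'gauss' or 'lorentz'")

    @property
    def pmax(self) -> float:
        """Pressure of maximal cooperativity, mm Hg."""
        return float(np.exp(self.ln_pmax))


def hill_classic_saturation(p, params: HillClassicParams):
    """Classic Hill saturation ``p^h / (p50^h + p^h)``.

    Evaluated on the log scale for numerical stability at extreme
    pressure/coefficient combinations.
    """
    arr = _as_pressure(p, allow_zero=True)
    out = np.zeros_like(arr)
    pos = arr > 0
    # y = 1 / (1 + (p50/p)^h), computed via expit of h*ln(p/p50)
    t = params.h * (np.log(arr[pos]) - np.log(params.p50))
    out[pos] = 1.0 / (1.0 + np.exp(-t))
    return out if out.ndim else float(out)


def hill_macroscopic_constant(params: HillClassicParams) -> float:
    """Macroscopic association constant ``K = p50^(-h)`` (mmHg^-h)."""
    return float(params.p50 ** (-params.h))


def adair_saturation(p, params: AdairParams):
    """Adair fractional saturation of the tetramer.

    ``y = (K1 p + 2 K2 p^2 + 3 K3 p^3 + 4 K4 p^4)
    / (4 (1 + K1 p + K2 p^2 + K3 p^3 + K4 p^4))``.
    """
    arr = _as_pressure(p, allow_zero=True)
    K1, K2, K3, K4 = params.K1, params.K2, params.K3, params.K4
    num = arr * (K1 + arr * (2 * K2 + arr * (3 * K3 + arr * 4 * K4)))
    den = 4.0 * (1.0 + arr * (K1 + arr * (K2 + arr * (K3 + arr * K4))))
    out = num / den
    return out if out.ndim else float(out)


def _peak(x: np.ndarray, profile: Profile) -> np.ndarray:
    if profile == "gauss":
        return np.exp(-x * x)
    return 1.0 / (1.0 + x * x)


def hill_coefficient(p, params: ModulatedHillParams):
    """Pressure-dependent Hill coefficient ``h(p) = 1 + (h_max - 1) G(x)``.

    ``x = (ln p - ln p_max) / s``; the coefficient peaks at exactly
    ``h_max = 1 + hmax_minus1`` at ``p = p_max`` and decays to 1 (no
    cooperativity) at both pressure extremes.
    """
    arr = _as_pressure(p, allow_zero=False)
    x = (np.log(arr) - params.ln_pmax) / params.s
    out = 1.0 + params.hmax_minus1 * _peak(x, params.profile)
    return out if out.ndim else float(out)


def modulated_hill_saturation(p, params: ModulatedHillParams):
    """Hill saturation with the pressure-dependent coefficient.

    ``y = p^h(p) / (p50^h(p) + p^h(p))``; equals 1/2 exactly at
    ``p = p50`` for any profile, since the coefficient only rescales
    the log-pressure distance from p50.
    """
    arr = _as_pressure(p, allow_zero=False)
    h = np.asarray(hill_coefficient(arr, params))
    t = h * (np.log(arr) - np.log(params.p50))
    out = 1.0 / (1.0 + np.exp(-t))
    return out if out.ndim else float(out)
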