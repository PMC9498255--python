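"""Seeded generation of synthetic oxygenation datasets.

The classic reference measurements of whole-blood oxygen equilibrium
(Winslow and colleagues; Severinghaus) are not redistributable here, so
this module generates stand-in curves: pressures on a log-spaced design
spanning the physiological range and saturations drawn from any of the
four binding models with additive homoscedastic Gaussian noise on the
saturation scale.  Published parameter estimates for those two data
sets are provided as generating truths so the synthetic curves have a
realistic shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .binding_models import (
    AdairParams,
    HillClassicParams,
    ModulatedHillParams,
    ODCDataset,
    adair_saturation,
    hill_classic_saturation,
    modulated_hill_saturation,
)

__all__ = ["SimSpec", "simulate", "default_odc_like_spec", "REFERENCE_FITS"]

# Published modulated-Hill parameter estimates for the two classic
# whole-blood oxygen-equilibrium data sets (human blood, 37 C, pH 7.4).
# Keys: (dataset, profile); values: (p50, hmax_minus1, pmax, s).
REFERENCE_FITS = {
    ("winslow", "gauss"): ModulatedHillParams(29.08, 1.66, float(np.log(52.92)), 3.33, "gauss"),
    ("winslow", "lorentz"): ModulatedHillParams(29.11, 1.68, float(np.log(47.82)), 1.80, "lorentz"),
    ("severinghaus", "gauss"): ModulatedHillParams(26.82, 1.82, float(np.log(80.85)), 3.59, "gauss"),
    ("severinghaus", "lorentz"): ModulatedHillParams(26.86, 1.82, float(np.log(67.28)), 1.91, "lorentz"),
}


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one synthetic dissociation-curve dataset.

    ``pressure_design`` is ``log_spaced`` or ``uniform`` over
    ``(p_min, p_max)`` with ``count`` points, or ``explicit`` with the
    pressures given directly.  ``noise_sd`` is the standard deviation
    of the additive Gaussian saturation noise; ``clip`` keeps noisy
    saturations inside [0, 1].
    """

    model_kind: Literal["hill_classic", "adair", "hill_gauss", "hill_lorentz"]
    params: object
    pressure_design: Literal["log_spaced", "uniform", "explicit"] = "log_spaced"
    p_min: float = 0.5
    p_max: float = 150.0
    count: int = 30
    pressures: Optional[Sequence[float]] = None
    noise_sd: float = 0.005
    seed: int = 0
    clip: bool = True
    label: str = "synthetic"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pressure_design == "explicit":
            if self.pressures is None or len(self.pressures) == 0:
                raise ValueError("explicit design requires pressures")
            if np.any(np.asarray(self.pressures, dtype=float) <= 0):
                raise ValueError("pressures must be positive")
        else:
            if self.count < 1:
                raise ValueError("count must be >= 1")
            if not (0 < self.p_min < self.p_max):
                raise ValueError("need 0 < p_min < p_max")
        _expected = {
            "hill_classic": HillClassicParams,
            "adair": AdairParams,
            "hill_gauss": ModulatedHillParams,
            "hill_lorentz": ModulatedHillParams,
        }
        if self.model_kind not in _expected:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not isinstance(self.params, _expected[self.model_kind]):
            raise ValueError(
                f"{self.model_kind} requires {_expected[self.model_kind].__name__}"
            )

    def design_pressures(self) -> np.ndarray:
        if self.pressure_design == "explicit":
            return np.sort(np.asarray(self.pressures, dtype=float))
        if self.pressure_design == "log_spaced":
            return np.geomspace(self.p_min, self.p_max, self.count)
        return np.linspace(self.p_min, self.p_max, self.count)


def _evaluate(spec: SimSpec, p: np.ndarray) -> np.ndarray:
    if spec.model_kind == "hill_classic":
        return np.asarray(hill_classic_saturation(p, spec.params))
    if spec.model_kind == "adair":
        return np.asarray(adair_saturation(p, spec.params))
    return np.asarray(modulated_hill_saturation(p, spec.params))


def simulate(spec: SimSpec) -> ODCDataset:
    """Generate one dataset; bit-reproducible for a fixed spec (incl. seed)."""
    p = spec.design_pressures()
    y = _evaluate(spec, p)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    if spec.clip:
        y = np.clip(y, 0.0, 1.0)
    elif np.any((y < 0) | (y > 1)):
        raise ValueError("noise pushed saturations outside [0, 1]; set clip=True")
    return ODCDataset(p, y, label=spec.label)


def default_odc_like_spec(dataset_style: str, seed: int = 0) -> SimSpec:
    """Spec emulating one of the two classic whole-blood data sets.

    ``winslow_like`` and ``severinghaus_like`` use the corresponding
    published Lorentz-profile modulated-Hill estimates as the
    generating truth, 30 log-spaced pressures over 0.5-150 mm Hg and
    0.005 saturation noise.
    """
    styles = {"winslow_like": "winslow", "severinghaus_like": "severinghaus"}
    if dataset_style not in styles:
        raise ValueError(f"dataset_style must be one of {sorted(styles)}")
    params = REFERENCE_FITS[(styles[dataset_style], "lorentz")]
    return SimSpec(
        model_kind="hill_lorentz",
        params=params,
        pressure_design="log_spaced",
        p_min=0.5,
        p_max=150.0,
        count=30,
        noise_sd=0.005,
        seed=seed,
        clip=True,
        label=dataset_style,
    )
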