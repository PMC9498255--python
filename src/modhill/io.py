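"""Dataset CSV reading/writing and JSON report serialization.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, ``#`` comment
lines, one header row.  Saturation columns may be fractions or percent;
any value above 1.5 is taken as percent and divided by 100.  JSON
reports carry a ``schema_version`` and floats rounded to 10
significant digits so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .binding_models import (
    AdairParams,
    HillClassicParams,
    ModulatedHillParams,
    ODCDataset,
)
from .derived_parameters import DerivedParams
from .model_fitting import FitResult
from .uncertainty_bands import BandSet

__all__ = [
    "ParseError",
    "read_odc_csv",
    "write_odc_csv",
    "fit_result_to_dict",
    "derived_to_dict",
    "write_json_report",
    "write_bands_csv",
    "params_from_dict",
]

SCHEMA_VERSION = 1

_PRESSURE_NAMES = ("po2_mmhg", "po2", "pressure", "p", "pressure_mmhg")
_SATURATION_NAMES = (
    "saturation_fraction", "saturation", "sat", "y", "hbo2", "hbo2_percent",
    "saturation_percent",
)


class ParseError(ValueError):
    """Malformed dataset file."""


def _find_column(columns, names, role: str) -> str:
    lowered = {str(c).strip().lower(): c for c in columns}
    for name in names:
        if name in lowered:
            return lowered[name]
    raise ParseError(f"no {role} column found among {list(columns)}")


def read_odc_csv(path) -> ODCDataset:
    """Read a pressure/saturation table into a validated dataset.

    Percent-scale saturations are detected (any value > 1.5) and
    rescaled to fractions.  Non-finite or non-numeric rows raise a
    :class:`ParseError` naming the offending data row (1-based, header
    and comments excluded).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    pcol = _find_column(frame.columns, _PRESSURE_NAMES, "pressure")
    scol = _find_column(frame.columns, _SATURATION_NAMES, "saturation")
    p = pd.to_numeric(frame[pcol], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(frame[scol], errors="coerce").to_numpy(dtype=float)
    bad = ~(np.isfinite(p) & np.isfinite(y))
    if np.any(bad):
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ParseError(f"{path}: non-numeric or non-finite value in data row {row}")
    if np.any(p <= 0):
        row = int(np.flatnonzero(p <= 0)[0]) + 1
        raise ParseError(f"{path}: non-positive pressure in data row {row}")
    if np.any(y > 1.5):  # percent scale
        y = y / 100.0
    if np.any((y < 0) | (y > 1)):
        row = int(np.flatnonzero((y < 0) | (y > 1))[0]) + 1
        raise ParseError(f"{path}: saturation outside [0, 1] in data row {row}")
    return ODCDataset(p, y, label=path.stem)


def write_odc_csv(data: ODCDataset, path, comment: Optional[str] = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("pO2_mmHg,saturation_fraction\n")
        for p, y in zip(data.pressures, data.saturations):
            fh.write(f"{_fmt(p)},{_fmt(y)}\n")


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(_fmt(obj))
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(_fmt(float(obj)))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _params_to_dict(params) -> dict:
    if isinstance(params, HillClassicParams):
        return {"kind": "hill_classic", "p50": params.p50, "h": params.h}
    if isinstance(params, AdairParams):
        return {"kind": "adair", "K1": params.K1, "K2": params.K2,
                "K3": params.K3, "K4": params.K4}
    if isinstance(params, ModulatedHillParams):
        return {
            "kind": f"hill_{params.profile}",
            "p50": params.p50,
            "hmax_minus1": params.hmax_minus1,
            "ln_pmax": params.ln_pmax,
            "pmax": params.pmax,
            "s": params.s,
            "profile": params.profile,
        }
    raise TypeError(f"unknown parameter record {type(params).__name__}")


def params_from_dict(d: dict):
    """Inverse of the parameter serialization used in fit reports."""
    kind = d["kind"]
    if kind == "hill_classic":
        return HillClassicParams(d["p50"], d["h"])
    if kind == "adair":
        return AdairParams(d["K1"], d["K2"], d["K3"], d["K4"])
    if kind in ("hill_gauss", "hill_lorentz"):
        ln_pmax = d["ln_pmax"] if "ln_pmax" in d else float(np.log(d["pmax"]))
        return ModulatedHillParams(
            d["p50"], d["hmax_minus1"], ln_pmax, d["s"], kind.split("_")[1]
        )
    raise ParseError(f"unknown parameter kind {kind!r}")


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model_kind": fit.model_kind,
        "params": _params_to_dict(fit.params),
        "r2": fit.r2,
        "best_objective": fit.best_objective,
        "converged": fit.converged,
        "n_starts_used": fit.n_starts_used,
        "n_points": int(fit.residuals.size),
        "residuals": fit.residuals,
        "covariance": None if fit.covariance is None else fit.covariance,
    }


def derived_to_dict(derived: DerivedParams) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "h_max": derived.h_max,
        "h_bar": derived.h_bar,
        "delta_h": derived.delta_h,
        "p_max": derived.p_max,
        "sat_at_pmax": derived.sat_at_pmax,
        "sat_at_pmax_percent": 100.0 * derived.sat_at_pmax,
        "delta_sat": derived.delta_sat,
        "delta_pmax_o2": derived.delta_pmax_o2,
        "omega": derived.omega,
        "pO2_low": derived.pO2_low,
        "pO2_high": derived.pO2_high,
        "delta_pO2": derived.delta_pO2,
        "theta": derived.theta,
        "n_subunits": derived.n_subunits,
    }


def write_json_report(obj: dict, path) -> None:
    """Write a report with deterministic float formatting and key order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bands_csv(bands: BandSet, path, clip: bool = True) -> None:
    b = bands.clipped() if clip else bands
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# alpha = {_fmt(b.alpha)}\n")
        fh.write("p,fitted,conf_low,conf_high,pred_low,pred_high\n")
        for row in zip(b.grid, b.fitted, b.conf_low, b.conf_high, b.pred_low, b.pred_high):
            fh.write(",".join(_fmt(v) for v in row) + "\n")
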