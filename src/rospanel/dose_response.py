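"""Resazurin viability normalization and IC25 estimation.

Raw fluorescence readouts (resorufin turnover, proportional to viable
metabolic activity) are normalized per (cell line, treatment) to the
untreated control (dose 0), and a log-logistic viability model is fitted
on log10 dose by nonlinear least squares:

    v(d) = 1 / (1 + (d / EC50)^h)                     (2-parameter)
    v(d) = b + (1 - b) / (1 + (d / EC50)^h)           (3-parameter)

IC25 is the dose where fitted viability equals 0.75 (25% inhibition):
EC50 * 3^(-1/h) for the 2-parameter model, and
EC50 * (0.25 / (0.75 - b))^(1/h) for the 3-parameter one (defined only
for b < 0.75). With 3-4 tested doses a fit with free top and bottom is
under-determined, so the 2-parameter model (top 1, bottom 0) is the
default. The "dose" may be a concentration or, for a gas-plasma jet, an
exposure time in seconds; both titrate identically on the log scale.

Fitting uses a multi-start strategy over EC50 initialized at every tested
dose crossed with Hill slopes {0.5, 1, 2, 4}; the lowest-RMSE solution is
kept, ties broken toward the smaller slope. Responses above 1 (stimulated
metabolism) are kept, not clipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr as _scipy_spearmanr

from rospanel.errors import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_line", "treatment", "dose", "replicate", "fluorescence")

_HILL_STARTS = (0.5, 1.0, 2.0, 4.0)
_HILL_BOUNDS = (1e-2, 50.0)


@dataclass(frozen=True)
class ViabilityCurve:
    """Mean normalized responses of one (cell line, treatment) group."""

    cell_line: str
    treatment: str
    doses: np.ndarray  # strictly positive, ascending
    responses: np.ndarray  # mean fluorescence at dose / control mean
    control_mean: float


@dataclass(frozen=True)
class IC25Estimate:
    """Fitted IC25 with diagnostics; ic25 is NaN when the fit failed."""

    cell_line: str
    treatment: str
    ic25: float
    ec50: float
    hill: float
    rmse: float
    converged: bool
    #: True when the IC25 falls outside the tested dose range.
    extrapolated: bool
    bottom: float = 0.0
    message: str = ""


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"dose-response table missing columns: {missing}")
    if (records["dose"] < 0).any():
        raise ValidationError("negative dose values present")
    if (records["fluorescence"] < 0).any():
        raise ValidationError("negative fluorescence values present")
    return records


def normalize_viability(records: pd.DataFrame) -> dict[tuple[str, str], ViabilityCurve]:
    """Normalize fluorescence to the untreated control per group.

    For each (cell_line, treatment): response(d) = mean fluorescence at
    dose d divided by the mean fluorescence at dose 0. Groups must
    contain at least one dose-0 record and two distinct non-zero doses.
    """
    _validate_records(records)
    curves: dict[tuple[str, str], ViabilityCurve] = {}
    for (line, trt), grp in records.groupby(["cell_line", "treatment"], sort=False):
        controls = grp.loc[grp["dose"] == 0, "fluorescence"]
        if controls.empty:
            raise ValidationError(f"missing dose-0 control for ({line}, {trt})")
        control_mean = float(controls.mean())
        if control_mean == 0:
            raise ValidationError(f"zero control mean for ({line}, {trt})")
        treated = grp[grp["dose"] > 0]
        means = treated.groupby("dose")["fluorescence"].mean().sort_index()
        if len(means) < 2:
            raise ValidationError(
                f"({line}, {trt}): need >= 2 distinct non-zero doses, got {len(means)}"
            )
        curves[(line, trt)] = ViabilityCurve(
            cell_line=line,
            treatment=trt,
            doses=means.index.to_numpy(dtype=float),
            responses=(means / control_mean).to_numpy(dtype=float),
            control_mean=control_mean,
        )
    return curves


def _loglogistic2(logd: np.ndarray, log_ec50: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (h * (logd - log_ec50)))


def _loglogistic3(logd: np.ndarray, log_ec50: float, h: float, b: float) -> np.ndarray:
    return b + (1.0 - b) / (1.0 + 10.0 ** (h * (logd - log_ec50)))


def fit_ic25(curve: ViabilityCurve, model_variant: str = "two_param") -> IC25Estimate:
    """Fit the log-logistic model and invert it at 75% viability.

    ``model_variant`` is ``"two_param"`` (default; needs >= 2 points) or
    ``"three_param"`` (free bottom; needs >= 4 points). A group whose
    responses all sit at or above 0.75 with no downward trend carries no
    information about 25% inhibition and is reported unconverged.
    """
    d = np.asarray(curve.doses, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    three = model_variant == "three_param"
    if model_variant not in ("two_param", "three_param"):
        raise ValidationError(f"unknown model variant {model_variant!r}")
    min_pts = 4 if three else 2
    if len(d) < min_pts:
        raise ValidationError(
            f"{model_variant} fit needs >= {min_pts} dose points, got {len(d)}"
        )

    def _fail(msg: str) -> IC25Estimate:
        return IC25Estimate(
            cell_line=curve.cell_line, treatment=curve.treatment,
            ic25=math.nan, ec50=math.nan, hill=math.nan, rmse=math.nan,
            converged=False, extrapolated=False, bottom=math.nan, message=msg,
        )

    if (y >= 0.75).all():
        trend = _scipy_spearmanr(d, y).statistic if len(d) > 2 else (y[-1] - y[0])
        if not (trend < 0):
            return _fail("no 25% inhibition in tested range")

    logd = np.log10(d)
    lo, hi = logd.min() - 3.0, logd.max() + 3.0
    best = None  # (rmse, h, params)
    for log_ec50_0 in logd:
        for h0 in _HILL_STARTS:
            if three:
                x0 = [log_ec50_0, h0, 0.0]
                bounds = ([lo, _HILL_BOUNDS[0], 0.0], [hi, _HILL_BOUNDS[1], 0.999])
                fun = lambda p: _loglogistic3(logd, *p) - y
            else:
                x0 = [log_ec50_0, h0]
                bounds = ([lo, _HILL_BOUNDS[0]], [hi, _HILL_BOUNDS[1]])
                fun = lambda p: _loglogistic2(logd, *p) - y
            try:
                sol = least_squares(fun, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:  # pragma: no cover - pathological numerics
                continue
            if not sol.success:
                continue
            rmse = float(np.sqrt(np.mean(sol.fun**2)))
            h_fit = float(sol.x[1])
            if best is None or rmse < best[0] - 1e-15 or (
                abs(rmse - best[0]) <= 1e-15 and h_fit < best[1]
            ):
                best = (rmse, h_fit, sol.x)
    if best is None:
        return _fail("nonlinear fit did not converge from any start")

    rmse, h, params = best
    ec50 = float(10.0 ** params[0])
    b = float(params[2]) if three else 0.0
    if three and b >= 0.75:
        return IC25Estimate(
            cell_line=curve.cell_line, treatment=curve.treatment,
            ic25=math.nan, ec50=ec50, hill=h, rmse=rmse, converged=False,
            extrapolated=False, bottom=b,
            message="fitted bottom >= 0.75: 25% inhibition unreachable",
        )
    if three:
        ic25 = ec50 * (0.25 / (0.75 - b)) ** (1.0 / h)
    else:
        ic25 = ec50 * 3.0 ** (-1.0 / h)
    extrapolated = not (d.min() <= ic25 <= d.max())
    return IC25Estimate(
        cell_line=curve.cell_line, treatment=curve.treatment,
        ic25=float(ic25), ec50=ec50, hill=h, rmse=rmse, converged=True,
        extrapolated=bool(extrapolated), bottom=b,
    )


def dynamic_range(ic25_values) -> float:
    """max(IC25)/min(IC25) over the panel for one treatment.

    Missing (NaN) estimates are excluded with a logged count; at least
    two finite values are required.
    """
    vals = pd.Series(ic25_values, dtype=float)
    n_missing = int(vals.isna().sum())
    vals = vals.dropna()
    if n_missing:
        logger.info("dynamic_range: excluded %d missing IC25 values", n_missing)
    if len(vals) < 2:
        raise ValidationError("dynamic range needs >= 2 non-missing IC25 estimates")
    return float(vals.max() / vals.min())


def baseline_metabolism(records: pd.DataFrame) -> pd.Series:
    """Mean untreated-control fluorescence per cell line.

    Pools dose-0 rows over treatments and replicates; the result is the
    panel's baseline metabolic activity readout.
    """
    _validate_records(records)
    controls = records[records["dose"] == 0]
    if controls.empty:
        raise ValidationError("no dose-0 control records present")
    out = controls.groupby("cell_line")["fluorescence"].mean()
    out.name = "baseline_fluorescence"
    return out
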