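"""Candidate calibration response functions and inverse prediction.

Four response functions are supported, matching common practice when
selecting a calibration model for a total-error validation:

``ols_linear``
    Simple unweighted least squares of response on concentration.
``single_point_120``
    Through-origin line whose slope is fixed by the mean response at the
    highest design level (the 120% level) only.
``weighted_1overX``
    Weighted least squares with weights 1/concentration, down-weighting the
    heteroscedastic top of the range.
``sqrt_linear``
    Unweighted least squares after square-root transformation of BOTH axes
    (sqrt(response) on sqrt(concentration)), the usual variance-stabilising
    choice.

Back-calculation (inverse prediction) is always performed on the fit's own
scale, with the calibration fit of the same series as the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import MeasurementTable
from .errors import DomainError, FitError

MODEL_KINDS = ("ols_linear", "single_point_120", "weighted_1overX", "sqrt_linear")

#: short CLI aliases
MODEL_ALIASES = {
    "ols": "ols_linear",
    "sp120": "single_point_120",
    "w1x": "weighted_1overX",
    "sqrt": "sqrt_linear",
}


def resolve_model_kind(name: str) -> str:
    kind = MODEL_ALIASES.get(name, name)
    if kind not in MODEL_KINDS:
        raise FitError(f"unknown model kind {name!r}; expected one of {MODEL_KINDS}")
    return kind


@dataclass(frozen=True)
class CalibrationFit:
    """One response function fitted to one series' calibration standards.

    ``slope``/``intercept`` are on the fitting scale (transformed scale for
    ``sqrt_linear``); ``r_squared`` is likewise computed on the fitting scale
    and is NaN for the single-point model, where it is undefined.
    """

    model_kind: str
    series_id: object
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise FitError(f"unknown model kind {self.model_kind!r}")
        if self.slope == 0:
            raise FitError("zero slope: calibration is non-informative")

    def predict(self, concentration: float):
        """Predicted response at a concentration, on the raw response scale."""
        c = np.asarray(concentration, dtype=float)
        if self.model_kind == "sqrt_linear":
            return (self.slope * np.sqrt(c) + self.intercept) ** 2
        if self.model_kind == "single_point_120":
            return self.slope * c
        return self.slope * c + self.intercept

    def back_calculate(self, response: float):
        """Inverse prediction of concentration from a response.

        For the linear kinds a negative back-calculated concentration is
        returned as-is: it is a meaningful (if extreme) bias observation,
        not an error.  The square-root model raises :class:`DomainError`
        when the response or the inverse-predicted sqrt-concentration is
        negative, since the transform is then undefined.
        """
        y = np.asarray(response, dtype=float)
        if self.model_kind == "sqrt_linear":
            if np.any(y < 0):
                raise DomainError("negative response under sqrt transformation")
            s = (np.sqrt(y) - self.intercept) / self.slope
            if np.any(s < 0):
                raise DomainError(
                    "inverse prediction gives negative sqrt(concentration)"
                )
            return s**2
        if self.model_kind == "single_point_120":
            return y / self.slope
        return (y - self.intercept) / self.slope


def fit_model(
    concentrations,
    responses,
    model_kind: str,
    series_id: object = None,
) -> CalibrationFit:
    """Fit one response function to (concentration, response) points."""
    model_kind = resolve_model_kind(model_kind)
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("concentrations and responses must be 1-D and equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("non-finite calibration points")

    if model_kind == "single_point_120":
        top = x.max()
        at_top = np.isclose(x, top)
        if not at_top.any():
            raise FitError("no calibration point at the top level")
        slope = float(np.mean(y[at_top]) / top)
        return CalibrationFit(model_kind, series_id, slope, 0.0, math.nan, int(at_top.sum()))

    if np.unique(x).size < 2:
        raise FitError("need at least 2 distinct concentrations")

    if model_kind == "sqrt_linear":
        if np.any(x < 0) or np.any(y < 0):
            raise DomainError("sqrt transformation requires non-negative data")
        xf, yf = np.sqrt(x), np.sqrt(y)
        res = sm.OLS(yf, sm.add_constant(xf)).fit()
    elif model_kind == "weighted_1overX":
        if np.any(x <= 0):
            raise DomainError("1/X weighting requires positive concentrations")
        res = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
    else:  # ols_linear
        res = sm.OLS(y, sm.add_constant(x)).fit()

    intercept, slope = (float(v) for v in res.params)
    return CalibrationFit(
        model_kind, series_id, slope, intercept, float(res.rsquared), int(x.size)
    )


def fit_all_series(table: MeasurementTable, model_kind: str) -> list[CalibrationFit]:
    """One fit per series, each on that series' calibration records only."""
    fits = []
    for sid in table.series_ids:
        cal = table.calibration(series_id=sid)
        if cal.empty:
            raise FitError(f"series {sid!r} has no calibration records")
        fits.append(
            fit_model(
                cal["nominal_concentration"], cal["response"], model_kind, series_id=sid
            )
        )
    return fits
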