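"""Total-error accuracy profile: variance components, beta-expectation
tolerance intervals, and LLOQ/ULOQ decisions.

The statistical model at each concentration level j is the balanced one-way
random-effects model for the back-calculated concentration x of a validation
standard measured in series i (day), replicate k:

    x_ik = mu_j + alpha_i + eps_ik,   alpha_i ~ N(0, sigma2_B),
                                      eps_ik  ~ N(0, sigma2_W),

with p series and n replicates per series.  From the method-of-moments
(ANOVA) estimates of the two variance components, the beta-expectation
tolerance interval on the relative-error scale is

    bias_j +/- t_{nu, (1+beta)/2} * sqrt(1 + 1/(p*n*B^2)) * s_R,

where s_R is the intermediate-precision RSD (both components), R is the
variance ratio sigma2_B/sigma2_W, B^2 = (R+1)/(n*R+1), and nu is the
Satterthwaite degrees of freedom

    nu = (R+1)^2 / [ (R + 1/n)^2/(p-1) + (1 - 1/n)/(p*n) ].

The multiplier sqrt(1 + 1/(p*n*B^2))*s_R equals the square root of
Var(new observation) + Var(grand mean), so the interval is a Satterthwaite
prediction interval for a single future result: on average a proportion
beta of future results falls inside it.

A method is declared valid over the concentration range where every level's
interval lies within the acceptance limits +/-lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datamodel import MeasurementTable, ValidationDesign
from .errors import DesignError, FitError
from .response_models import CalibrationFit, MODEL_KINDS, fit_all_series


# ---------------------------------------------------------------------------
# variance components


def variance_components(backcalc, p: int | None = None, n: int | None = None):
    """ANOVA (method-of-moments) variance components of a balanced p x n grid.

    Parameters
    ----------
    backcalc : array-like, shape (p, n)
        Back-calculated concentrations, one row per series.

    Returns
    -------
    (sigma2_within, sigma2_between) : tuple of float
        ``sigma2_within`` is the pooled within-series mean square;
        ``sigma2_between`` is ``max(0, (MS_between - MS_within)/n)``
        (negative moment estimates are truncated at zero).
    """
    x = np.asarray(backcalc, dtype=float)
    if x.ndim != 2:
        raise DesignError("expected a 2-D (series x replicate) grid")
    if p is not None and x.shape[0] != p:
        raise DesignError(f"expected {p} series, got {x.shape[0]}")
    if n is not None and x.shape[1] != n:
        raise DesignError(f"expected {n} replicates, got {x.shape[1]}")
    p_, n_ = x.shape
    if p_ < 2 or n_ < 2:
        raise DesignError("variance components need p >= 2 and n >= 2")
    if not np.all(np.isfinite(x)):
        raise DesignError("non-finite values in the grid")
    ms_within = float(np.mean(np.var(x, axis=1, ddof=1)))
    ms_between = float(n_ * np.var(np.mean(x, axis=1), ddof=1))
    sigma2_between = max(0.0, (ms_between - ms_within) / n_)
    return ms_within, sigma2_between


def satterthwaite_dof(R: float, p: int, n: int) -> float:
    """Satterthwaite degrees of freedom of the intermediate-precision
    variance, as a function of the variance ratio R = sigma2_B/sigma2_W.

    Tends to p-1 as R -> inf and stays finite and positive at R = 0.
    """
    if p < 2 or n < 1:
        raise DesignError("need p >= 2 series")
    if math.isinf(R):
        return float(p - 1)
    return (R + 1.0) ** 2 / (
        (R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n)
    )


def b_factor_squared(R: float, n: int) -> float:
    """B^2 = (R+1)/(nR+1), in (0, 1]; relates Var(grand mean) to s_R^2."""
    if math.isinf(R):
        return 1.0 / n
    return (R + 1.0) / (n * R + 1.0)


def beta_eti(
    relative_bias_pct: float,
    rsd_intermediate_pct: float,
    R: float,
    p: int,
    n: int,
    beta: float = 0.95,
) -> tuple[float, float]:
    """Beta-expectation tolerance interval on the relative-error (%) scale.

    Degenerates to ``[bias, bias]`` when the intermediate-precision RSD is
    zero (noiseless data), without evaluating the degrees of freedom.
    """
    if not 0.0 < beta < 1.0:
        raise DesignError("beta must lie in (0, 1)")
    if rsd_intermediate_pct < 0 or R < 0:
        raise DesignError("RSD and variance ratio must be non-negative")
    if rsd_intermediate_pct == 0.0:
        return (relative_bias_pct, relative_bias_pct)
    nu = satterthwaite_dof(R, p, n)
    q = float(stats.t.ppf((1.0 + beta) / 2.0, nu))
    half = q * math.sqrt(1.0 + 1.0 / (p * n * b_factor_squared(R, n))) * rsd_intermediate_pct
    return (relative_bias_pct - half, relative_bias_pct + half)


# ---------------------------------------------------------------------------
# per-level statistics


@dataclass(frozen=True)
class LevelStats:
    """All per-level quantities of the accuracy profile."""

    level_index: int
    nominal_concentration: float
    mean_backcalc: float
    relative_bias_pct: float
    sigma2_within: float        # concentration^2 units
    sigma2_between: float
    rsd_repeatability_pct: float
    rsd_intermediate_pct: float
    variance_ratio: float       # R = sigma2_B / sigma2_W
    b_factor: float             # B_j in (0, 1]
    dof: float
    t_quantile: float
    beta_eti_low_pct: float
    beta_eti_high_pct: float

    def passes(self, lambda_limit: float) -> bool:
        return (
            self.beta_eti_low_pct >= -lambda_limit
            and self.beta_eti_high_pct <= lambda_limit
        )


def level_stats_from_grid(
    backcalc_grid, nominal: float, level_index: int = 0, beta: float = 0.95
) -> LevelStats:
    """Level statistics from a balanced (series x replicate) grid of
    back-calculated concentrations."""
    x = np.asarray(backcalc_grid, dtype=float)
    p, n = x.shape
    s2w, s2b = variance_components(x)
    mean = float(x.mean())
    bias = 100.0 * (mean - nominal) / nominal
    sd_ip = math.sqrt(s2w + s2b)
    rsd_r = 100.0 * math.sqrt(s2w) / mean
    rsd_ip = 100.0 * sd_ip / mean
    if s2w == 0.0 and s2b == 0.0:
        R: float = 0.0
        b2 = 1.0
        nu = math.nan
        q = math.nan
        low = high = bias
    else:
        R = s2b / s2w if s2w > 0 else math.inf
        b2 = b_factor_squared(R, n)
        nu = satterthwaite_dof(R, p, n)
        q = float(stats.t.ppf((1.0 + beta) / 2.0, nu))
        low, high = beta_eti(bias, rsd_ip, R, p, n, beta)
    return LevelStats(
        level_index=level_index,
        nominal_concentration=float(nominal),
        mean_backcalc=mean,
        relative_bias_pct=bias,
        sigma2_within=s2w,
        sigma2_between=s2b,
        rsd_repeatability_pct=rsd_r,
        rsd_intermediate_pct=rsd_ip,
        variance_ratio=R,
        b_factor=math.sqrt(b2),
        dof=nu,
        t_quantile=q,
        beta_eti_low_pct=low,
        beta_eti_high_pct=high,
    )


def backcalc_grid(
    table: MeasurementTable,
    fits: list[CalibrationFit],
    level_index: int,
    **filters,
) -> np.ndarray:
    """Back-calculate the validation responses at one level, arranged as a
    balanced (series x replicate) grid using each series' own fit."""
    design = table.design
    by_series = {f.series_id: f for f in fits}
    rows = []
    for sid in table.series_ids:
        if sid not in by_series:
            raise DesignError(f"no calibration fit for series {sid!r}")
        cell = table.validation(series_id=sid, level_index=level_index, **filters)
        cell = cell.sort_values("replicate_index")
        if len(cell) != design.n_replicates:
            raise DesignError(
                f"level {level_index}, series {sid!r}: expected "
                f"{design.n_replicates} validation replicates, got {len(cell)}"
            )
        rows.append(by_series[sid].back_calculate(cell["response"].to_numpy()))
    return np.asarray(rows, dtype=float)


def level_stats(
    table: MeasurementTable,
    fits: list[CalibrationFit],
    level_index: int,
    beta: float = 0.95,
    **filters,
) -> LevelStats:
    """Accuracy-profile statistics at one concentration level.

    Each validation response is back-calculated through the calibration fit
    of its own series (day) before the variance decomposition.
    """
    grid = backcalc_grid(table, fits, level_index, **filters)
    nominal = table.design.level_concentration(level_index)
    return level_stats_from_grid(grid, nominal, level_index, beta)


# ---------------------------------------------------------------------------
# profile assembly


@dataclass(frozen=True)
class AccuracyProfile:
    levels: tuple[LevelStats, ...]
    lambda_limit_pct: float
    beta: float
    lloq: float | None          # ug/mL
    uloq: float | None
    valid: bool
    model_kind: str | None = None
    target_concentration: float | None = None

    @property
    def lloq_pct(self) -> float | None:
        if self.lloq is None or not self.target_concentration:
            return None
        return 100.0 * self.lloq / self.target_concentration

    @property
    def uloq_pct(self) -> float | None:
        if self.uloq is None or not self.target_concentration:
            return None
        return 100.0 * self.uloq / self.target_concentration


def _crossing(
    c_fail: float, c_pass: float, stat_fail: LevelStats, stat_pass: LevelStats, lam: float
) -> float:
    """Linear interpolation (on concentration) of where the offending
    tolerance bound crosses the acceptance limit between two levels."""
    candidates = []
    if stat_fail.beta_eti_high_pct > lam:
        y0, y1 = stat_fail.beta_eti_high_pct, stat_pass.beta_eti_high_pct
        candidates.append(c_fail + (y0 - lam) / (y0 - y1) * (c_pass - c_fail))
    if stat_fail.beta_eti_low_pct < -lam:
        y0, y1 = stat_fail.beta_eti_low_pct, stat_pass.beta_eti_low_pct
        candidates.append(c_fail + (y0 + lam) / (y0 - y1) * (c_pass - c_fail))
    # if both bounds offend, the method becomes acceptable only once the
    # later (closer to the passing level) crossing has been reached
    return max(candidates) if c_fail < c_pass else min(candidates)


def build_profile(
    stats_list,
    lambda_limit: float,
    beta: float = 0.95,
    model_kind: str | None = None,
    target_concentration: float | None = None,
) -> AccuracyProfile:
    """Assemble an accuracy profile and decide LLOQ/ULOQ.

    A level passes when its tolerance interval lies entirely within
    [-lambda, +lambda].  The LLOQ is the lowest passing concentration when
    the lowest level passes; otherwise it is interpolated (linearly on
    concentration) where the offending bound crosses the limit between the
    highest failing and first passing level from below.  The ULOQ is
    symmetric from the top.  With no passing level, both are undefined.
    """
    levels = tuple(stats_list)
    if len(levels) < 2:
        raise DesignError("an accuracy profile needs at least 2 levels")
    conc = [s.nominal_concentration for s in levels]
    if not all(c1 < c2 for c1, c2 in zip(conc, conc[1:])):
        raise DesignError("levels must be sorted by increasing concentration")
    passing = [s.passes(lambda_limit) for s in levels]
    if target_concentration is None:
        target_concentration = conc[-1] / 1.2

    lloq: float | None = None
    uloq: float | None = None
    if any(passing):
        first = passing.index(True)
        last = len(passing) - 1 - passing[::-1].index(True)
        if first == 0:
            lloq = conc[0]
        else:
            lloq = _crossing(
                conc[first - 1], conc[first], levels[first - 1], levels[first], lambda_limit
            )
        if last == len(levels) - 1:
            uloq = conc[-1]
        else:
            uloq = _crossing(
                conc[last + 1], conc[last], levels[last + 1], levels[last], lambda_limit
            )
    return AccuracyProfile(
        levels=levels,
        lambda_limit_pct=float(lambda_limit),
        beta=beta,
        lloq=lloq,
        uloq=uloq,
        valid=all(passing),
        model_kind=model_kind,
        target_concentration=target_concentration,
    )


def profile_from_table(
    table: MeasurementTable,
    model_kind: str = "ols_linear",
    beta: float | None = None,
    lambda_limit: float | None = None,
    **filters,
) -> AccuracyProfile:
    """Full pipeline: per-series fits -> per-level statistics -> profile."""
    design = table.design
    beta = design.beta if beta is None else beta
    lam = design.lambda_limit if lambda_limit is None else lambda_limit
    fits = fit_all_series(table, model_kind)
    stats_list = [
        level_stats(table, fits, lvl, beta, **filters)
        for lvl in range(1, design.n_levels + 1)
    ]
    return build_profile(
        stats_list,
        lam,
        beta,
        model_kind=fits[0].model_kind,
        target_concentration=design.target_concentration,
    )


# ---------------------------------------------------------------------------
# linearity, LOD, model selection


@dataclass(frozen=True)
class LinearityResult:
    """Regression of back-calculated on introduced concentration, with the
    per-level tolerance bands re-expressed on the concentration scale."""

    slope: float
    intercept: float
    r_squared: float
    levels: tuple[float, ...] = ()
    band_low: tuple[float, ...] = ()       # ug/mL
    band_high: tuple[float, ...] = ()
    within_limits: tuple[bool, ...] = ()


def linearity_profile(
    introduced,
    backcalculated,
    stats_list=None,
    lambda_limit: float | None = None,
) -> LinearityResult:
    """Unweighted regression of back-calculated on introduced concentration.

    When per-level statistics are supplied, the tolerance intervals are
    re-expressed on the concentration scale (C * (1 + bound/100)) and each
    level is checked against the acceptance limits.
    """
    x = np.asarray(introduced, dtype=float)
    y = np.asarray(backcalculated, dtype=float)
    if np.unique(x).size < 2:
        raise FitError("linearity needs at least 2 distinct levels")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = (float(v) for v in res.params)
    bands_lo: list[float] = []
    bands_hi: list[float] = []
    levels: list[float] = []
    ok: list[bool] = []
    if stats_list is not None:
        for s in stats_list:
            c = s.nominal_concentration
            levels.append(c)
            bands_lo.append(c * (1.0 + s.beta_eti_low_pct / 100.0))
            bands_hi.append(c * (1.0 + s.beta_eti_high_pct / 100.0))
            ok.append(s.passes(lambda_limit) if lambda_limit is not None else True)
    return LinearityResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rsquared),
        levels=tuple(levels),
        band_low=tuple(bands_lo),
        band_high=tuple(bands_hi),
        within_limits=tuple(ok),
    )


def lod_from_lloq(lloq: float) -> float:
    """Detection limit from the quantitation limit, LOD = LLOQ / 3.3."""
    if lloq is None or not lloq > 0:
        raise ValueError("LLOQ must be a positive, defined concentration")
    return lloq / 3.3


@dataclass(frozen=True)
class ModelSelection:
    profiles: dict
    ranking: tuple[str, ...]
    chosen: str
    tie: bool
    unavailable: dict


#: tie-break preference: simplest adequate model first
_PREFERENCE = ("ols_linear", "weighted_1overX", "sqrt_linear", "single_point_120")


def select_response_function(
    table: MeasurementTable,
    candidates=MODEL_KINDS,
    lambda_limit: float | None = None,
    beta: float | None = None,
) -> ModelSelection:
    """Build one accuracy profile per candidate response function and rank
    them: all-pass profiles first, then by the smallest maximum absolute
    tolerance bound.  Ties are flagged and broken in favour of the simplest
    model (unweighted linear first)."""
    profiles: dict = {}
    unavailable: dict = {}
    for kind in candidates:
        try:
            profiles[kind] = profile_from_table(
                table, kind, beta=beta, lambda_limit=lambda_limit
            )
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            unavailable[kind] = str(exc)
    if not profiles:
        raise FitError("no candidate response function could be fitted")

    def score(kind: str) -> tuple:
        prof = profiles[kind]
        worst = max(
            max(abs(s.beta_eti_low_pct), abs(s.beta_eti_high_pct)) for s in prof.levels
        )
        # quantize so float jitter cannot defeat the preference tie-break
        return (0 if prof.valid else 1, round(worst, 9))

    ranked = sorted(profiles, key=lambda k: (*score(k), _PREFERENCE.index(k)))
    best = score(ranked[0])
    tie = sum(1 for k in profiles if np.allclose(score(k), best, atol=1e-9)) > 1
    return ModelSelection(
        profiles=profiles,
        ranking=tuple(ranked),
        chosen=ranked[0],
        tie=tie,
        unavailable=unavailable,
    )

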