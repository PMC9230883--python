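"""Synthetic-data generators: hierarchical validation datasets, EMG
chromatograms and two-stage dissolution runs.

The validation generator emulates the study design the package targets — a
balanced 3-series x 5-level x 3-replicate layout at 10/50/100/300/600 ug/mL
(2-120% of a 500 ug/mL target) — with a multiplicative two-component error
model on concentration: for series j and replicate k at level l,

    C_true = C_l * (1 + bias_l/100) * (1 + alpha_jl + eps_jkl),
    alpha_jl ~ N(0, (cv_between_l/100)^2),   eps_jkl ~ N(0, (cv_within_l/100)^2),

and response = slope_j * C_true + intercept, where slope_j is the day's
effective instrument sensitivity.  Calibration standards are generated
bias-free (aqueous truth) with their own, much tighter error model —
aqueous serial dilutions are far more precise than matrix-matched
validation standards — parameterised by ``cal_cv_within_pct`` and a
day-sensitivity effect ``day_effect_cv_pct`` that multiplies the slope of
BOTH roles on a given day (day is the blocking unit, and a sensitivity
drift cancels in back-calculation exactly as on a real instrument).
Default biases and CVs are the reported per-level trueness and precision of
the validated assay (repeatability RSD as the within-series CV;
between-series CV = sqrt(s_R^2 - s_r^2)); the default calibration precision
reproduces the reported day-to-day calibration slope spread (RSD ~0.26%)
and per-day r^2 (>= 0.9997).

All generators are deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy_profile import backcalc_grid, satterthwaite_dof, b_factor_squared
from .datamodel import (
    MeasurementTable,
    ROLE_CALIBRATION,
    ROLE_VALIDATION,
    ValidationDesign,
    study_design,
)
from .dissolution import DissolutionRun
from .chrom_metrics import Chromatogram
from .response_models import fit_all_series

# reported per-level truth of the validated assay (2-120% range)
DEFAULT_BIAS_PCT = (1.1, 3.9, -1.2, -3.0, -4.5)
DEFAULT_CV_WITHIN_PCT = (2.1, 2.7, 1.9, 1.5, 1.4)
_DEFAULT_SR_INTERMEDIATE = (2.6, 3.0, 3.1, 2.4, 2.5)
DEFAULT_CV_BETWEEN_PCT = tuple(
    math.sqrt(sr2**2 - sr1**2)
    for sr1, sr2 in zip(DEFAULT_CV_WITHIN_PCT, _DEFAULT_SR_INTERMEDIATE)
)
#: aqueous calibration slope, detector area units per ug/mL
DEFAULT_SLOPE = 21100.0


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth for a synthetic validation experiment."""

    design: ValidationDesign
    bias_pct: tuple[float, ...]
    cv_within_pct: tuple[float, ...]
    cv_between_pct: tuple[float, ...]
    slope: float = DEFAULT_SLOPE
    intercept: float = 0.0
    cal_cv_within_pct: float = 0.3   # aqueous serial-dilution repeatability
    day_effect_cv_pct: float = 0.2   # day-to-day instrument sensitivity
    seed: int = 0
    error_scale: str = "relative"   # or "absolute" (CVs read as ug/mL SDs)
    matrix: str = "FaSSGF:milk"
    fat_content: float = 3.6
    reagent: str = "TFA10"

    def __post_init__(self) -> None:
        m = self.design.n_levels
        for name in ("bias_pct", "cv_within_pct", "cv_between_pct"):
            vals = getattr(self, name)
            if len(vals) != m:
                raise ValueError(f"{name} must have one value per level ({m})")
        if any(v < 0 for v in self.cv_within_pct + self.cv_between_pct):
            raise ValueError("CVs must be non-negative")
        if self.cal_cv_within_pct < 0 or self.day_effect_cv_pct < 0:
            raise ValueError("calibration CVs must be non-negative")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.error_scale not in ("relative", "absolute"):
            raise ValueError("error_scale must be 'relative' or 'absolute'")


def study_truth_spec(seed: int = 0, beta: float = 0.95, lambda_limit: float = 15.0) -> TruthSpec:
    """Truth spec parameterised by the validated assay's reported per-level
    biases and precision components."""
    return TruthSpec(
        design=study_design(beta=beta, lambda_limit=lambda_limit),
        bias_pct=DEFAULT_BIAS_PCT,
        cv_within_pct=DEFAULT_CV_WITHIN_PCT,
        cv_between_pct=DEFAULT_CV_BETWEEN_PCT,
        seed=seed,
    )


def _noise_factor(truth: TruthSpec, nominal: float, alpha, eps):
    if truth.error_scale == "relative":
        return 1.0 + alpha + eps
    return 1.0 + (alpha + eps) / nominal


def simulate_validation_dataset(
    truth: TruthSpec, seed: int | None = None
) -> MeasurementTable:
    """One complete calibration + validation dataset as a MeasurementTable.

    Each day j gets a sensitivity factor (1 + d_j), d_j ~
    N(0, day_effect_cv^2), multiplying the response slope of both roles;
    it cancels when validation standards are back-calculated through their
    own day's fit.  Calibration concentrations carry only the tight aqueous
    repeatability ``cal_cv_within_pct``; validation concentrations carry the
    per-level bias, between-series effect and within-series error.
    """
    design = truth.design
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p, n, m = design.n_series, design.n_replicates, design.n_levels
    rows = []
    scale = 0.01 if truth.error_scale == "relative" else 1.0
    for j in range(p):
        sid = f"day{j + 1}"
        day_slope = truth.slope * (1.0 + rng.normal(0.0, truth.day_effect_cv_pct / 100.0))
        for lvl in range(m):
            c = design.nominal_concentrations[lvl]
            cv_b = truth.cv_between_pct[lvl] * scale
            cv_w = truth.cv_within_pct[lvl] * scale
            cv_cal = truth.cal_cv_within_pct * (0.01 if truth.error_scale == "relative" else 1.0)
            alpha = rng.normal(0.0, cv_b) if cv_b > 0 else 0.0
            for role, bias, a, cv in (
                (ROLE_CALIBRATION, 0.0, 0.0, cv_cal),
                (ROLE_VALIDATION, truth.bias_pct[lvl], alpha, cv_w),
            ):
                eps = rng.normal(0.0, cv, size=n) if cv > 0 else np.zeros(n)
                c_true = c * (1.0 + bias / 100.0) * _noise_factor(truth, c, a, eps)
                resp = day_slope * c_true + truth.intercept
                for k in range(n):
                    rows.append(
                        {
                            "role": role,
                            "series_id": sid,
                            "level_index": lvl + 1,
                            "replicate_index": k + 1,
                            "nominal_concentration": c,
                            "response": resp[k],
                            "matrix": "aqueous" if role == ROLE_CALIBRATION else truth.matrix,
                            "fat_content": 0.0 if role == ROLE_CALIBRATION else truth.fat_content,
                            "reagent": "" if role == ROLE_CALIBRATION else truth.reagent,
                        }
                    )
    return MeasurementTable.from_frame(pd.DataFrame(rows), design=design)


# ---------------------------------------------------------------------------
# coverage of the tolerance intervals (defining property)


def _eti_bounds_many(x: np.ndarray, nominal: float, beta: float):
    """Vectorised per-dataset tolerance bounds for datasets of shape
    (n_datasets, p, n), on the relative-error (%) scale."""
    D, p, n = x.shape
    s2w = np.mean(np.var(x, axis=2, ddof=1), axis=1)
    msb = n * np.var(np.mean(x, axis=2), axis=1, ddof=1)
    s2b = np.maximum(0.0, (msb - s2w) / n)
    mean = x.mean(axis=(1, 2))
    bias = 100.0 * (mean - nominal) / nominal
    rsd_ip = 100.0 * np.sqrt(s2w + s2b) / mean
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(s2w > 0, s2b / s2w, np.inf)
    nu = np.array([satterthwaite_dof(float(r), p, n) for r in R])
    b2 = np.array([b_factor_squared(float(r), n) for r in R])
    q = stats.t.ppf((1.0 + beta) / 2.0, nu)
    half = q * np.sqrt(1.0 + 1.0 / (p * n * b2)) * rsd_ip
    return bias - half, bias + half


@dataclass(frozen=True)
class CoverageResult:
    concentrations: tuple[float, ...]
    coverage: tuple[float, ...]      # per-level mean coverage, fraction
    mc_se: tuple[float, ...]
    overall_coverage: float
    overall_se: float
    n_datasets: int
    n_future: int


def coverage_experiment(
    truth: TruthSpec,
    n_datasets: int = 500,
    n_future: int = 200,
    seed: int | None = None,
) -> CoverageResult:
    """Empirical expectation property of the tolerance intervals.

    For each simulated dataset the interval is estimated from p x n
    hierarchical draws of the level's measurement model, then ``n_future``
    fresh single measurements (each with its own series effect) are drawn
    from the same model and the fraction falling inside the interval is
    recorded.  The mean of that fraction over datasets should equal beta.
    """
    if n_datasets < 100:
        raise ValueError("need at least 100 datasets for a stable coverage estimate")
    design = truth.design
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p, n = design.n_series, design.n_replicates
    beta = design.beta
    cov_means, cov_ses = [], []
    for lvl in range(design.n_levels):
        c = design.nominal_concentrations[lvl]
        b = truth.bias_pct[lvl] / 100.0
        sw = truth.cv_within_pct[lvl] / 100.0
        sb = truth.cv_between_pct[lvl] / 100.0
        alpha = rng.normal(0.0, sb, size=(n_datasets, p, 1))
        eps = rng.normal(0.0, sw, size=(n_datasets, p, n))
        x = c * (1.0 + b) * (1.0 + alpha + eps)
        low, high = _eti_bounds_many(x, c, beta)
        a_new = rng.normal(0.0, sb, size=(n_datasets, n_future))
        e_new = rng.normal(0.0, sw, size=(n_datasets, n_future))
        err_new = 100.0 * ((1.0 + b) * (1.0 + a_new + e_new) - 1.0)
        inside = (err_new >= low[:, None]) & (err_new <= high[:, None])
        per_dataset = inside.mean(axis=1)
        cov_means.append(float(per_dataset.mean()))
        cov_ses.append(float(per_dataset.std(ddof=1) / math.sqrt(n_datasets)))
    overall = float(np.mean(cov_means))
    overall_se = float(np.sqrt(np.sum(np.square(cov_ses))) / len(cov_means))
    return CoverageResult(
        concentrations=design.nominal_concentrations,
        coverage=tuple(cov_means),
        mc_se=tuple(cov_ses),
        overall_coverage=overall,
        overall_se=overall_se,
        n_datasets=n_datasets,
        n_future=n_future,
    )


# ---------------------------------------------------------------------------
# parameter recovery through the full pipeline


@dataclass(frozen=True)
class RecoveryResult:
    concentrations: tuple[float, ...]
    mean_bias_pct: tuple[float, ...]          # mean estimated relative bias
    pooled_rsd_repeatability_pct: tuple[float, ...]
    mean_backcalc: tuple[float, ...]
    n_datasets: int


def recovery_experiment(
    truth: TruthSpec,
    n_datasets: int = 1000,
    seed: int | None = None,
    model_kind: str = "ols_linear",
) -> RecoveryResult:
    """Estimator consistency through the full pipeline.

    Each replicate dataset is simulated, fitted per series, back-calculated,
    and reduced to per-level bias and within-series variance; the function
    returns the across-dataset mean bias and the pooled repeatability RSD
    (sqrt of the mean within-series variance over the mean back-calculated
    concentration) per level.
    """
    design = truth.design
    m = design.n_levels
    seeds = np.random.SeedSequence(truth.seed if seed is None else seed)
    child = seeds.generate_state(n_datasets, dtype=np.uint32)
    bias_acc = np.zeros((n_datasets, m))
    s2w_acc = np.zeros((n_datasets, m))
    mean_acc = np.zeros((n_datasets, m))
    for d in range(n_datasets):
        table = simulate_validation_dataset(truth, seed=int(child[d]))
        fits = fit_all_series(table, model_kind)
        for lvl in range(1, m + 1):
            grid = backcalc_grid(table, fits, lvl)
            nominal = design.level_concentration(lvl)
            mean = grid.mean()
            bias_acc[d, lvl - 1] = 100.0 * (mean - nominal) / nominal
            s2w_acc[d, lvl - 1] = np.mean(np.var(grid, axis=1, ddof=1))
            mean_acc[d, lvl - 1] = mean
    mean_bc = mean_acc.mean(axis=0)
    pooled_rsd = 100.0 * np.sqrt(s2w_acc.mean(axis=0)) / mean_bc
    return RecoveryResult(
        concentrations=design.nominal_concentrations,
        mean_bias_pct=tuple(float(v) for v in bias_acc.mean(axis=0)),
        pooled_rsd_repeatability_pct=tuple(float(v) for v in pooled_rsd),
        mean_backcalc=tuple(float(v) for v in mean_bc),
        n_datasets=n_datasets,
    )


# ---------------------------------------------------------------------------
# chromatograms


def emg_shape(t, t_r: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-maximum exponentially-modified-Gaussian peak shape.

    ``t_r`` is the centre of the underlying Gaussian; with ``tau == 0`` the
    shape is a pure Gaussian.  The maximum is normalised on a dense internal
    grid so the amplitude is independent of the caller's sampling.
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau < 1e-9 * sigma or tau == 0.0:
        return np.exp(-0.5 * ((t - t_r) / sigma) ** 2)
    K = tau / sigma
    dense = np.linspace(t_r - 8 * sigma, t_r + 8 * sigma + 10 * tau, 20001)
    peak_max = stats.exponnorm.pdf(dense, K, loc=t_r, scale=sigma).max()
    return stats.exponnorm.pdf(t, K, loc=t_r, scale=sigma) / peak_max


def simulate_chromatogram(
    peaks,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    duration: float = 12.0,
    sampling_rate: float = 300.0,
    seed: int = 0,
) -> Chromatogram:
    """Sum of EMG peaks over a drifting baseline with white noise.

    Parameters
    ----------
    peaks : list of (t_r, sigma, tau, height)
        Peak centre (min), Gaussian width (min), exponential tail constant
        (min; 0 for a symmetric peak) and apex amplitude (detector units).
    baseline : (offset, drift)
        Intensity offset and linear drift per minute.
    sampling_rate : float
        Points per minute.
    """
    rng = np.random.default_rng(seed)
    n_pts = int(round(duration * sampling_rate)) + 1
    t = np.linspace(0.0, duration, n_pts)
    y = baseline[0] + baseline[1] * t
    for t_r, sigma, tau, height in peaks:
        if not 0.0 <= t_r <= duration:
            raise ValueError(f"peak at {t_r} min outside the {duration}-min trace")
        y = y + height * emg_shape(t, t_r, sigma, tau)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return Chromatogram(time=t, intensity=y, metadata={"seed": seed})


# ---------------------------------------------------------------------------
# dissolution


def release_fraction(
    t,
    k_stage1: float,
    k_stage2: float | None = None,
    change_time: float | None = 60.0,
) -> np.ndarray:
    """True cumulative dissolved fraction of a first-order two-stage release.

    Within each stage the release is first-order towards complete
    dissolution, continuous at the medium change.
    """
    t = np.asarray(t, dtype=float)
    if k_stage1 < 0 or (k_stage2 is not None and k_stage2 < 0):
        raise ValueError("release rate constants must be non-negative")
    if change_time is None or k_stage2 is None:
        return 1.0 - np.exp(-k_stage1 * t)
    f_change = 1.0 - math.exp(-k_stage1 * change_time)
    stage2 = 1.0 - (1.0 - f_change) * np.exp(-k_stage2 * np.maximum(t - change_time, 0.0))
    return np.where(t <= change_time, 1.0 - np.exp(-k_stage1 * t), stage2)


def simulate_dissolution(
    k_stage1: float,
    k_stage2: float | None = None,
    dose_mg: float = 50.0,
    stage1_volume_ml: float = 100.0,
    stage2_volume_ml: float = 200.0,
    schedule=(0.0, 5.0, 15.0, 30.0, 60.0, 75.0, 90.0, 120.0, 180.0, 240.0),
    sample_volume_ml: float = 2.0,
    change_time: float | None = 60.0,
    sample_before_change: bool = True,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DissolutionRun:
    """Simulate sampled concentrations of a two-stage dissolution test.

    The in-vessel mass balance tracks every withdrawal (the aliquot removes
    analyte; the replacement medium carries none) and the medium addition at
    the stage change (mass conserved, concentration diluted).  Sampled
    concentrations get multiplicative Gaussian noise of CV ``noise_cv`` (%).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule, dtype=float)
    dose_ug = dose_mg * 1000.0
    frac = release_fraction(t, k_stage1, k_stage2, change_time)
    removed = 0.0  # analyte mass carried away by earlier aliquots, ug
    c_true = np.zeros_like(t)
    for i, ti in enumerate(t):
        if change_time is None or ti < change_time or (
            ti == change_time and sample_before_change
        ):
            vol = stage1_volume_ml
        else:
            vol = stage2_volume_ml
        in_vessel = dose_ug * frac[i] - removed
        c_true[i] = in_vessel / vol
        removed += c_true[i] * sample_volume_ml
    noise = (
        rng.normal(0.0, noise_cv / 100.0, size=t.shape) if noise_cv > 0 else 0.0
    )
    sampled = c_true * (1.0 + noise)
    return DissolutionRun(
        timepoints=tuple(t),
        sampled_concentrations=tuple(sampled),
        dose_mg=dose_mg,
        sample_volume_ml=sample_volume_ml,
        stage1_volume_ml=stage1_volume_ml,
        stage2_volume_ml=stage2_volume_ml,
        stage_change_time=change_time,
        sample_before_change=sample_before_change,
    )
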