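"""Variance components, tolerance intervals and profile decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apval import (
    beta_eti,
    build_profile,
    level_stats,
    level_stats_from_grid,
    linearity_profile,
    lod_from_lloq,
    fit_all_series,
    profile_from_table,
    satterthwaite_dof,
    select_response_function,
    simulate_validation_dataset,
    variance_components,
)
from apval.accuracy_profile import LevelStats
from apval.errors import DesignError


# ---------------------------------------------------------------------------
# variance components

TOY = [[9.0, 10.0, 11.0], [10.0, 11.0, 12.0], [11.0, 12.0, 13.0]]


def test_variance_components_hand_anova():
    s2w, s2b = variance_components(TOY)
    assert s2w == pytest.approx(1.0)
    assert s2b == pytest.approx(2.0 / 3.0)


def test_variance_components_degenerate_cases():
    assert variance_components(np.full((3, 3), 7.0)) == (0.0, 0.0)
    # equal series means, within spread > 0 -> negative moment clamps to 0
    grid = [[9.0, 11.0], [8.0, 12.0], [10.0, 10.0]]
    s2w, s2b = variance_components(grid)
    assert s2w > 0
    assert s2b == 0.0


def test_variance_components_rejects_bad_grids():
    with pytest.raises(DesignError):
        variance_components([[1.0, 2.0]])  # p = 1
    with pytest.raises(DesignError):
        variance_components([[1.0], [2.0]])  # n = 1
    with pytest.raises(DesignError):
        variance_components(TOY, p=4)


@settings(derandomize=True, deadline=None, max_examples=80)
@given(
    p=st.integers(2, 5),
    n=st.integers(2, 6),
    seed=st.integers(0, 10_000),
)
def test_variance_components_match_bruteforce_sums_of_squares(p, n, seed):
    """Oracle: explicit ANOVA sums of squares computed from first principles."""
    rng = np.random.default_rng(seed)
    x = rng.normal(10.0, 2.0, size=(p, n)) + rng.normal(0, 1.5, size=(p, 1))
    grand = x.mean()
    ss_within = sum((x[i, j] - x[i].mean()) ** 2 for i in range(p) for j in range(n))
    ss_between = n * sum((x[i].mean() - grand) ** 2 for i in range(p))
    ms_w = ss_within / (p * (n - 1))
    ms_b = ss_between / (p - 1)
    s2w, s2b = variance_components(x)
    assert s2w == pytest.approx(ms_w, rel=1e-10)
    assert s2b == pytest.approx(max(0.0, (ms_b - ms_w) / n), rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# tolerance interval arithmetic


def test_satterthwaite_limits():
    # R -> inf: dof tends to p-1
    assert satterthwaite_dof(math.inf, 3, 3) == pytest.approx(2.0)
    assert satterthwaite_dof(1e9, 3, 3) == pytest.approx(2.0, rel=1e-6)
    # R = 0: finite and positive
    nu0 = satterthwaite_dof(0.0, 3, 3)
    assert nu0 == pytest.approx(1.0 / ((1.0 / 3.0) ** 2 / 2.0 + (2.0 / 3.0) / 9.0))
    assert nu0 > 0


def test_beta_eti_degenerate_width():
    assert beta_eti(2.5, 0.0, 0.0, 3, 3) == (2.5, 2.5)


def test_beta_eti_halfwidth_closed_form_at_r0():
    """At R=0 the half-width is t(nu0; 0.975) * sqrt(1 + 1/9) * s_R."""
    nu0 = satterthwaite_dof(0.0, 3, 3)
    expected = stats.t.ppf(0.975, nu0) * math.sqrt(1.0 + 1.0 / 9.0)
    low, high = beta_eti(0.0, 1.0, 0.0, 3, 3, 0.95)
    assert high == pytest.approx(expected)
    assert low == pytest.approx(-expected)


def test_beta_eti_monotone_in_rsd():
    widths = [
        beta_eti(1.0, s, 0.5, 3, 3)[1] - beta_eti(1.0, s, 0.5, 3, 3)[0]
        for s in (0.5, 1.0, 2.0, 4.0)
    ]
    assert all(w1 < w2 for w1, w2 in zip(widths, widths[1:]))


def test_beta_eti_expectation_property_full_procedure():
    """Monte-Carlo oracle: estimate the interval from p x n draws, then check
    the fraction of fresh observations inside averages to ~beta."""
    rng = np.random.default_rng(5)
    p = n = 3
    n_datasets, n_future = 400, 250
    covered = np.empty(n_datasets)
    for d in range(n_datasets):
        x = 100.0 + rng.normal(0, 1.5, size=(p, 1)) + rng.normal(0, 2.0, size=(p, n))
        s2w, s2b = variance_components(x)
        mean = x.mean()
        bias = mean - 100.0
        rsd = math.sqrt(s2w + s2b)
        R = s2b / s2w if s2w > 0 else math.inf
        low, high = beta_eti(bias, rsd, R, p, n, 0.95)
        fresh = 100.0 + rng.normal(0, 1.5, n_future) + rng.normal(0, 2.0, n_future)
        err = fresh - 100.0
        covered[d] = np.mean((err >= low) & (err <= high))
    se = covered.std(ddof=1) / math.sqrt(n_datasets)
    assert covered.mean() == pytest.approx(0.95, abs=max(3 * se, 0.01))


# ---------------------------------------------------------------------------
# level statistics


def test_level_stats_toy_grid():
    s = level_stats_from_grid(TOY, nominal=10.0, level_index=1)
    assert s.relative_bias_pct == pytest.approx(10.0)
    assert s.rsd_intermediate_pct == pytest.approx(100.0 * math.sqrt(5.0 / 3.0) / 11.0)
    assert s.rsd_repeatability_pct == pytest.approx(100.0 / 11.0)
    assert s.rsd_intermediate_pct >= s.rsd_repeatability_pct
    assert s.beta_eti_low_pct <= s.relative_bias_pct <= s.beta_eti_high_pct
    assert 0 < s.b_factor <= 1


def test_level_stats_noiseless_pipeline(noiseless_table):
    fits = fit_all_series(noiseless_table, "ols_linear")
    s = level_stats(noiseless_table, fits, 1)
    assert s.relative_bias_pct == pytest.approx(0.0, abs=1e-9)
    assert s.rsd_intermediate_pct == pytest.approx(0.0, abs=1e-9)
    assert (s.beta_eti_low_pct, s.beta_eti_high_pct) == pytest.approx((0.0, 0.0), abs=1e-9)


def test_level_stats_pure_bias(noiseless_truth):
    from dataclasses import replace

    truth = replace(noiseless_truth, bias_pct=(10.0,) * 5)
    table = simulate_validation_dataset(truth)
    fits = fit_all_series(table, "ols_linear")
    s = level_stats(table, fits, 3)
    assert s.relative_bias_pct == pytest.approx(10.0, abs=1e-9)
    assert s.beta_eti_low_pct == pytest.approx(10.0, abs=1e-9)
    assert s.beta_eti_high_pct == pytest.approx(10.0, abs=1e-9)


# ---------------------------------------------------------------------------
# profile assembly and limits of quantitation


def _stats(conc, low, high, idx=0):
    return LevelStats(
        level_index=idx,
        nominal_concentration=conc,
        mean_backcalc=conc,
        relative_bias_pct=(low + high) / 2,
        sigma2_within=1.0,
        sigma2_between=0.0,
        rsd_repeatability_pct=1.0,
        rsd_intermediate_pct=1.0,
        variance_ratio=0.0,
        b_factor=1.0,
        dof=5.0,
        t_quantile=2.5,
        beta_eti_low_pct=low,
        beta_eti_high_pct=high,
    )


def test_profile_all_pass_reports_design_extremes():
    levels = [_stats(c, -8.0, 8.0, i) for i, c in enumerate((10, 50, 100, 300, 600))]
    prof = build_profile(levels, lambda_limit=15.0)
    assert prof.valid
    assert prof.lloq == 10.0
    assert prof.uloq == 600.0
    assert prof.lloq_pct == pytest.approx(2.0)
    assert prof.uloq_pct == pytest.approx(120.0)


def test_profile_lloq_interpolated_between_fail_and_pass():
    levels = [
        _stats(10.0, -5.0, 20.0, 1),   # fails: upper bound 20 > 15
        _stats(50.0, -5.0, 10.0, 2),   # passes
        _stats(100.0, -5.0, 5.0, 3),
    ]
    prof = build_profile(levels, lambda_limit=15.0)
    assert not prof.valid
    # crossing of the upper bound with +15 between 10 (20%) and 50 (10%)
    expected = 10.0 + (20.0 - 15.0) / (20.0 - 10.0) * (50.0 - 10.0)
    assert prof.lloq == pytest.approx(expected)
    assert 10.0 < prof.lloq < 50.0
    assert prof.uloq == 100.0


def test_profile_uloq_interpolated_from_top():
    levels = [
        _stats(10.0, -5.0, 5.0, 1),
        _stats(100.0, -5.0, 5.0, 2),
        _stats(600.0, -25.0, 5.0, 3),  # fails at the top: lower bound -25
    ]
    prof = build_profile(levels, lambda_limit=15.0)
    expected = 600.0 + (-25.0 + 15.0) / (-25.0 - (-5.0)) * (100.0 - 600.0)
    assert prof.uloq == pytest.approx(expected)
    assert 100.0 < prof.uloq < 600.0


def test_profile_no_passing_level():
    levels = [_stats(10.0, -30.0, 30.0, 1), _stats(600.0, -30.0, 30.0, 2)]
    prof = build_profile(levels, lambda_limit=15.0)
    assert not prof.valid
    assert prof.lloq is None and prof.uloq is None


def test_lod_from_lloq():
    assert lod_from_lloq(10.0) == pytest.approx(10.0 / 3.3)
    assert lod_from_lloq(3.3) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        lod_from_lloq(0.0)
    with pytest.raises(ValueError):
        lod_from_lloq(None)


# ---------------------------------------------------------------------------
# linearity


def test_linearity_identity_and_constant_bias():
    c = np.repeat([10.0, 50.0, 100.0, 300.0, 600.0], 3)
    res = linearity_profile(c, c)
    assert res.slope == pytest.approx(1.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-9)
    assert res.r_squared == pytest.approx(1.0)
    res = linearity_profile(c, 1.10 * c)
    assert res.slope == pytest.approx(1.10)
    assert res.intercept == pytest.approx(0.0, abs=1e-9)


def test_linearity_slope_near_unity_under_study_noise(truth):
    table = simulate_validation_dataset(truth, seed=31)
    fits = fit_all_series(table, "ols_linear")
    from apval.accuracy_profile import backcalc_grid

    xs, ys = [], []
    for lvl in range(1, 6):
        grid = backcalc_grid(table, fits, lvl)
        c = table.design.level_concentration(lvl)
        xs.extend([c] * grid.size)
        ys.extend(grid.ravel())
    res = linearity_profile(xs, ys)
    assert 0.95 <= res.slope <= 1.05
    assert res.r_squared > 0.99


# ---------------------------------------------------------------------------
# response-function selection


def test_selection_noiseless_tie_prefers_unweighted_linear(noiseless_table):
    sel = select_response_function(noiseless_table)
    assert sel.chosen == "ols_linear"
    assert sel.tie
    assert all(p.valid for p in sel.profiles.values())


def test_selection_isolates_failing_candidate(noiseless_table):
    frame = noiseless_table.frame.copy()
    # a negative response poisons the sqrt model only
    idx = frame[(frame["role"] == "calibration")].index[0]
    frame.loc[idx, "response"] = -1.0
    from apval import MeasurementTable

    table = MeasurementTable(frame=frame, design=noiseless_table.design)
    sel = select_response_function(table)
    assert "sqrt_linear" in sel.unavailable
    assert "ols_linear" in sel.profiles


def test_full_pipeline_profile_reports_tablewide_stats(table):
    prof = profile_from_table(table, "ols_linear")
    assert len(prof.levels) == 5
    for s in prof.levels:
        assert s.rsd_intermediate_pct >= s.rsd_repeatability_pct
        assert s.beta_eti_low_pct <= s.relative_bias_pct <= s.beta_eti_high_pct
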