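"""Peak metrics: plates, tailing, S/N and the system-suitability gates."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import exponnorm

from apval import (
    Chromatogram,
    detect_peak,
    lod_from_sn,
    peak_metrics,
    signal_to_noise,
    simulate_chromatogram,
    sst_evaluate,
    tailing_factor,
    theoretical_plates,
    width_at_fraction,
)
from apval.chrom_metrics import PeakRegion, SSTCriteria
from apval.errors import BoundaryError, DesignError, PeakError

SIGMA = 0.05
TR = 5.9
FWHM = 2.0 * SIGMA * math.sqrt(2.0 * math.log(2.0))


@pytest.fixture
def gaussian_chrom():
    return simulate_chromatogram(
        peaks=[(TR, SIGMA, 0.0, 30.0)], sampling_rate=2000.0, seed=0
    )


def _peak(chrom, window=(5.4, 6.4)):
    return detect_peak(chrom, window)


def test_gaussian_apex_located(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    assert gaussian_chrom.time[peak.apex_index] == pytest.approx(TR, abs=1e-3)


def test_flat_trace_has_no_peak():
    t = np.linspace(0, 12, 1000)
    with pytest.raises(PeakError):
        detect_peak(Chromatogram(t, np.full_like(t, 3.0)), (5.4, 6.4))


def test_two_peaks_warns_and_uses_taller():
    chrom = simulate_chromatogram(
        peaks=[(5.7, SIGMA, 0.0, 30.0), (6.1, SIGMA, 0.0, 15.0)],
        sampling_rate=2000.0,
    )
    with pytest.warns(UserWarning, match="multiple peaks"):
        peak = detect_peak(chrom, (5.4, 6.4))
    assert chrom.time[peak.apex_index] == pytest.approx(5.7, abs=1e-3)


def test_gaussian_fwhm_closed_form(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    w, front, back = width_at_fraction(gaussian_chrom, peak, 0.5)
    assert w == pytest.approx(FWHM, rel=2e-3)
    assert front == pytest.approx(back, abs=2e-3)


def test_width_fraction_not_crossed_is_boundary_error():
    t = np.linspace(0.0, 1.0, 101)
    y = 5.0 + t  # apex at the trace edge: right crossing cannot exist
    peak = PeakRegion(100, 0, 100, (0.0, 1.0), 0.0, 0.0, 0.0)
    with pytest.raises(BoundaryError):
        width_at_fraction(Chromatogram(t, y), peak, 0.5)


def test_theoretical_plates_closed_form_and_scaling(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    w, _, _ = width_at_fraction(gaussian_chrom, peak, 0.5)
    n = theoretical_plates(TR, w)
    # 5.54 (t_R/FWHM)^2 ~ (t_R/sigma)^2 to 0.1%
    assert n == pytest.approx((TR / SIGMA) ** 2, rel=5e-3)
    assert n > 13000
    assert theoretical_plates(1.0, 1.0) == pytest.approx(5.54)
    assert theoretical_plates(2 * TR, w) == pytest.approx(4 * n)
    with pytest.raises(ValueError):
        theoretical_plates(-1.0, 0.1)


def test_gaussian_tailing_is_unity(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    assert tailing_factor(gaussian_chrom, peak) == pytest.approx(1.0, abs=0.005)


def _emg_tf_oracle(sigma, tau, tr=TR):
    """Independent high-resolution oracle: 5%-width tailing of the continuous
    EMG density, with crossings found by root bracketing."""
    k = tau / sigma
    f = lambda t: exponnorm.pdf(t, k, loc=tr, scale=sigma)
    grid = np.linspace(tr - 6 * sigma, tr + 6 * sigma + 10 * tau, 10_000)
    vals = f(grid)
    i = int(np.argmax(vals))
    apex_t, apex_v = grid[i], vals[i]
    target = 0.05 * apex_v
    left = brentq(lambda t: f(t) - target, grid[0], apex_t)
    right = brentq(lambda t: f(t) - target, apex_t, grid[-1])
    return (right - left) / (2.0 * (apex_t - left))


@pytest.mark.parametrize("tau", [0.05, 0.10])
def test_emg_tailing_matches_numeric_oracle(tau):
    chrom = simulate_chromatogram(
        peaks=[(TR, SIGMA, tau, 30.0)], sampling_rate=2000.0
    )
    peak = detect_peak(chrom, (5.4, 7.0))
    tf = tailing_factor(chrom, peak)
    assert tf > 1.0
    assert tf == pytest.approx(_emg_tf_oracle(SIGMA, tau), rel=0.01)


def test_fronting_peak_by_reflection():
    chrom = simulate_chromatogram(peaks=[(TR, SIGMA, 0.1, 30.0)], sampling_rate=2000.0)
    mirrored = Chromatogram(chrom.time, chrom.intensity[::-1].copy())
    peak = detect_peak(mirrored, (12.0 - 7.0, 12.0 - 5.4))
    assert tailing_factor(mirrored, peak) < 1.0


def test_emg_tailing_monotone_in_tau():
    tfs = []
    for tau in (0.02, 0.05, 0.10, 0.15):
        chrom = simulate_chromatogram(peaks=[(TR, SIGMA, tau, 30.0)], sampling_rate=2000.0)
        peak = detect_peak(chrom, (5.4, 7.5))
        tfs.append(tailing_factor(chrom, peak))
    assert all(a < b for a, b in zip(tfs, tfs[1:]))


def test_tailing_invariant_under_scaling_and_translation(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    tf = tailing_factor(gaussian_chrom, peak)
    scaled = Chromatogram(gaussian_chrom.time, 17.0 * gaussian_chrom.intensity)
    assert tailing_factor(scaled, _peak(scaled)) == pytest.approx(tf, rel=1e-9)
    shifted = Chromatogram(gaussian_chrom.time + 2.0, gaussian_chrom.intensity)
    speak = detect_peak(shifted, (7.4, 8.4))
    assert tailing_factor(shifted, speak) == pytest.approx(tf, rel=1e-9)
    w0 = width_at_fraction(gaussian_chrom, peak, 0.5)[0]
    assert width_at_fraction(shifted, speak, 0.5)[0] == pytest.approx(w0, rel=1e-9)


def test_signal_to_noise_by_definition(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    # zero-noise trace -> infinite S/N
    assert signal_to_noise(gaussian_chrom, peak, (8.0, 10.0)) == math.inf
    with pytest.raises(DesignError):
        signal_to_noise(gaussian_chrom, peak, (5.8, 6.0))  # overlaps peak


def test_signal_to_noise_white_noise_expectation():
    """Over seeds, S/N approaches 2H / (expected peak-to-peak ~ 6.6 sigma)."""
    h, sigma_n = 30.0, 0.5
    snrs = []
    for seed in range(8):
        chrom = simulate_chromatogram(
            peaks=[(TR, SIGMA, 0.0, h)], noise_sd=sigma_n, sampling_rate=300.0, seed=seed
        )
        peak = detect_peak(chrom, (5.4, 6.4))
        snrs.append(signal_to_noise(chrom, peak, (8.0, 10.0)))
    expected = 2.0 * h / (6.6 * sigma_n)
    assert np.mean(snrs) == pytest.approx(expected, rel=0.20)


def test_lod_from_sn():
    assert lod_from_sn(300.0, 4.0, target_sn=3.0) == pytest.approx(0.02)
    assert lod_from_sn(300.0, 8.0, target_sn=3.0) == pytest.approx(0.04)
    assert lod_from_sn(300.0, 4.0, target_sn=0.0) == 0.0
    with pytest.raises(ValueError):
        lod_from_sn(-1.0, 4.0)


def test_sst_gates():
    ident = [(5.9, 1000.0)] * 6
    report = sst_evaluate(ident, plates=13_000.0, tailing=1.1)
    assert report.overall_pass
    assert report.rsd_area_pct == 0.0
    # area RSD above 2% fails that gate
    areas = [(5.9, a) for a in (1000, 1050, 950, 1030, 970, 1060)]
    report = sst_evaluate(areas, plates=13_000.0, tailing=1.1)
    assert not report.area_rsd_ok and not report.overall_pass
    # low efficiency fails
    report = sst_evaluate(ident, plates=4000.0, tailing=1.1)
    assert not report.plates_ok
    with pytest.raises(DesignError):
        sst_evaluate([(5.9, 1000.0)], plates=13000.0, tailing=1.0)


def test_peak_metrics_bundle(gaussian_chrom):
    peak = _peak(gaussian_chrom)
    m = peak_metrics(gaussian_chrom, peak, noise_window=(8.0, 10.0))
    assert m.retention_time == pytest.approx(TR, abs=1e-3)
    assert m.height == pytest.approx(30.0, rel=1e-3)
    # Gaussian area = h * sigma * sqrt(2 pi), truncated at the 3-noise bounds
    assert m.area == pytest.approx(30.0 * SIGMA * math.sqrt(2 * math.pi), rel=0.02)
    assert m.plates > 13_000
    assert m.snr == math.inf
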