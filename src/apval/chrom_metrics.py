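"""Chromatographic peak metrics and the system-suitability test.

Conventions (compendial):

* theoretical plates by the half-height formula N = 5.54 (t_R / W_0.5)^2;
* tailing factor at 5% of peak height, T_f = W_0.05 / (2 f), with f the
  front half-width;
* signal-to-noise by the peak-to-peak convention S/N = 2H/h, where H is the
  baseline-corrected peak height and h the peak-to-peak noise amplitude in
  an analyte-free window (an RMS-based alternative is available).

The baseline inside the peak window is the straight line through the
window's endpoints; no automatic baseline modelling is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundaryError, DesignError, PeakError

MIN_POINTS = 50


@dataclass
class Chromatogram:
    """A time-intensity trace.  Time in minutes, strictly increasing."""

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D and equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")


@dataclass(frozen=True)
class PeakRegion:
    """A detected peak: apex plus baseline-return bounds inside the window."""

    apex_index: int
    left_index: int
    right_index: int
    window: tuple[float, float]
    baseline_slope: float
    baseline_intercept: float
    noise_sd: float

    def baseline(self, t):
        return self.baseline_slope * np.asarray(t, dtype=float) + self.baseline_intercept


@dataclass(frozen=True)
class PeakMetrics:
    retention_time: float
    area: float
    height: float
    plates: float
    tailing: float
    snr: float | None = None


def _corrected(chrom: Chromatogram, peak: PeakRegion) -> np.ndarray:
    return chrom.intensity - peak.baseline(chrom.time)


def detect_peak(chrom: Chromatogram, window: tuple[float, float]) -> PeakRegion:
    """Locate the analyte peak inside a time window.

    The baseline is the line through the window endpoints; the apex is the
    maximum of the corrected signal.  Bounds are where the corrected signal
    first returns below 3x the noise level, estimated robustly (MAD) from
    the outer tenth of the window on each side.  With two local maxima the
    taller is used and a warning emitted.
    """
    t, y = chrom.time, chrom.intensity
    if len(t) < MIN_POINTS:
        raise PeakError(f"need at least {MIN_POINTS} points, got {len(t)}")
    lo, hi = window
    idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if idx.size < 5:
        raise PeakError("window contains too few samples")
    i0, i1 = idx[0], idx[-1]
    slope = (y[i1] - y[i0]) / (t[i1] - t[i0])
    intercept = y[i0] - slope * t[i0]
    corr = y[idx] - (slope * t[idx] + intercept)

    edge = max(5, idx.size // 10)
    edges = np.concatenate([corr[:edge], corr[-edge:]])
    noise = float(1.4826 * np.median(np.abs(edges - np.median(edges))))

    apex_local = int(np.argmax(corr))
    height = corr[apex_local]
    floor = max(3.0 * noise, 1e-12 * max(1.0, float(np.max(np.abs(y)))))
    if height <= floor:
        raise PeakError("no peak above the noise level in the window")

    # warn about co-elution: distinct islands above 30% of the apex lasting
    # at least 3 samples (single-sample noise spikes do not count)
    above = corr > max(floor, 0.3 * height)
    bounded = np.concatenate([[False], above, [False]])
    starts = np.nonzero(np.diff(bounded.astype(int)) == 1)[0]
    ends = np.nonzero(np.diff(bounded.astype(int)) == -1)[0]
    if int(np.sum((ends - starts) >= 3)) > 1:
        warnings.warn("multiple peaks in window; using the tallest", stacklevel=2)

    left = apex_local
    while left > 0 and corr[left] > floor:
        left -= 1
    right = apex_local
    while right < corr.size - 1 and corr[right] > floor:
        right += 1
    return PeakRegion(
        apex_index=int(idx[apex_local]),
        left_index=int(idx[left]),
        right_index=int(idx[right]),
        window=(float(lo), float(hi)),
        baseline_slope=float(slope),
        baseline_intercept=float(intercept),
        noise_sd=noise,
    )


def width_at_fraction(
    chrom: Chromatogram, peak: PeakRegion, fraction: float
) -> tuple[float, float, float]:
    """(total width, front half-width, back half-width) at a height fraction.

    Crossing times are linearly interpolated between samples of the
    baseline-corrected signal.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    t = chrom.time
    corr = _corrected(chrom, peak)
    apex = peak.apex_index
    target = fraction * corr[apex]

    def cross(direction: int) -> float:
        i = apex
        while 0 < i < len(t) - 1:
            j = i + direction
            if corr[j] <= target:
                # interpolate between j (below) and i (above)
                fr = (corr[i] - target) / (corr[i] - corr[j])
                return float(t[i] + fr * (t[j] - t[i]))
            i = j
        raise BoundaryError(
            f"signal does not cross {fraction:.0%} of peak height "
            f"{'after' if direction > 0 else 'before'} the apex"
        )

    t_left = cross(-1)
    t_right = cross(+1)
    apex_t = float(t[apex])
    return (t_right - t_left, apex_t - t_left, t_right - apex_t)


def theoretical_plates(t_r: float, width_half: float) -> float:
    """Column efficiency from the half-height width: N = 5.54 (t_R/W_0.5)^2."""
    if t_r <= 0 or width_half <= 0:
        raise ValueError("retention time and width must be positive")
    return 5.54 * (t_r / width_half) ** 2


def tailing_factor(chrom: Chromatogram, peak: PeakRegion) -> float:
    """USP tailing factor T_f = W_0.05 / (2 f) at 5% of peak height."""
    w, f, _ = width_at_fraction(chrom, peak, 0.05)
    return w / (2.0 * f)


def signal_to_noise(
    chrom: Chromatogram,
    peak: PeakRegion,
    noise_window: tuple[float, float],
    convention: str = "peak-to-peak",
) -> float:
    """S/N = 2H/h (peak-to-peak) or H/sd (rms) against an analyte-free window.

    The noise window is linearly detrended before measuring its amplitude.
    A noiseless trace yields ``inf``.
    """
    lo, hi = noise_window
    t = chrom.time
    peak_lo, peak_hi = t[peak.left_index], t[peak.right_index]
    if lo < peak_hi and hi > peak_lo:
        raise DesignError("noise window overlaps the peak region")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 20:
        raise DesignError("noise window must contain at least 20 points")
    yn = chrom.intensity[mask]
    tn = t[mask]
    coef = np.polyfit(tn, yn, 1)
    resid = yn - np.polyval(coef, tn)
    height = float(_corrected(chrom, peak)[peak.apex_index])
    if convention == "peak-to-peak":
        h = float(np.ptp(resid))
        if h == 0.0:
            return math.inf
        return 2.0 * height / h
    if convention == "rms":
        sd = float(np.std(resid, ddof=1))
        if sd == 0.0:
            return math.inf
        return height / sd
    raise ValueError("convention must be 'peak-to-peak' or 'rms'")


def lod_from_sn(
    height_slope: float, noise_h: float, target_sn: float = 3.0
) -> float:
    """Concentration whose predicted peak height reaches a target S/N.

    ``height_slope`` is peak height per unit concentration; with the
    peak-to-peak convention S/N = 2 H / h, so C = target * h / (2 * slope).
    """
    if height_slope <= 0 or noise_h <= 0:
        raise ValueError("height slope and noise amplitude must be positive")
    if target_sn < 0:
        raise ValueError("target S/N must be non-negative")
    return target_sn * noise_h / (2.0 * height_slope)


def peak_metrics(
    chrom: Chromatogram,
    peak: PeakRegion,
    noise_window: tuple[float, float] | None = None,
) -> PeakMetrics:
    """Bundle of retention time, area, height, N, T_f and (optionally) S/N."""
    t = chrom.time
    corr = _corrected(chrom, peak)
    sel = slice(peak.left_index, peak.right_index + 1)
    area = float(np.trapezoid(corr[sel], t[sel]))
    t_r = float(t[peak.apex_index])
    w_half, _, _ = width_at_fraction(chrom, peak, 0.5)
    snr = (
        signal_to_noise(chrom, peak, noise_window) if noise_window is not None else None
    )
    return PeakMetrics(
        retention_time=t_r,
        area=area,
        height=float(corr[peak.apex_index]),
        plates=theoretical_plates(t_r, w_half),
        tailing=tailing_factor(chrom, peak),
        snr=snr,
    )


# ---------------------------------------------------------------------------
# system suitability


@dataclass(frozen=True)
class SSTCriteria:
    """Acceptance gates: efficiency, injection repeatability, peak symmetry."""

    min_plates: float = 5000.0
    max_rsd_pct: float = 2.0       # both retention time and area
    max_tailing: float = 1.5


@dataclass(frozen=True)
class SSTReport:
    rsd_retention_pct: float
    rsd_area_pct: float
    plates: float
    tailing: float
    plates_ok: bool
    retention_rsd_ok: bool
    area_rsd_ok: bool
    tailing_ok: bool
    overall_pass: bool


def sst_evaluate(
    injections,
    plates: float,
    tailing: float,
    criteria: SSTCriteria = SSTCriteria(),
) -> SSTReport:
    """Evaluate replicate injections (list of (t_R, area)) against the gates."""
    arr = np.asarray(injections, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DesignError("need at least 2 (retention, area) replicate injections")
    t_r, area = arr[:, 0], arr[:, 1]
    rsd_t = 100.0 * np.std(t_r, ddof=1) / np.mean(t_r)
    rsd_a = 100.0 * np.std(area, ddof=1) / np.mean(area)
    plates_ok = plates > criteria.min_plates
    t_ok = rsd_t <= criteria.max_rsd_pct
    a_ok = rsd_a <= criteria.max_rsd_pct
    tf_ok = tailing <= criteria.max_tailing
    return SSTReport(
        rsd_retention_pct=float(rsd_t),
        rsd_area_pct=float(rsd_a),
        plates=float(plates),
        tailing=float(tailing),
        plates_ok=bool(plates_ok),
        retention_rsd_ok=bool(t_ok),
        area_rsd_ok=bool(a_ok),
        tailing_ok=bool(tf_ok),
        overall_pass=bool(plates_ok and t_ok and a_ok and tf_ok),
    )
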