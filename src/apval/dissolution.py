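"""Two-stage dissolution reduction: cumulative percent dissolved with
withdrawal/replacement correction and medium-change volume accounting.

The test starts in a gastric-stage volume V1 (e.g. 100 mL); at the stage
change an equal volume of double-concentrated intestinal medium is added,
doubling the vessel volume to V2 while conserving the analyte mass (the
in-vessel concentration halves).  At each sampling time a small aliquot V_s
is withdrawn for analysis and replaced with blank medium, so the analyte
removed with earlier aliquots must be added back when accumulating:

    %dissolved_i = 100 * ( C_i * V(t_i) + V_s * sum_{j<i} C_j ) / dose,

with V(t) the stage-appropriate vessel volume.  On noiseless data this
correction recovers the true dissolved fraction exactly for any sampling
schedule (the aliquot mass-balance telescopes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DesignError


@dataclass(frozen=True)
class DissolutionRun:
    """Time-stamped sampled concentrations of one dissolution vessel.

    ``sampled_concentrations`` are vessel concentrations in ug/mL (any
    analytical dilution already removed); ``dose_mg`` is the label claim of
    analyte in the formulation.  ``sample_before_change`` states whether the
    sample taken exactly at the stage-change time precedes the medium
    addition (default) or follows it.
    """

    timepoints: tuple[float, ...]              # min
    sampled_concentrations: tuple[float, ...]  # ug/mL
    dose_mg: float
    sample_volume_ml: float = 2.0
    stage1_volume_ml: float = 100.0
    stage2_volume_ml: float = 200.0
    stage_change_time: float | None = 60.0
    sample_before_change: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        c = np.asarray(self.sampled_concentrations, dtype=float)
        object.__setattr__(self, "timepoints", tuple(t))
        object.__setattr__(self, "sampled_concentrations", tuple(c))
        if t.shape != c.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("timepoints and concentrations must match and be non-empty")
        if np.any(t < 0):
            raise ValueError("timepoints must be non-negative")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("negative sampled concentration")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        if self.stage1_volume_ml <= 0 or self.stage2_volume_ml <= 0:
            raise ValueError("vessel volumes must be positive")
        if not 0 <= self.sample_volume_ml < self.stage1_volume_ml:
            raise ValueError("sample volume must be smaller than the vessel volume")

    def volume_at(self, t: float) -> float:
        """Vessel volume applicable to the sample drawn at time t (mL)."""
        if self.stage_change_time is None or t < self.stage_change_time:
            return self.stage1_volume_ml
        if t == self.stage_change_time and self.sample_before_change:
            return self.stage1_volume_ml
        return self.stage2_volume_ml


def apply_stage_change(
    run: DissolutionRun,
    t_change: float,
    added_volume_ml: float,
    concentrate_factor: float = 2.0,
) -> tuple[DissolutionRun, float]:
    """Install a medium change in the run's volume schedule.

    Returns the updated run and the expected dilution factor of the
    in-vessel analyte concentration, V_before / (V_before + V_added):
    the added concentrate carries medium (at ``concentrate_factor`` strength,
    so the mixed medium returns to 1x) but no analyte, whose mass is
    conserved across the change.
    """
    if added_volume_ml < 0:
        raise ValueError("added volume must be non-negative")
    if concentrate_factor <= 0:
        raise ValueError("concentrate factor must be positive")
    t = np.asarray(run.timepoints)
    if not (t[0] <= t_change <= t[-1]):
        raise DesignError("stage-change time outside the sampling schedule")
    v1 = run.stage1_volume_ml
    v2 = v1 + added_volume_ml
    dilution = v1 / v2
    updated = replace(
        run, stage_change_time=t_change, stage2_volume_ml=v2
    )
    return updated, dilution


def cumulative_release(
    run: DissolutionRun,
    withdrawal_correction: bool = True,
    monotonicity_tol_pct: float = 5.0,
) -> np.ndarray:
    """Cumulative percent of the dose dissolved at each timepoint.

    The withdrawal correction adds back the analyte removed with earlier
    aliquots; it can be disabled to reproduce uncorrected reductions.
    Decreases larger than ``monotonicity_tol_pct`` raise a warning (noise
    makes small decreases legitimate; large ones suggest a schedule or
    volume misconfiguration) but the values are returned as computed.
    """
    c = np.asarray(run.sampled_concentrations, dtype=float)
    t = np.asarray(run.timepoints, dtype=float)
    dose_ug = run.dose_mg * 1000.0
    vols = np.array([run.volume_at(ti) for ti in t])
    removed = (
        run.sample_volume_ml * np.concatenate([[0.0], np.cumsum(c)[:-1]])
        if withdrawal_correction
        else np.zeros_like(c)
    )
    pct = 100.0 * (c * vols + removed) / dose_ug
    drops = np.diff(pct)
    if np.any(drops < -monotonicity_tol_pct):
        worst = float(drops.min())
        warnings.warn(
            f"cumulative release decreases by {-worst:.2f}% between timepoints; "
            "check volumes and schedule",
            stacklevel=2,
        )
    return pct


@dataclass(frozen=True)
class DissolutionSummary:
    value_at: float | None
    value_at_time: float
    time_to_threshold: float | None
    threshold_pct: float
    plateau_pct: float


def profile_summary(
    timepoints,
    percent_dissolved,
    at_time: float = 5.0,
    threshold_pct: float = 85.0,
    plateau_points: int = 3,
) -> DissolutionSummary:
    """Linear-interpolated read-outs of a cumulative-release curve.

    ``time_to_threshold`` is None when the curve never reaches the
    threshold; the plateau is the mean of the last ``plateau_points``.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(percent_dissolved, dtype=float)
    if t.size == 0 or t.size != y.size:
        raise ValueError("empty or mismatched curve")
    value_at = float(np.interp(at_time, t, y)) if t[0] <= at_time <= t[-1] else None
    time_to = None
    reached = np.nonzero(y >= threshold_pct)[0]
    if reached.size:
        i = int(reached[0])
        if i == 0:
            time_to = float(t[0])
        else:
            frac = (threshold_pct - y[i - 1]) / (y[i] - y[i - 1])
            time_to = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    plateau = float(np.mean(y[-plateau_points:]))
    return DissolutionSummary(
        value_at=value_at,
        value_at_time=at_time,
        time_to_threshold=time_to,
        threshold_pct=threshold_pct,
        plateau_pct=plateau,
    )
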