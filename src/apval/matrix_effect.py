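"""Matrix effect as the ratio of matrix-matched to aqueous calibration slopes.

ME% = 100 * slope_matrix / slope_aqueous.  100% means the sample matrix
neither suppresses nor enhances the detector response; values inside a
90-110% band are conventionally treated as acceptable for UV detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .response_models import CalibrationFit

DEFAULT_BAND = (90.0, 110.0)


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention of printed tables;
    avoids banker's-rounding surprises at .x5 boundaries)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _slope(fit_or_slope) -> float:
    if isinstance(fit_or_slope, CalibrationFit):
        return float(fit_or_slope.slope)
    return float(fit_or_slope)


@dataclass(frozen=True)
class MatrixEffectResult:
    matrix: str
    fat_content: float
    reagent: str
    matrix_slope: float
    aqueous_slope: float
    me_pct: float                  # full precision
    acceptable: bool

    @property
    def me_pct_display(self) -> float:
        return round_half_away(self.me_pct, 1)


def matrix_effect(
    matrix_fit,
    aqueous_fit,
    matrix: str = "",
    fat_content: float = float("nan"),
    reagent: str = "",
    band: tuple[float, float] = DEFAULT_BAND,
) -> MatrixEffectResult:
    """ME% for one matrix-matched calibration against the aqueous one."""
    ms, aq = _slope(matrix_fit), _slope(aqueous_fit)
    if ms <= 0 or aq <= 0:
        raise ValueError("slopes must be strictly positive")
    me = 100.0 * ms / aq
    return MatrixEffectResult(
        matrix=matrix,
        fat_content=fat_content,
        reagent=reagent,
        matrix_slope=ms,
        aqueous_slope=aq,
        me_pct=me,
        acceptable=band[0] <= me <= band[1],
    )


@dataclass(frozen=True)
class MatrixEffectTable:
    results: tuple[MatrixEffectResult, ...]
    me_min: float
    me_max: float
    all_acceptable: bool


def me_table(
    slope_grid: dict,
    aqueous_slope,
    band: tuple[float, float] = DEFAULT_BAND,
) -> MatrixEffectTable:
    """ME% for a grid of per-(matrix, fat%, reagent) slopes.

    ``slope_grid`` maps ``(matrix, fat_content, reagent)`` to a slope or
    :class:`CalibrationFit`.
    """
    if not slope_grid:
        raise ValueError("empty slope grid")
    results = tuple(
        matrix_effect(s, aqueous_slope, matrix=m, fat_content=f, reagent=r, band=band)
        for (m, f, r), s in slope_grid.items()
    )
    mes = [r.me_pct for r in results]
    return MatrixEffectTable(
        results=results,
        me_min=min(mes),
        me_max=max(mes),
        all_acceptable=all(r.acceptable for r in results),
    )


def slope_sd_from_replicates(fits) -> tuple[float, float]:
    """Mean and sample standard deviation of per-day calibration slopes."""
    slopes = np.asarray([_slope(f) for f in fits], dtype=float)
    if slopes.size < 2:
        raise ValueError("need at least 2 per-day fits for a slope SD")
    return float(slopes.mean()), float(slopes.std(ddof=1))
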