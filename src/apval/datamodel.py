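"""Domain types shared by every validation stage.

The central objects are :class:`ValidationDesign` — the p-series x m-level x
n-replicate layout of a calibration/validation experiment — and
:class:`MeasurementTable`, a thin wrapper around a long-format pandas
DataFrame of detector responses.

Concentrations are stored in ug/mL throughout; percent-of-target is derived
as ``100 * C / target_concentration``, where the target is the highest
expected analyte concentration (the top design level corresponds to 120% of
it, e.g. 600 ug/mL -> target 500 ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, IntegrityError, SchemaError

#: canonical column names of the long-format measurement table
REQUIRED_COLUMNS = (
    "role",
    "series_id",
    "level_index",
    "replicate_index",
    "nominal_concentration",
    "response",
)
OPTIONAL_COLUMN_DEFAULTS = {
    "matrix": "aqueous",
    "fat_content": 0.0,
    "reagent": "",
}
KEY_COLUMNS = (
    "role",
    "series_id",
    "level_index",
    "replicate_index",
    "matrix",
    "fat_content",
    "reagent",
)

ROLE_CALIBRATION = "calibration"
ROLE_VALIDATION = "validation"

#: fraction of the target concentration covered by the top design level
TOP_LEVEL_FRACTION = 1.2


@dataclass(frozen=True)
class ValidationDesign:
    """Layout of a calibration/validation experiment.

    Parameters
    ----------
    n_series : int
        Number of independent series (days), ``p`` (>= 2).
    n_replicates : int
        Replicates per series and level, ``n`` (>= 2).
    n_levels : int
        Number of concentration levels, ``m`` (>= 2).
    nominal_concentrations : tuple of float
        Strictly increasing level concentrations in ug/mL.
    beta : float
        Proportion of future results the tolerance interval should contain.
    lambda_limit : float
        Acceptance half-width of the accuracy profile, in percent.
    """

    n_series: int
    n_replicates: int
    n_levels: int
    nominal_concentrations: tuple[float, ...]
    beta: float = 0.95
    lambda_limit: float = 15.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "nominal_concentrations",
            tuple(float(c) for c in self.nominal_concentrations),
        )
        if self.n_series < 2:
            raise DesignError("need at least 2 series (p >= 2)")
        if self.n_replicates < 2:
            raise DesignError("need at least 2 replicates per series (n >= 2)")
        if self.n_levels < 2:
            raise DesignError("need at least 2 concentration levels (m >= 2)")
        if len(self.nominal_concentrations) != self.n_levels:
            raise DesignError(
                f"{self.n_levels} levels declared but "
                f"{len(self.nominal_concentrations)} concentrations given"
            )
        conc = np.asarray(self.nominal_concentrations)
        if not np.all(conc > 0):
            raise DesignError("nominal concentrations must be strictly positive")
        if not np.all(np.diff(conc) > 0):
            raise DesignError("nominal concentrations must be strictly increasing")
        if not 0.0 < self.beta < 1.0:
            raise DesignError("beta must lie in (0, 1)")
        if self.lambda_limit <= 0:
            raise DesignError("lambda_limit must be positive")

    @property
    def target_concentration(self) -> float:
        """Highest expected analyte concentration (top level / 1.2), ug/mL."""
        return self.nominal_concentrations[-1] / TOP_LEVEL_FRACTION

    def percent_of_target(self, concentration: float) -> float:
        return 100.0 * concentration / self.target_concentration

    def level_concentration(self, level_index: int) -> float:
        """Concentration of a 1-based level index."""
        return self.nominal_concentrations[level_index - 1]


def study_design(beta: float = 0.95, lambda_limit: float = 15.0) -> ValidationDesign:
    """The 3-series x 5-level x 3-replicate design at 10-600 ug/mL
    (2-120% of a 500 ug/mL target)."""
    return ValidationDesign(
        n_series=3,
        n_replicates=3,
        n_levels=5,
        nominal_concentrations=(10.0, 50.0, 100.0, 300.0, 600.0),
        beta=beta,
        lambda_limit=lambda_limit,
    )


@dataclass
class MeasurementTable:
    """Long-format measurement records plus the design they instantiate."""

    frame: pd.DataFrame
    design: ValidationDesign

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design: ValidationDesign | None = None
    ) -> "MeasurementTable":
        """Validate a raw DataFrame and wrap it; infer the design if absent."""
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for col, default in OPTIONAL_COLUMN_DEFAULTS.items():
            if col not in frame.columns:
                frame[col] = default
        frame["nominal_concentration"] = frame["nominal_concentration"].astype(float)
        frame["response"] = frame["response"].astype(float)
        frame["level_index"] = frame["level_index"].astype(int)
        frame["replicate_index"] = frame["replicate_index"].astype(int)

        if not np.isfinite(frame["response"]).all():
            raise IntegrityError("non-finite response values present")
        if (frame["nominal_concentration"] <= 0).any():
            raise IntegrityError("nominal concentrations must be positive")
        bad_role = set(frame["role"]) - {ROLE_CALIBRATION, ROLE_VALIDATION}
        if bad_role:
            raise IntegrityError(f"unknown role(s): {sorted(bad_role)}")
        dup = frame.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            first = frame.loc[dup.idxmax(), list(KEY_COLUMNS)].to_dict()
            raise IntegrityError(f"duplicate measurement key: {first}")

        if design is None:
            design = infer_design(frame)
        known = set(design.nominal_concentrations)
        extra = sorted(set(frame["nominal_concentration"]) - known)
        if extra:
            raise IntegrityError(
                f"record concentrations {extra} not among design levels"
            )
        return cls(frame=frame, design=design)

    def subset(self, role: str, **filters) -> pd.DataFrame:
        sel = self.frame["role"] == role
        for col, val in filters.items():
            sel &= self.frame[col] == val
        return self.frame[sel]

    def calibration(self, **filters) -> pd.DataFrame:
        return self.subset(ROLE_CALIBRATION, **filters)

    def validation(self, **filters) -> pd.DataFrame:
        return self.subset(ROLE_VALIDATION, **filters)

    @property
    def series_ids(self) -> list:
        """Series labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["series_id"]))


def infer_design(frame: pd.DataFrame) -> ValidationDesign:
    """Infer (p, n, m, levels) from a parsed long-format frame.

    The replicate count is taken as the modal cell size so that a single
    aberrant cell does not distort the design; `validate_design` reports
    such cells explicitly.  Inference is invariant to row order.
    """
    levels = tuple(sorted(set(frame["nominal_concentration"].astype(float))))
    p = frame["series_id"].nunique()
    cell_sizes = frame.groupby(list(KEY_COLUMNS[:3]) + ["matrix"], sort=True).size()
    n = int(cell_sizes.mode().iloc[0])
    return ValidationDesign(
        n_series=p,
        n_replicates=n,
        n_levels=len(levels),
        nominal_concentrations=levels,
    )


def validate_design(table: MeasurementTable, roles: Iterable[str] | None = None) -> list[str]:
    """Check balance/completeness; return human-readable findings (empty = OK).

    Unbalanced tables are reported, not rejected — the accuracy-profile stage
    refuses them separately because its formulas assume balance.
    """
    design = table.design
    findings: list[str] = []
    if roles is None:
        roles = sorted(set(table.frame["role"]))
    series = table.series_ids
    if len(series) != design.n_series:
        findings.append(
            f"table has {len(series)} series but design declares {design.n_series}"
        )
    for role in roles:
        sub = table.frame[table.frame["role"] == role]
        if sub.empty:
            continue
        for s in series:
            for lvl in range(1, design.n_levels + 1):
                cell = sub[(sub["series_id"] == s) & (sub["level_index"] == lvl)]
                got = len(cell)
                want = design.n_replicates
                if got == 0:
                    findings.append(f"{role}: missing cell (series {s}, level {lvl})")
                elif got < want:
                    present = set(cell["replicate_index"])
                    for r in range(1, want + 1):
                        if r not in present:
                            findings.append(
                                f"{role}: missing (series {s}, level {lvl}, replicate {r})"
                            )
                elif got > want:
                    findings.append(
                        f"{role}: extra replicate in (series {s}, level {lvl}): "
                        f"{got} > {want}"
                    )
    return findings
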