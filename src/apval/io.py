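"""CSV readers, design validation entry points and report assembly.

The single tabular interchange format is UTF-8 CSV with a header row.
Default column names are the canonical ones in :mod:`apval.datamodel`
(``role, series_id, level_index, replicate_index, nominal_concentration,
response`` plus optional ``matrix, fat_content, reagent``); a schema map
``{file_column: canonical_column}`` adapts foreign headers.

Reports are written as a machine-readable JSON file (floats at full
precision, so a write/read round trip is bit-exact) plus profile plots.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy_profile import AccuracyProfile
from .datamodel import (
    MeasurementTable,
    REQUIRED_COLUMNS,
    ValidationDesign,
)
from .errors import ParseError, SchemaError
from .matrix_effect import MatrixEffectTable

RESULT_FILENAME = "results.json"


def read_measurements(
    path,
    schema: dict | None = None,
    design: ValidationDesign | None = None,
) -> MeasurementTable:
    """Read a long-format CSV of calibration/validation standards.

    ``schema`` maps file column names to the canonical names; the design is
    inferred from the data when not supplied.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    if schema:
        frame = frame.rename(columns=dict(schema))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("response", "nominal_concentration"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
        elif coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
        else:
            frame[col] = coerced
            continue
        raise ParseError(f"{path}: non-numeric {col} at file row {row}")
    return MeasurementTable.from_frame(frame, design=design)


def write_measurements(table: MeasurementTable, path) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report assembly


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def profile_report_dict(
    profile: AccuracyProfile, me: MatrixEffectTable | None = None
) -> dict:
    """The report payload: per-level statistics, limits and decision."""
    doc = _jsonable(profile)
    if profile.valid and profile.target_concentration:
        doc["decision"] = (
            f"valid over {profile.lloq_pct:g}–{profile.uloq_pct:g}%"
        )
    else:
        doc["decision"] = "not valid over the full range"
    if me is not None:
        doc["matrix_effect"] = _jsonable(me)
    return doc


def write_report(
    profile: AccuracyProfile,
    me: MatrixEffectTable | None = None,
    path=".",
    plots: bool = True,
) -> list[Path]:
    """Write ``results.json`` (and profile plots) into a directory.

    Returns the written paths.  Re-reading the JSON reproduces every numeric
    field bit-exactly (JSON floats round-trip at full precision).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    result_path = out / RESULT_FILENAME
    with open(result_path, "w", encoding="utf-8") as fh:
        json.dump(profile_report_dict(profile, me), fh, indent=2)
    written.append(result_path)
    if plots:
        written.append(plot_accuracy_profile(profile, out / "accuracy_profile.png"))
    return written


def read_report(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / RESULT_FILENAME
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def plot_accuracy_profile(profile: AccuracyProfile, path) -> Path:
    """Accuracy-profile figure: per-level bias, tolerance interval and the
    acceptance limits on a log-concentration axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    conc = [s.nominal_concentration for s in profile.levels]
    bias = [s.relative_bias_pct for s in profile.levels]
    low = [s.beta_eti_low_pct for s in profile.levels]
    high = [s.beta_eti_high_pct for s in profile.levels]
    lam = profile.lambda_limit_pct

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axhline(lam, color="k", ls=":", label=f"acceptance limits ±{lam:g}%")
    ax.axhline(-lam, color="k", ls=":")
    ax.plot(conc, bias, "o-", color="tab:red", label="relative bias")
    ax.plot(conc, low, "--", color="tab:blue", label=f"β-ETI (β={profile.beta:g})")
    ax.plot(conc, high, "--", color="tab:blue")
    ax.set_xscale("log")
    ax.set_xlabel("concentration (µg/mL)")
    ax.set_ylabel("relative error (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
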