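"""Reading, writing and canonicalising CGM traces and clinical tables.

All glucose values are held internally in mmol/L.  A flash-monitor export
(LibreView-style) dialect is supported in addition to the canonical long CSV
``patient_id,timestamp,glucose[,unit]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

#: Conversion factor between mg/dL and mmol/L (molar mass of glucose 180.16 g/mol).
MMOL_PER_MGDL = 1.0 / 18.016


@dataclass
class GlucoseSeries:
    """One patient's time-ordered CGM trace in mmol/L.

    ``timestamps`` are minute-resolution instants; after
    :func:`dedup_minute_median` they are strictly increasing with at most one
    value per calendar minute.  Values are finite and positive.
    """

    patient_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must be parallel")
        if len(self.values) and (not np.all(np.isfinite(self.values))
                                 or np.any(self.values <= 0)):
            raise ValueError("glucose values must be finite and > 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DropReport:
    """Counts of rows discarded while reading a CGM file."""

    n_rows: int = 0
    n_bad_timestamp: int = 0
    n_bad_glucose: int = 0
    per_patient: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_bad_timestamp + self.n_bad_glucose

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "n_rows": self.n_rows,
            "n_bad_timestamp": self.n_bad_timestamp,
            "n_bad_glucose": self.n_bad_glucose,
            "n_dropped": self.n_dropped,
            "per_patient": self.per_patient,
        }, indent=2))


def _to_mmol(values: pd.Series, units: pd.Series) -> pd.Series:
    factor = np.where(units.str.lower().isin(["mg_dl", "mg/dl", "mgdl"]),
                      MMOL_PER_MGDL, 1.0)
    return values * factor


def _infer_unit(values: pd.Series) -> str:
    # mmol/L values live roughly in [2, 30]; mg/dL in [40, 500].
    return "mg_dl" if values.median() > 35 else "mmol_l"


def read_cgm_csv(path, dialect: str = "long", unit: str = "auto",
                 patient_id: str | None = None,
                 include_scans: bool = False) -> tuple[list[GlucoseSeries], DropReport]:
    """Read CGM traces from a CSV file.

    Parameters
    ----------
    path
        CSV file.  The ``long`` dialect requires columns ``patient_id``,
        ``timestamp`` (ISO-8601) and ``glucose``, with an optional per-row
        ``unit`` column.  The ``libreview`` dialect accepts a flash-monitor
        export with ``Device Timestamp`` and ``Historic Glucose mmol/L`` (or
        the mg/dL variant) columns.
    dialect
        ``"long"`` or ``"libreview"``.
    unit
        ``"mmol_l"``, ``"mg_dl"`` or ``"auto"``.  ``auto`` uses a per-row
        ``unit`` column when present, else infers from the value magnitude.
    patient_id
        For the libreview dialect (one patient per file): overrides the
        patient id; defaults to the file stem.
    include_scans
        Libreview only: also keep manually scanned readings (record type 1)
        in addition to the automatically logged historic readings (type 0).

    Returns
    -------
    (series, report)
        One not-yet-deduplicated :class:`GlucoseSeries` per patient, values in
        mmol/L, plus a :class:`DropReport` counting discarded rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        df = pd.read_csv(path, dtype={"patient_id": str})
        required = {"patient_id", "timestamp", "glucose"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"missing required column(s): {sorted(missing)}")
    elif dialect == "libreview":
        df = _read_libreview(path, patient_id or path.stem, include_scans)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    report = DropReport(n_rows=len(df))
    if df.empty:
        warnings.warn(f"{path}: no data rows")
        return [], report

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad_ts = ts.isna()
    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    bad_glu = ~np.isfinite(glucose) | (glucose <= 0)
    report.n_bad_timestamp = int(bad_ts.sum())
    report.n_bad_glucose = int((bad_glu & ~bad_ts).sum())
    keep = ~(bad_ts | bad_glu)
    df = df.loc[keep].copy()
    df["timestamp"] = ts[keep]
    df["glucose"] = glucose[keep]

    if unit == "auto":
        if "unit" in df.columns:
            df["glucose"] = _to_mmol(df["glucose"], df["unit"].astype(str))
        elif len(df) and _infer_unit(df["glucose"]) == "mg_dl":
            df["glucose"] = df["glucose"] * MMOL_PER_MGDL
    elif unit == "mg_dl":
        df["glucose"] = df["glucose"] * MMOL_PER_MGDL
    elif unit != "mmol_l":
        raise ValueError(f"unknown unit: {unit!r}")

    series = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        series.append(GlucoseSeries(str(pid),
                                    pd.DatetimeIndex(grp["timestamp"]),
                                    grp["glucose"].to_numpy()))
        report.per_patient[str(pid)] = len(grp)
    return series, report


def _read_libreview(path: Path, patient_id: str, include_scans: bool) -> pd.DataFrame:
    """Normalise a LibreView-style export into long-format columns."""
    # Exports may carry a one-line file header before the column header.
    with open(path) as fh:
        head = [fh.readline() for _ in range(3)]
    skip = next((i for i, line in enumerate(head) if "Device Timestamp" in line), 0)
    df = pd.read_csv(path, skiprows=skip)
    if "Device Timestamp" not in df.columns:
        raise FormatError("missing required column(s): ['Device Timestamp']")

    frames = []
    specs = [("Historic Glucose mmol/L", 1.0, "0"),
             ("Historic Glucose mg/dL", MMOL_PER_MGDL, "0")]
    if include_scans:
        specs += [("Scan Glucose mmol/L", 1.0, "1"),
                  ("Scan Glucose mg/dL", MMOL_PER_MGDL, "1")]
    has_type = "Record Type" in df.columns
    for col, factor, rectype in specs:
        if col not in df.columns:
            continue
        sub = df
        if has_type:
            sub = df[df["Record Type"].astype(str) == rectype]
        vals = pd.to_numeric(sub[col], errors="coerce") * factor
        frames.append(pd.DataFrame({
            "patient_id": patient_id,
            "timestamp": sub["Device Timestamp"],
            "glucose": vals,
        }).dropna(subset=["glucose"]))
    if not frames:
        raise FormatError("no glucose columns found "
                          "(expected 'Historic Glucose mmol/L' or mg/dL variant)")
    return pd.concat(frames, ignore_index=True)


def write_cgm_csv(series: list[GlucoseSeries], path) -> None:
    """Write traces as canonical long CSV (patient_id,timestamp,glucose)."""
    rows = [pd.DataFrame({
        "patient_id": s.patient_id,
        "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "glucose": s.values,
    }) for s in series]
    out = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["patient_id", "timestamp", "glucose"]))
    out.to_csv(path, index=False, float_format="%.9g")


def dedup_minute_median(series: GlucoseSeries) -> GlucoseSeries:
    """Collapse each populated calendar minute to the median of its readings.

    Timestamps are truncated (not rounded) to the minute; minutes with no
    data remain absent.  Idempotent; empty input passes through.
    """
    if len(series) == 0:
        return series
    minutes = series.timestamps.floor("min")
    df = pd.DataFrame({"minute": minutes, "value": series.values})
    agg = df.groupby("minute", sort=True)["value"].median()
    return GlucoseSeries(series.patient_id, pd.DatetimeIndex(agg.index),
                         agg.to_numpy())


def read_clinical_csv(path) -> pd.DataFrame:
    """Read a per-patient clinical covariate table.

    Requires a unique ``patient_id`` column; any other columns may be numeric
    or categorical with missing values allowed.  Non-finite numerics other
    than NaN are rejected.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise FormatError("missing required column(s): ['patient_id']")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise FormatError(f"duplicate patient_id values: {dupes}")
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            vals = df[col].to_numpy(dtype=float)
            if np.any(np.isinf(vals)):
                raise FormatError(f"column {col!r} contains non-finite values")
    return df
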