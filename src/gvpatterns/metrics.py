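"""Patient-level glycemic metrics.

Time in patterns (the share of a patient's windows assigned to each extracted
pattern), time in range over the standard 3 / 3.9 / 10 / 13.9 mmol/L
breakpoints, mean/SD/coefficient-of-variation summaries, fulfilment of the
consensus targets (TIR 3.9-10 > 70%, COV < 0.36, HbA1c < 58 mmol/mol), and
the hourly distribution of patterns across the day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm_io import GlucoseSeries
from .preprocess import Window

TIR_BREAKPOINTS = (3.0, 3.9, 10.0, 13.9)
TIR_BAND_NAMES = ("tir_le_3", "tir_3_3.9", "tir_3.9_10", "tir_10_13.9",
                  "tir_ge_13.9")


@dataclass
class TimeInPatterns:
    """Per-patient composition (percentages summing to 100) over k patterns."""

    patient_id: str
    k: int
    composition: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if len(self.composition) != self.k:
            raise ValueError("composition length must equal k")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if np.any(self.composition < 0) or abs(self.composition.sum() - 100) > 1e-9:
            raise ValueError("composition must be nonnegative and sum to 100")


@dataclass
class GlycemicSummary:
    """Mean, sample SD, COV (= SD/mean) and TIR vector for one patient."""

    patient_id: str
    mean_glucose: float
    sd_glucose: float
    cov: float
    tir: np.ndarray


def time_in_patterns(labels_by_patient: dict[str, np.ndarray],
                     k: int) -> list[TimeInPatterns]:
    """Tally each patient's window labels into percentages over patterns 1..k."""
    out = []
    for pid, labels in labels_by_patient.items():
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            warnings.warn(f"patient {pid!r} has no labeled windows; excluded")
            continue
        if labels.min() < 1 or labels.max() > k:
            raise ValueError(f"patient {pid!r}: labels must lie in 1..{k}")
        counts = np.bincount(labels, minlength=k + 1)[1:k + 1]
        out.append(TimeInPatterns(pid, k, 100.0 * counts / labels.size,
                                  int(labels.size)))
    return out


def time_in_range(series: GlucoseSeries,
                  breakpoints=TIR_BREAKPOINTS) -> np.ndarray:
    """Percent of measurements per glucose band (measurement-weighted).

    Bands, matching the conventional row labels "<=3" and ">=13.9":
    v <= b1; b1 < v <= b2; b2 < v <= b3; b3 < v < b4; v >= b4.
    """
    if len(series) == 0:
        raise ValueError("series must be nonempty")
    v = series.values
    b1, b2, b3, b4 = breakpoints
    counts = np.array([
        np.count_nonzero(v <= b1),
        np.count_nonzero((v > b1) & (v <= b2)),
        np.count_nonzero((v > b2) & (v <= b3)),
        np.count_nonzero((v > b3) & (v < b4)),
        np.count_nonzero(v >= b4),
    ], dtype=float)
    return 100.0 * counts / len(v)


def glycemic_summary(series: GlucoseSeries) -> GlycemicSummary:
    """Mean, sample SD (n-1 denominator), COV and TIR for one trace."""
    v = series.values
    mean = float(v.mean())
    if len(v) < 2:
        warnings.warn(f"patient {series.patient_id!r}: single sample; "
                      "sd and cov undefined")
        sd = cov = float("nan")
    else:
        sd = float(v.std(ddof=1))
        cov = sd / mean
    return GlycemicSummary(series.patient_id, mean, sd, cov,
                           time_in_range(series))


def target_fulfillment(summary: GlycemicSummary,
                       hba1c: float | None = None) -> dict:
    """Consensus-target flags: TIR(3.9-10] > 70%, COV < 0.36, HbA1c < 58.

    All comparisons are strict, so a patient sitting exactly on a cutoff does
    not meet the target.  Missing HbA1c leaves that flag ``None``.
    """
    return {
        "tir_ok": bool(summary.tir[2] > 70.0),
        "cov_ok": bool(summary.cov < 0.36) if np.isfinite(summary.cov) else None,
        "hba1c_ok": None if hba1c is None or not np.isfinite(hba1c)
        else bool(hba1c < 58.0),
    }


def pattern_occurrence_by_hour(windows: list[Window], labels,
                               k: int) -> pd.DataFrame:
    """k x 24 table: share (%) of windows in each midpoint hour carrying each
    pattern label.  Populated hour columns sum to 100; empty hours are NaN."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(windows):
        raise ValueError("labels and windows must be parallel")
    table = np.full((k, 24), np.nan)
    hours = np.array([w.start_hour for w in windows])
    for h in range(24):
        mask = hours == h
        if not mask.any():
            continue
        counts = np.bincount(labels[mask], minlength=k + 1)[1:k + 1]
        table[:, h] = 100.0 * counts / mask.sum()
    return pd.DataFrame(table, index=pd.RangeIndex(1, k + 1, name="pattern"),
                        columns=pd.RangeIndex(0, 24, name="hour"))


def metrics_table(summaries: list[GlycemicSummary],
                  tips: list[TimeInPatterns],
                  hba1c: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-patient metrics frame: mean/sd/cov, TIR bands, tip_1..tip_k,
    target flags."""
    hba1c = hba1c or {}
    tip_by_pid = {t.patient_id: t for t in tips}
    rows = []
    for s in summaries:
        row = {"patient_id": s.patient_id, "mean_glucose": s.mean_glucose,
               "sd_glucose": s.sd_glucose, "cov": s.cov}
        row.update(dict(zip(TIR_BAND_NAMES, s.tir)))
        t = tip_by_pid.get(s.patient_id)
        if t is not None:
            row.update({f"tip_{p + 1}": t.composition[p] for p in range(t.k)})
        row.update(target_fulfillment(s, hba1c.get(s.patient_id)))
        rows.append(row)
    return pd.DataFrame(rows)
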