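"""Window extraction and measurement-density filtering.

A trace is sliced into fixed-duration windows on a regular stride grid
anchored at the patient's first sample (or midnight).  Windows carry their
samples as (offset, value) pairs, so unevenly spaced data pass through to the
DTW stage without resampling.  Windows averaging fewer than a minimum number
of measurements per hour are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cgm_io import GlucoseSeries
from .errors import ConfigError


@dataclass
class Window:
    """A fixed-duration slice of one patient's trace.

    ``offsets`` are minutes since ``start``, strictly increasing and all
    < ``duration``; ``values`` (mmol/L) run parallel.  ``start_hour`` is the
    hour of day (0-23) of the window midpoint, used for diurnal analysis.
    """

    patient_id: str
    start: pd.Timestamp
    duration: int
    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.offsets) != len(self.values) or len(self.values) < 1:
            raise ValueError("offsets/values must be parallel and nonempty")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.offsets[0] < 0 or self.offsets[-1] >= self.duration:
            raise ValueError("offsets must lie in [0, duration)")

    @property
    def density(self) -> float:
        """Measurements per hour."""
        return 60.0 * len(self.values) / self.duration

    @property
    def start_hour(self) -> int:
        return int((self.start + pd.Timedelta(minutes=self.duration / 2)).hour)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class WindowingConfig:
    """Window duration / overlap / density-filter settings.

    The default search grid is durations {120, 150, 180} minutes and overlaps
    {0, 25, 50, 75} %; the stride ``duration * (1 - overlap/100)`` must be a
    whole positive number of minutes.
    """

    duration: int = 150
    overlap_pct: float = 50.0
    min_density: float = 4.0
    anchor: str = "first_sample"          # or "midnight"
    emit_trailing_partial: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not (0 <= self.overlap_pct < 100):
            raise ConfigError("overlap_pct must be in [0, 100)")
        stride = self.duration * (1 - self.overlap_pct / 100.0)
        # fractional strides (e.g. 150 min at 25% -> 112.5) are rounded to
        # the nearest whole minute; only a degenerate stride is an error
        if round(stride) < 1:
            raise ConfigError(
                f"stride {stride} (duration={self.duration}, "
                f"overlap={self.overlap_pct}%) rounds below one minute")
        if self.anchor not in ("first_sample", "midnight"):
            raise ConfigError(f"unknown anchor: {self.anchor!r}")

    @property
    def stride(self) -> int:
        return int(round(self.duration * (1 - self.overlap_pct / 100.0)))


def extract_windows(series: GlucoseSeries,
                    config: WindowingConfig) -> list[Window]:
    """Slice a deduplicated trace into overlapping windows.

    Window starts lie at ``t0, t0+stride, t0+2*stride, ...`` where ``t0`` is
    the first timestamp (or the preceding midnight under the ``midnight``
    anchor); each window covers the half-open interval
    ``[start, start+duration)`` and is emitted only if it contains at least
    one sample.  By default windows extending past the last sample are
    suppressed (``emit_trailing_partial``), except that the first window is
    always kept so a trace shorter than one duration still yields one window.
    """
    if len(series) == 0:
        return []
    t0 = series.timestamps[0]
    if config.anchor == "midnight":
        t0 = t0.normalize()
    # minutes of each sample relative to the grid origin
    mins = (series.timestamps - t0) / pd.Timedelta(minutes=1)
    mins = np.asarray(mins, dtype=float)
    last = mins[-1]
    stride, dur = config.stride, config.duration
    n_starts = int(np.floor(last / stride)) + 1
    windows: list[Window] = []
    lo = 0
    for i in range(n_starts):
        ws = i * stride
        if ws > last:
            break
        if not config.emit_trailing_partial and ws + dur - 1 > last and i > 0:
            continue  # window extends past the observation span; first window
            # is always kept so short traces still yield one window
        lo = int(np.searchsorted(mins, ws, side="left"))
        hi = int(np.searchsorted(mins, ws + dur, side="left"))
        if hi <= lo:
            continue
        windows.append(Window(
            patient_id=series.patient_id,
            start=t0 + pd.Timedelta(minutes=ws),
            duration=dur,
            offsets=mins[lo:hi] - ws,
            values=series.values[lo:hi],
        ))
    return windows


def density_filter(windows: list[Window],
                   min_density: float = 4.0) -> tuple[list[Window], int]:
    """Keep windows with at least ``min_density`` measurements per hour.

    A window is discarded iff its average rate ``60 * n / duration`` is
    strictly below the threshold, so a 150-minute window needs >= 10 samples
    at the default 4/h.
    """
    if min_density <= 0:
        raise ValueError("min_density must be positive")
    kept = [w for w in windows if w.density >= min_density]
    return kept, len(windows) - len(kept)


def resample_window(window: Window, step: int = 15) -> np.ndarray:
    """Linearly interpolate a window onto a regular offset grid
    ``0, step, ..., duration - step`` (sensitivity-analysis helper)."""
    grid = np.arange(0, window.duration, step, dtype=float)
    return np.interp(grid, window.offsets, window.values)


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    """Long-format view: one row per sample."""
    rows = []
    for i, w in enumerate(windows):
        rows.append(pd.DataFrame({
            "window_index": i,
            "patient_id": w.patient_id,
            "start": w.start.isoformat(),
            "duration": w.duration,
            "offset": w.offsets,
            "value": w.values,
        }))
    if not rows:
        return pd.DataFrame(columns=["window_index", "patient_id", "start",
                                     "duration", "offset", "value"])
    return pd.concat(rows, ignore_index=True)


def save_windows_csv(windows: list[Window], path) -> None:
    windows_to_frame(windows).to_csv(path, index=False, float_format="%.9g")


def save_windows_json(windows: list[Window], path) -> None:
    bundle = [{
        "patient_id": w.patient_id,
        "start": w.start.isoformat(),
        "duration": w.duration,
        "offsets": w.offsets.tolist(),
        "values": w.values.tolist(),
    } for w in windows]
    Path(path).write_text(json.dumps(bundle))


def load_windows_json(path) -> list[Window]:
    bundle = json.loads(Path(path).read_text())
    return [Window(d["patient_id"], pd.Timestamp(d["start"]), d["duration"],
                   np.array(d["offsets"]), np.array(d["values"]))
            for d in bundle]
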