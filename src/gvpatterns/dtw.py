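"""Dynamic time warping distance between glucose sequences.

The distance is the minimal cumulative local cost over monotone,
continuity-respecting warping paths from (1,1) to (n,m), with a symmetric
unit-weight step (diagonal, vertical and horizontal moves each add the local
cost once).  Sequences are compared on their raw mmol/L values by default:
the extracted patterns must distinguish absolute glucose levels (a "normal"
trace from a "severely hyperglycemic" one), which z-normalisation would
destroy.  An optional Sakoe-Chiba band limits |i - j| for speed on long
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class DtwConfig:
    """DTW settings.

    ``local_cost``: ``"abs_diff"`` (L1, default) or ``"squared_diff"`` (L2²).
    ``band_width``: Sakoe-Chiba band half-width in cells, or None for an
    unconstrained alignment; must be at least |len(a) - len(b)| or the path
    is infeasible.  ``normalize_inputs`` z-normalises each sequence first
    (off by default; see module docstring).
    """

    local_cost: str = "abs_diff"
    band_width: int | None = None
    normalize_inputs: bool = False

    def __post_init__(self) -> None:
        if self.local_cost not in ("abs_diff", "squared_diff"):
            raise ConfigError(f"unknown local_cost: {self.local_cost!r}")
        if self.band_width is not None and self.band_width < 0:
            raise ConfigError("band_width must be >= 0")


DEFAULT_DTW = DtwConfig()


def _prepare(seq, normalize: bool) -> list[float]:
    a = np.asarray(seq, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("sequences must be nonempty 1-D arrays")
    if normalize:
        sd = a.std()
        a = (a - a.mean()) / (sd if sd > 0 else 1.0)
    return a.tolist()


def _dtw_cost(a: list[float], b: list[float], squared: bool,
              band: int | None) -> float:
    """O(n·m) dynamic program with a rolling row; plain Python is fast enough
    for the short (10-20 point) sequences a CGM window produces."""
    n, m = len(a), len(b)
    if band is not None and band < abs(n - m):
        raise ConfigError(
            f"Sakoe-Chiba band {band} narrower than length difference "
            f"{abs(n - m)}: no feasible path")
    prev = [inf] * (m + 1)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = [inf] * (m + 1)
        ai = a[i - 1]
        jlo, jhi = 1, m
        if band is not None:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            d = ai - b[j - 1]
            c = d * d if squared else abs(d)
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev = cur
    return prev[m]


def dtw_distance(a, b, config: DtwConfig = DEFAULT_DTW) -> float:
    """DTW distance between two value sequences (raw cumulative cost).

    Symmetric in its arguments, nonnegative, and 0 when ``a == b``.  Raises
    on empty input or an infeasible band.  Note DTW is not a metric: the
    triangle inequality does not hold in general.
    """
    av = _prepare(a, config.normalize_inputs)
    bv = _prepare(b, config.normalize_inputs)
    return _dtw_cost(av, bv, config.local_cost == "squared_diff",
                     config.band_width)


def dtw_distance_normalized(a, b, config: DtwConfig = DEFAULT_DTW) -> float:
    """Path-length-insensitive variant: raw cost divided by len(a)+len(b)."""
    return dtw_distance(a, b, config) / (len(a) + len(b))


def dtw_distance_matrix(seqs, config: DtwConfig = DEFAULT_DTW) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix (each pair computed once)."""
    prepared = []
    for i, s in enumerate(seqs):
        try:
            prepared.append(_prepare(s, config.normalize_inputs))
        except ValueError as e:
            raise ValueError(f"sequence {i}: {e}") from e
    n = len(prepared)
    squared = config.local_cost == "squared_diff"
    D = np.zeros((n, n))
    for i in range(n):
        ai = prepared[i]
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = _dtw_cost(ai, prepared[j], squared,
                                              config.band_width)
            except ConfigError as e:
                raise ConfigError(f"pair ({i}, {j}): {e}") from e
    return D


def save_distance_matrix(D: np.ndarray, ids, path) -> None:
    """Persist a square distance matrix as CSV with sequence ids as header."""
    import pandas as pd
    pd.DataFrame(D, index=list(ids), columns=list(ids)).to_csv(
        path, float_format="%.12g")
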