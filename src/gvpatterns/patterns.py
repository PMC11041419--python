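"""Pattern extraction: DTW k-medoids, cluster validity indices, model selection.

Recurring glycemic-variability patterns are the medoids of a k-medoids (PAM)
partition of CGM windows under the DTW distance.  Window duration and overlap
are chosen by a grid search ranked on four internal validity indices
(Silhouette, Calinski-Harabasz, COP, modified Davies-Bouldin), and the number
of patterns k by the elbow of the total within-cluster distance curve over
k = 3..8.  Pattern labels 1..k are ordered by ascending medoid mean so that
pattern 1 is always the lowest-glucose pattern.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dtw import DtwConfig, DEFAULT_DTW, dtw_distance, dtw_distance_matrix
from .errors import ConfigError, DegenerateDataError
from .preprocess import Window, WindowingConfig, extract_windows, density_filter


# ---------------------------------------------------------------------------
# PAM k-medoids on a precomputed distance matrix
# ---------------------------------------------------------------------------

def _seed_medoids(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point seeding: a random first medoid, then greedily the point
    maximising its distance to the nearest chosen medoid."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    mind = D[medoids[0]].copy()
    for _ in range(1, k):
        mind[medoids] = -1.0
        nxt = int(np.argmax(mind))
        medoids.append(nxt)
        mind = np.minimum(mind, D[nxt])
    return np.array(sorted(medoids))


def _pam_single(D: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """One PAM run: greedy best-improvement swaps until convergence.

    Returns (medoid_indices, assignment, total_within_distance).
    """
    n = D.shape[0]
    medoids = _seed_medoids(D, k, rng)
    for _ in range(max_iter):
        Dm = D[:, medoids]                       # (n, k)
        order = np.argsort(Dm, axis=1, kind="stable")
        assign = order[:, 0]
        d1 = Dm[np.arange(n), assign]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

        cand = np.setdiff1d(np.arange(n), medoids, assume_unique=False)
        if cand.size == 0:
            break
        A = D[np.ix_(np.arange(n), cand)]        # (n, C)
        base = np.minimum(A, d1[:, None]) - d1[:, None]
        base_sum = base.sum(axis=0)              # gain if h added, no removal
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            mask = assign == mi
            if not mask.any():
                delta = base_sum.copy()
            else:
                reassigned = (np.minimum(A[mask], d2[mask, None])
                              - d1[mask, None]).sum(axis=0)
                delta = base_sum - base[mask].sum(axis=0) + reassigned
            ci = int(np.argmin(delta))
            if delta[ci] < best_delta:
                best_delta, best_swap = float(delta[ci]), (mi, int(cand[ci]))
        if best_swap is None:
            break
        medoids = medoids.copy()
        medoids[best_swap[0]] = best_swap[1]
    Dm = D[:, medoids]
    assign = np.argmin(Dm, axis=1)
    # medoid property: each medoid belongs to its own cluster
    assign[medoids] = np.arange(k)
    total = float(Dm[np.arange(n), assign].sum())
    return medoids, assign, total


@dataclass
class PatternModel:
    """k medoid glucose sequences plus the settings that produced them.

    Medoids are actual training windows (medoid property); labels run 1..k
    and are sorted so mean(medoid_1) <= ... <= mean(medoid_k).
    """

    k: int
    medoids: list[np.ndarray]
    windowing: WindowingConfig
    dtw: DtwConfig
    labels: np.ndarray
    total_within_distance: float
    pattern_order: list[int]
    medoid_indices: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        from . import __version__
        Path(path).write_text(json.dumps({
            "version": __version__,
            "k": self.k,
            "medoids": [m.tolist() for m in self.medoids],
            "windowing": asdict(self.windowing),
            "dtw": asdict(self.dtw),
            "pattern_order": self.pattern_order,
            "total_within_distance": self.total_within_distance,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "PatternModel":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], medoids=[np.array(m) for m in d["medoids"]],
                   windowing=WindowingConfig(**d["windowing"]),
                   dtw=DtwConfig(**d["dtw"]),
                   labels=np.array([], dtype=int),
                   total_within_distance=d["total_within_distance"],
                   pattern_order=d["pattern_order"])


def cluster_windows(windows: list[Window], k: int,
                    dtw: DtwConfig = DEFAULT_DTW, seed: int = 0,
                    restarts: int = 5,
                    windowing: WindowingConfig | None = None,
                    distance_matrix: np.ndarray | None = None) -> PatternModel:
    """PAM k-medoids of windows under DTW; best of ``restarts`` seedings.

    ``distance_matrix`` may be supplied to reuse a precomputed pairwise DTW
    matrix (e.g. across the k values of an elbow scan).
    """
    n = len(windows)
    if not (1 <= k <= n):
        raise ValueError(f"need n_windows >= k >= 1, got n={n}, k={k}")
    D = distance_matrix
    if D is None:
        D = dtw_distance_matrix([w.values for w in windows], dtw)
    if k >= 2 and D.max() == 0.0:
        raise DegenerateDataError(
            "all windows identical under DTW: cannot split into k >= 2 clusters")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        med, assign, total = _pam_single(D, k, rng)
        if best is None or total < best[2] - 1e-12:
            best = (med, assign, total)
    med, assign, total = best
    # relabel clusters 1..k by ascending medoid mean glucose
    means = np.array([windows[m].values.mean() for m in med])
    order = np.argsort(means, kind="stable")           # order[p-1] = internal id
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, k + 1)                  # internal id -> label
    labels = rank[assign]
    return PatternModel(
        k=k,
        medoids=[windows[med[i]].values.copy() for i in order],
        windowing=windowing or WindowingConfig(),
        dtw=dtw,
        labels=labels,
        total_within_distance=total,
        pattern_order=[int(i) for i in order],
        medoid_indices=[int(med[i]) for i in order],
    )


# ---------------------------------------------------------------------------
# Cluster validity indices on a precomputed distance matrix
# ---------------------------------------------------------------------------

def compute_cvis(D: np.ndarray, labels: np.ndarray,
                 medoid_indices: np.ndarray) -> dict:
    """Silhouette, Calinski-Harabasz, COP and modified Davies-Bouldin (DB*)
    for a medoid partition, all defined directly on the distance matrix.

    - silhouette: mean over points of (b-a)/max(a,b), a = mean distance to
      own cluster (excluding self), b = min mean distance to another cluster;
      singletons score 0.
    - CH = [B/(k-1)] / [W/(N-k)], W = sum d(x, own medoid)^2,
      B = sum_c |c| d(medoid_c, global medoid)^2, the global medoid being the
      minimiser of total distance over all points.
    - COP = (1/N) sum_c |c| * mean_{x in c} d(x, medoid_c)
      / min_{y not in c} max_{x in c} d(x, y)   (lower is better).
    - DB* = (1/k) sum_i max_{j!=i}(S_i+S_j) / min_{j!=i} d(m_i, m_j),
      S_i = mean distance of members to medoid i   (lower is better).
    """
    labels = np.asarray(labels)
    medoid_indices = np.asarray(medoid_indices)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("need at least 2 nonempty clusters")
    members = [np.flatnonzero(labels == u) for u in uniq]
    pos = {u: i for i, u in enumerate(uniq)}

    # silhouette
    sil = np.zeros(n)
    for idx, lab in enumerate(labels):
        own = members[pos[lab]]
        if len(own) == 1:
            sil[idx] = 0.0
            continue
        a = D[idx, own].sum() / (len(own) - 1)
        b = min(D[idx, mem].mean() for u, mem in zip(uniq, members) if u != lab)
        denom = max(a, b)
        sil[idx] = 0.0 if denom == 0 else (b - a) / denom
    silhouette = float(sil.mean())

    d_own = np.zeros(n)
    for mi, mem in zip(medoid_indices, members):
        d_own[mem] = D[mem, mi]
    total_d = D.sum(axis=1)
    gmed = int(np.argmin(total_d))
    W = float((d_own ** 2).sum())
    B = float(sum(len(mem) * D[mi, gmed] ** 2
                  for mi, mem in zip(medoid_indices, members)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = (B / (k - 1)) / (W / (n - k)) if W > 0 else np.nan
    if not np.isfinite(ch):
        warnings.warn("Calinski-Harabasz undefined (zero within-scatter)")

    cop_terms = []
    for mi, mem in zip(medoid_indices, members):
        intra = D[mem, mi].mean()
        outside = np.setdiff1d(np.arange(n), mem, assume_unique=True)
        denom = D[np.ix_(mem, outside)].max(axis=0).min()
        if denom == 0:
            warnings.warn("COP denominator zero; index reported as NaN")
            cop_terms = [np.nan]
            break
        cop_terms.append(len(mem) * intra / denom)
    cop = float(np.sum(cop_terms) / n)

    S = np.array([D[mem, mi].mean()
                  for mi, mem in zip(medoid_indices, members)])
    Dmm = D[np.ix_(medoid_indices, medoid_indices)]
    db_terms = []
    for i in range(k):
        other = [j for j in range(k) if j != i]
        num = max(S[i] + S[j] for j in other)
        den = min(Dmm[i, j] for j in other)
        if den == 0:
            warnings.warn("DB* denominator zero (coincident medoids); NaN")
            db_terms = [np.nan]
            break
        db_terms.append(num / den)
    db_star = float(np.sum(db_terms) / k)

    return {"silhouette": silhouette, "calinski_harabasz": float(ch),
            "cop": cop, "davies_bouldin_star": db_star}


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _windows_for_config(series_list, wcfg: WindowingConfig) -> list[Window]:
    wins: list[Window] = []
    for s in series_list:
        wins.extend(extract_windows(s, wcfg))
    kept, _ = density_filter(wins, wcfg.min_density)
    return kept


def grid_search(series_list, durations=(120, 150, 180),
                overlaps=(0, 25, 50, 75), k_fixed: int = 6,
                dtw: DtwConfig = DEFAULT_DTW, seed: int = 0,
                max_windows: int = 300, restarts: int = 3,
                min_density: float = 4.0) -> tuple[WindowingConfig, pd.DataFrame]:
    """Choose window duration and overlap by clustering each grid cell at a
    fixed k and ranking the four validity indices.

    A validation subsample of at most ``max_windows`` windows per cell keeps
    the search tractable.  Configs are ranked per index (higher better for
    silhouette/CH, lower better for COP/DB*); the winner has the best mean
    rank, with ties broken by shorter duration then lower overlap.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for dur in durations:
        for ov in overlaps:
            wcfg = WindowingConfig(duration=dur, overlap_pct=ov,
                                   min_density=min_density)
            wins = _windows_for_config(series_list, wcfg)
            if len(wins) < k_fixed:
                warnings.warn(f"config ({dur}, {ov}%) yields "
                              f"{len(wins)} < k={k_fixed} windows; skipped")
                continue
            if len(wins) > max_windows:
                idx = rng.choice(len(wins), size=max_windows, replace=False)
                wins = [wins[i] for i in np.sort(idx)]
            D = dtw_distance_matrix([w.values for w in wins], dtw)
            model = cluster_windows(wins, k_fixed, dtw,
                                    seed=int(rng.integers(2**31)),
                                    restarts=restarts, windowing=wcfg,
                                    distance_matrix=D)
            # map sorted labels back to internal cluster order for the CVIs
            cvis = compute_cvis(D, model.labels,
                                np.array(model.medoid_indices))
            rows.append({"duration": dur, "overlap_pct": ov, "k": k_fixed,
                         "n_windows": len(wins),
                         "total_within_distance": model.total_within_distance,
                         **cvis})
    if not rows:
        raise DegenerateDataError("every grid config was skipped "
                                  "(too few windows)")
    report = pd.DataFrame(rows)
    ranks = pd.DataFrame({
        "silhouette": rankdata(-report["silhouette"]),
        "calinski_harabasz": rankdata(-report["calinski_harabasz"]),
        "cop": rankdata(report["cop"]),
        "davies_bouldin_star": rankdata(report["davies_bouldin_star"]),
    })
    report["mean_rank"] = ranks.mean(axis=1)
    best = report.sort_values(
        ["mean_rank", "duration", "overlap_pct"], kind="stable").iloc[0]
    wcfg = WindowingConfig(duration=int(best["duration"]),
                           overlap_pct=float(best["overlap_pct"]),
                           min_density=min_density)
    return wcfg, report


def elbow_select_k(windows: list[Window], k_range=range(3, 9),
                   dtw: DtwConfig = DEFAULT_DTW, seed: int = 0,
                   restarts: int = 5,
                   distance_matrix: np.ndarray | None = None
                   ) -> tuple[int, pd.DataFrame]:
    """Pick the number of patterns at the elbow of the within-distance curve.

    Fits k-medoids for each k, then takes the interior k maximising the
    discrete second difference W(k-1) - 2 W(k) + W(k+1); ties go to the
    smaller k.  A perfectly straight curve has no elbow and returns the
    smallest interior k with a warning.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values "
                         "(second difference undefined otherwise)")
    if len(windows) < max(ks):
        raise ValueError("need at least max(k_range) windows")
    D = distance_matrix
    if D is None:
        D = dtw_distance_matrix([w.values for w in windows], dtw)
    W = {}
    for k in ks:
        model = cluster_windows(windows, k, dtw, seed=seed, restarts=restarts,
                                distance_matrix=D)
        W[k] = model.total_within_distance
    curve = pd.DataFrame({"k": ks, "total_within_distance": [W[k] for k in ks]})
    interior = ks[1:-1]
    sec = np.array([W[k - 1] - 2 * W[k] + W[k + 1] for k in interior])
    if np.allclose(sec, 0.0, atol=1e-12):
        warnings.warn("within-distance curve is flat/linear: no elbow; "
                      "returning the smallest interior k")
        return interior[0], curve
    k_star = interior[int(np.argmax(sec))]
    return k_star, curve


def assign_windows(model: PatternModel, windows: list[Window]) -> np.ndarray:
    """Label each window with its nearest medoid (1..k); ties take the
    lowest pattern label."""
    labels = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        dists = np.array([dtw_distance(w.values, m, model.dtw)
                          for m in model.medoids])
        labels[i] = int(np.argmin(dists)) + 1
    return labels


# ---------------------------------------------------------------------------
# Per-pattern envelopes (band summaries)
# ---------------------------------------------------------------------------

TIR_BREAKPOINTS = (3.0, 3.9, 10.0, 13.9)


def pattern_range_summary(model: PatternModel, windows: list[Window],
                          labels: np.ndarray | None = None,
                          percentiles: tuple[float, float] = (20.0, 80.0),
                          grid_step: int = 15) -> pd.DataFrame:
    """Pointwise percentile envelopes and median trend per pattern.

    Windows are mapped to a common offset grid (``grid_step``-minute steps
    from 0 to duration - step) by nearest-offset sample; the lower/upper
    band is the pointwise 20th/80th percentile (linear-interpolation
    percentile) over the windows assigned to each pattern.  The returned
    frame also reports which glucose bands delimited by the standard
    time-in-range breakpoints (3, 3.9, 10, 13.9 mmol/L) the envelope spans.
    """
    if labels is None:
        labels = model.labels
    labels = np.asarray(labels)
    if len(labels) != len(windows):
        raise ValueError("labels and windows must be parallel")
    duration = model.windowing.duration
    grid = np.arange(0, duration, grid_step, dtype=float)
    lo_p, hi_p = percentiles
    rows = []
    for p in range(1, model.k + 1):
        idx = np.flatnonzero(labels == p)
        if idx.size == 0:
            warnings.warn(f"pattern {p} has no assigned windows; band omitted")
            continue
        mat = np.empty((idx.size, grid.size))
        for r, wi in enumerate(idx):
            w = windows[wi]
            nearest = np.abs(w.offsets[None, :] - grid[:, None]).argmin(axis=1)
            mat[r] = w.values[nearest]
        lower = np.percentile(mat, lo_p, axis=0)
        median = np.percentile(mat, 50, axis=0)
        upper = np.percentile(mat, hi_p, axis=0)
        env_lo, env_hi = float(lower.min()), float(upper.max())
        edges = (0.0,) + TIR_BREAKPOINTS + (np.inf,)
        band_names = ["<=3", "3-3.9", "3.9-10", "10-13.9", ">=13.9"]
        spanned = [name for name, a, b in
                   zip(band_names, edges[:-1], edges[1:])
                   if env_lo < b and env_hi > a]
        for g, l, m, u in zip(grid, lower, median, upper):
            rows.append({"pattern": p, "offset": g, "lower": l,
                         "median": m, "upper": u,
                         "n_windows": idx.size,
                         "bands_spanned": "|".join(spanned)})
    return pd.DataFrame(rows)
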