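"""Patient clustering on time-in-patterns compositions and group statistics.

Compositions (percentages summing to 100) are compared with a distance suited
to percentage data — Hellinger by default, with Bray-Curtis, Aitchison and
plain Euclidean selectable — then clustered agglomeratively with complete
linkage.  The dendrogram is cut at the largest gap between successive merge
heights.  Clinical variables are compared across the resulting clusters with
one-way ANOVA (numeric) and Pearson chi-square without continuity correction
(categorical), omitting missing values per variable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, chi2_contingency

from .errors import DegenerateDataError

P_SIGNIFICANT = 0.05


def percentage_distance(p, q, method: str = "hellinger") -> float:
    """Distance between two percentage compositions (each sums to 100).

    hellinger: (1/sqrt(2))·||sqrt(p/100) - sqrt(q/100)||_2, bounded in [0,1]
    and tolerant of zero shares.  bray_curtis: sum|p-q| / sum(p+q).
    aitchison: Euclidean distance between centred log-ratio transforms after
    multiplicative zero replacement (delta = 0.5 · smallest positive share).
    euclidean: plain L2 on the percentage vectors.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("compositions must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("compositions must be nonnegative")
    for v in (p, q):
        if abs(v.sum() - 100.0) > 1e-6:
            raise ValueError("each composition must sum to 100")
    if method == "hellinger":
        return float(np.linalg.norm(np.sqrt(p / 100) - np.sqrt(q / 100))
                     / np.sqrt(2))
    if method == "bray_curtis":
        return float(np.abs(p - q).sum() / (p + q).sum())
    if method == "aitchison":
        return float(np.linalg.norm(_clr(p / 100) - _clr(q / 100)))
    if method == "euclidean":
        return float(np.linalg.norm(p - q))
    raise ValueError(f"unknown method: {method!r}")


def _clr(x: np.ndarray) -> np.ndarray:
    """Centred log-ratio with multiplicative zero replacement."""
    x = x.copy()
    if np.any(x == 0):
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError("composition is all zeros")
        delta = 0.5 * pos.min()
        nz = np.count_nonzero(x == 0)
        x[x == 0] = delta
        x[x > delta] *= (1 - nz * delta)  # renormalise the nonzero mass
        x /= x.sum()
    lx = np.log(x)
    return lx - lx.mean()


@dataclass
class CohortResult:
    """Patient cluster labels, the linkage tree, and the statistics table."""

    patient_ids: list[str]
    cluster_labels: np.ndarray
    linkage_matrix: np.ndarray
    distance_name: str
    stats_table: pd.DataFrame | None = None

    def save_labels_csv(self, path) -> None:
        pd.DataFrame({"patient_id": self.patient_ids,
                      "cluster": self.cluster_labels}).to_csv(path, index=False)

    def save_linkage_json(self, path) -> None:
        Z = self.linkage_matrix
        Path(path).write_text(json.dumps({
            "distance": self.distance_name,
            "children": Z[:, :2].astype(int).tolist(),
            "heights": Z[:, 2].tolist(),
            "sizes": Z[:, 3].astype(int).tolist(),
        }, indent=2))


def composition_distance_matrix(compositions,
                                method: str = "hellinger") -> np.ndarray:
    comps = [np.asarray(c, dtype=float) for c in compositions]
    n = len(comps)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = percentage_distance(comps[i], comps[j], method)
    return D


def hcluster_patients(compositions, method: str = "hellinger") -> np.ndarray:
    """Complete-linkage agglomeration on the chosen percentage distance.

    Returns a scipy linkage matrix; complete linkage guarantees
    non-decreasing merge heights (no inversions).
    """
    if len(compositions) < 2:
        raise ValueError("need at least 2 patients")
    D = composition_distance_matrix(compositions, method)
    return linkage(squareform(D, checks=False), method="complete")


def cut_by_largest_gap(Z: np.ndarray, min_clusters: int = 2,
                       max_clusters: int = 10,
                       D: np.ndarray | None = None,
                       criterion: str = "within") -> np.ndarray:
    """Cut the dendrogram at the greatest jump, cluster count constrained to
    [min_clusters, max_clusters]; ties prefer fewer clusters.

    Two criteria:

    - ``"within"`` (default): each merge increases the total within-cluster
      distance by the sum of the cross pairwise distances it fuses; the cut
      is placed just before the merge with the greatest *relative* increase
      (its jump divided by the preceding merge's jump), considering only
      merges whose jump is at least the mean jump.  The relative form keeps
      the criterion from always selecting the final, largest-by-size merge
      on a convexly increasing curve, and the mean-jump guard ignores
      spurious ratios between two near-zero early merges.  Requires the
      original distance matrix ``D``.
    - ``"height"``: cut where the gap between successive merge heights is
      maximal.

    Returns labels 1..m ordered by decreasing cluster size.
    """
    n = Z.shape[0] + 1
    heights = Z[:, 2]
    max_clusters = min(max_clusters, n)
    if min_clusters > max_clusters:
        raise DegenerateDataError(
            f"cannot cut into [{min_clusters}, {max_clusters}] clusters; "
            f"heights={heights.tolist()}")
    if criterion == "within":
        if D is None:
            raise ValueError("criterion='within' needs the distance matrix D")
        jumps = _merge_within_jumps(Z, D)
        mean_jump = jumps.mean()
        # cutting just before merge i (0-based) leaves n - i clusters
        candidates = [(n - i, jumps[i] / jumps[i - 1])
                      for i in range(1, n - 1)
                      if min_clusters <= n - i <= max_clusters
                      and jumps[i] >= mean_jump and jumps[i - 1] > 0]
    elif criterion == "height":
        # cutting between merges i and i+1 leaves n - 1 - i clusters
        candidates = [(n - 1 - i, heights[i + 1] - heights[i])
                      for i in range(n - 2)
                      if min_clusters <= n - 1 - i <= max_clusters]
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    if not candidates:
        best_m = min(max(min_clusters, 2), max_clusters)
    else:
        best_gap = max(g for _, g in candidates)
        best_m = min(m for m, g in candidates if g >= best_gap - 1e-15)
        if best_gap <= 1e-15:
            warnings.warn("all gaps equal; returning min_clusters")
            best_m = min_clusters
    return _relabel_by_size(_labels_after_merges(Z, best_m))


def _labels_after_merges(Z: np.ndarray, m: int) -> np.ndarray:
    """Replay the first n - m merges of the agglomeration sequence.

    Unlike ``fcluster(..., criterion="maxclust")`` this yields exactly m
    clusters even when tied merge heights make a height threshold unable to
    separate them."""
    n = Z.shape[0] + 1
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - m):
        a, b = find(int(Z[i, 0])), find(int(Z[i, 1]))
        parent[a] = parent[b] = n + i
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots) + 1)
    return labels


def _merge_within_jumps(Z: np.ndarray, D: np.ndarray) -> np.ndarray:
    """For each merge, the total within-cluster distance it adds: the sum of
    pairwise distances between the two fused clusters' members."""
    n = Z.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    jumps = np.empty(n - 1)
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        la, lb = members.pop(a), members.pop(b)
        jumps[i] = D[np.ix_(la, lb)].sum()
        members[n + i] = la + lb
    return jumps


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..m by decreasing size (ties by first appearance)."""
    uniq, counts = np.unique(raw, return_counts=True)
    first = {u: int(np.argmax(raw == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in raw])


def compare_clusters(clinical: pd.DataFrame,
                     labels: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Per-variable tests across patient clusters.

    One-way ANOVA F-test for numeric columns, Pearson chi-square (no
    continuity correction) on the cluster-by-category table for categorical
    ones.  Rows missing a variable are omitted from that variable's test
    only; two-tailed p-values; a ``significant`` flag marks p < 0.05.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) \
        else labels
    df = clinical.copy()
    matched = df["patient_id"].isin(labels.index)
    if (~matched).any():
        warnings.warn(f"{int((~matched).sum())} patients without cluster "
                      "labels dropped from comparison")
        df = df[matched]
    df = df.assign(_cluster=df["patient_id"].map(labels))

    rows = []
    for col in clinical.columns:
        if col == "patient_id":
            continue
        sub = df[[col, "_cluster"]].dropna(subset=[col])
        n_missing = len(df) - len(sub)
        # numeric columns get ANOVA, except two-level (binary) flags which
        # are contingency-table material like any other categorical
        numeric = pd.api.types.is_numeric_dtype(clinical[col]) and \
            clinical[col].dropna().nunique() != 2
        row = {"variable": col, "n_missing_omitted": n_missing,
               "statistic": np.nan, "p_value": np.nan, "significant": False}
        if numeric:
            row["test"] = "anova"
            groups = [g[col].to_numpy(dtype=float)
                      for _, g in sub.groupby("_cluster")]
            pooled = np.concatenate(groups) if groups else np.array([])
            if len(groups) < 2 or pooled.size - len(groups) < 1:
                row["skip_reason"] = "insufficient degrees of freedom"
            elif np.all(pooled == pooled[0]):
                row["skip_reason"] = "zero variance"
            else:
                stat, p = f_oneway(*groups)
                row.update(statistic=float(stat), p_value=float(p),
                           significant=bool(p < P_SIGNIFICANT))
        else:
            row["test"] = "chi_square"
            table = pd.crosstab(sub["_cluster"], sub[col])
            table = table.loc[:, table.sum(axis=0) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                row["skip_reason"] = "constant within/across clusters"
            else:
                res = chi2_contingency(table.to_numpy(), correction=False)
                if (res.expected_freq < 5).any():
                    warnings.warn(f"{col}: expected cell counts < 5; "
                                  "chi-square approximation may be poor")
                row.update(statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           significant=bool(res.pvalue < P_SIGNIFICANT),
                           df=int(res.dof))
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(clinical: pd.DataFrame, by: str,
                  n_groups: int = 3) -> pd.DataFrame:
    """Split patients into ``n_groups`` approximately equal-sized groups by a
    numeric column (e.g. duration of CGM use) and compare the remaining
    variables across those groups."""
    col = clinical[by]
    if not pd.api.types.is_numeric_dtype(col):
        raise ValueError(f"{by!r} must be numeric")
    valid = clinical.dropna(subset=[by])
    groups = pd.qcut(valid[by], q=n_groups, labels=False, duplicates="drop") + 1
    labels = pd.Series(groups.to_numpy(), index=valid["patient_id"])
    rest = clinical.drop(columns=[by])
    return compare_clusters(rest, labels)


def cluster_patients(tips, method: str = "hellinger",
                     min_clusters: int = 2, max_clusters: int = 10,
                     criterion: str = "within") -> CohortResult:
    """End-to-end patient clustering from TimeInPatterns objects."""
    pids = [t.patient_id for t in tips]
    comps = [t.composition for t in tips]
    D = composition_distance_matrix(comps, method)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = cut_by_largest_gap(Z, min_clusters, max_clusters, D=D,
                                criterion=criterion)
    return CohortResult(pids, labels, Z, method)
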