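"""Recurring connectivity states from window-resolved directed matrices.

Each window's directed connectivity matrix (off-diagonal entries,
vectorized in a canonical pair order) is one sample; samples pooled across
scans are clustered with k-means (Lloyd's algorithm, Euclidean distance,
several seeded initializations per k).  The number of states is chosen on
the within-cluster sum of squares (WCSS) curve by a deterministic elbow
rule, and state labels from two solutions (e.g. two modalities) are
aligned by the centroid permutation maximizing total Pearson correlation.

Features are used as-is (no per-column scaling): windowed capacity or
correlation matrices are already on a common scale across pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "WindowFeatureSet",
    "StateSolution",
    "CentroidAlignment",
    "features_from_frames",
    "fit_states",
    "align_centroids",
    "state_timecourse_correlation",
]


@dataclass
class WindowFeatureSet:
    """Pooled window-by-feature matrix (one row per window, one column per
    directed off-diagonal ROI pair)."""

    features: np.ndarray
    window_meta: pd.DataFrame | None = None
    roi_pair_order: list[tuple[str, str]] | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (windows x pairs)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("windows with missing measures must be dropped before pooling")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


def features_from_frames(
    frames: list[pd.DataFrame], measure: str = "capacity"
) -> WindowFeatureSet:
    """Pool long-format per-scan result tables into a window-feature set.

    Windows where any directed pair is missing (NaN) are dropped and
    counted in the returned metadata.
    """
    rows, metas = [], []
    pair_order: list[tuple[str, str]] | None = None
    for frame in frames:
        wide = frame.pivot_table(
            index="window_index", columns=["sender", "receiver"],
            values=measure, sort=True,
        )
        if pair_order is None:
            pair_order = list(wide.columns)
        wide = wide[pair_order]
        keep = wide.dropna()
        scan = frame["scan_id"].iloc[0]
        rows.append(keep.to_numpy())
        metas.append(pd.DataFrame({"scan_id": scan, "window_index": keep.index}))
    return WindowFeatureSet(
        features=np.concatenate(rows, axis=0),
        window_meta=pd.concat(metas, ignore_index=True),
        roi_pair_order=pair_order,
    )


@dataclass
class StateSolution:
    """k-means state solution with its WCSS curve over candidate k."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    k_candidates: np.ndarray
    wcss_curve: np.ndarray
    chosen_by: str


def _elbow(ks: np.ndarray, wcss: np.ndarray, flatness_threshold: float = 0.2) -> int:
    """Deterministic elbow: maximum second difference of the WCSS curve
    after normalizing both axes to [0, 1]; ties toward smaller k.

    If the whole curve is nearly flat (total relative WCSS drop below
    ``flatness_threshold``), there is no meaningful cluster structure and
    the smallest candidate k is returned.
    """
    if ks.size == 1:
        return int(ks[0])
    w0 = wcss[0]
    if w0 <= 0 or (w0 - wcss.min()) / w0 < flatness_threshold:
        return int(ks[0])
    if ks.size == 2:
        return int(ks[1])
    xn = (ks - ks[0]) / (ks[-1] - ks[0])
    span = wcss.max() - wcss.min()
    yn = (wcss - wcss.min()) / span if span > 0 else np.zeros_like(wcss)
    d2 = yn[:-2] - 2 * yn[1:-1] + yn[2:]
    best = int(np.argmax(d2))  # first occurrence wins -> smaller k on ties
    return int(ks[1 + best])


def fit_states(
    features: WindowFeatureSet | np.ndarray,
    k_range=range(1, 11),
    n_init: int = 6,
    seed: int = 0,
    flatness_threshold: float = 0.2,
) -> StateSolution:
    """k-means over candidate k with elbow selection.

    For each k, Lloyd's k-means is run ``n_init`` times from distinct
    seeded initializations and the lowest-WCSS run is kept; the returned
    solution is the one at the elbow of the WCSS curve.  Identical seeds
    yield identical labels.
    """
    X = features.features if isinstance(features, WindowFeatureSet) else np.asarray(features, float)
    ks = np.asarray(sorted(set(int(k) for k in k_range)))
    if ks.size == 0 or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    W = X.shape[0]
    if ks[-1] > W:
        raise ValueError(f"k={ks[-1]} exceeds the number of windows W={W}")
    if W < 2 * ks[-1]:
        raise ValueError("need at least 2 windows per candidate state")
    wcss = np.empty(ks.size)
    solutions = {}
    for i, k in enumerate(ks):
        km = KMeans(
            n_clusters=int(k), n_init=n_init, random_state=seed, algorithm="lloyd"
        ).fit(X)
        wcss[i] = km.inertia_
        solutions[int(k)] = (km.cluster_centers_, km.labels_)
    # WCSS must be non-increasing in k; multi-start Lloyd can violate this
    # only by tiny numerical slack.
    assert np.all(np.diff(wcss) <= 1e-8 * max(wcss[0], 1.0)), "WCSS curve not non-increasing"
    k_star = _elbow(ks, wcss, flatness_threshold)
    centroids, labels = solutions[k_star]
    return StateSolution(
        k=k_star,
        centroids=centroids,
        labels=labels,
        k_candidates=ks,
        wcss_curve=wcss,
        chosen_by="wcss-elbow-second-difference",
    )


@dataclass
class CentroidAlignment:
    """Permutation aligning another solution's states to a reference."""

    permutation: tuple[int, ...]  # reference state i <-> other state permutation[i]
    pair_correlations: np.ndarray
    total_correlation: float

    def relabel(self, labels: np.ndarray) -> np.ndarray:
        """Relabel the other solution's label sequence into reference ids."""
        mapping = np.empty(len(self.permutation), dtype=int)
        for ref_i, other_j in enumerate(self.permutation):
            mapping[other_j] = ref_i
        return mapping[np.asarray(labels, int)]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    denom = math.sqrt(float(uc @ uc) * float(vc @ vc))
    if denom == 0.0:
        return 0.0
    return float(uc @ vc) / denom


def align_centroids(reference: StateSolution, other: StateSolution) -> CentroidAlignment:
    """Exhaustive permutation alignment of two k-state solutions.

    Searches all k! pairings and maximizes the total Pearson correlation
    between matched centroid vectors.  Guarded at k > 8 where the
    factorial search becomes unreasonable.
    """
    if reference.k != other.k:
        raise ValueError("solutions must share k")
    if reference.centroids.shape[1] != other.centroids.shape[1]:
        raise ValueError("solutions must share the feature dimension")
    k = reference.k
    if k > 8:
        raise ValueError("permutation alignment guarded at k <= 8")
    corr = np.array(
        [
            [_pearson(reference.centroids[i], other.centroids[j]) for j in range(k)]
            for i in range(k)
        ]
    )
    best_perm, best_total = None, -math.inf
    for perm in itertools.permutations(range(k)):
        total = sum(corr[i, perm[i]] for i in range(k))
        if total > best_total:
            best_perm, best_total = perm, total
    pair_corrs = np.array([corr[i, best_perm[i]] for i in range(k)])
    return CentroidAlignment(
        permutation=best_perm,
        pair_correlations=pair_corrs,
        total_correlation=float(best_total),
    )


def state_timecourse_correlation(labels_a, labels_b) -> float:
    """Pearson correlation of two aligned state-label time courses.

    Labels are treated as numeric series; a constant sequence has no
    defined correlation and returns NaN.
    """
    a = np.asarray(labels_a, float)
    b = np.asarray(labels_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D of equal length")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return math.nan
    return _pearson(a, b)
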