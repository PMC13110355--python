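"""Permutation inference on gaze behavior.

Two tests are provided, both controlling multiplicity through the
max-statistic construction:

* ``cluster_permutation`` — cluster-based permutation test on
  reversal-aligned gaze time courses.  Per-sample paired t-values between
  the two percept conditions are thresholded (two-sided pointwise t at
  ``alpha_cf``), contiguous suprathreshold runs of consistent sign form
  clusters, and each cluster's mass is its summed t.  The observed
  strongest cluster is compared against the permutation distribution of
  strongest clusters obtained by flipping the condition assignment within
  participant (sign flips of the difference time courses).

* ``gaze_label_permutation`` — label-permutation test on fixation
  positions, either the Euclidean distance between condition centroids or
  the absolute difference of mean distances to a diagnostic region.

p-values use the (b + 1)/(B + 1) convention so p is never exactly zero;
critical values (t_crit, delta_gaze_crit) are the 95th percentile of the
permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AlignedTimecourses", "ClusterResult", "GazePermResult",
           "cluster_permutation", "gaze_label_permutation",
           "align_to_reversals", "distance_to_region"]


@dataclass(frozen=True)
class AlignedTimecourses:
    """Participant x time matrices per condition on a common time axis.

    ``times`` is in ms relative to the perceptual reversal (0 = report
    flip).  ``cond_a`` and ``cond_b`` are the within-participant average
    gaze-distance time courses under the two percepts; the participant is
    the exchangeable unit of the permutation test.
    """

    times: np.ndarray
    cond_a: np.ndarray
    cond_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "cond_a", np.atleast_2d(np.asarray(self.cond_a, float)))
        object.__setattr__(self, "cond_b", np.atleast_2d(np.asarray(self.cond_b, float)))
        if self.cond_a.shape != self.cond_b.shape:
            raise ValueError("condition matrices must have identical shapes")
        if self.cond_a.shape[1] != self.times.size:
            raise ValueError("time axis does not match matrix width")
        if self.cond_a.shape[0] < 2:
            raise ValueError("need >= 2 participants")


@dataclass(frozen=True)
class ClusterResult:
    t_sum: float
    t_crit: float
    p: float
    window: tuple[float, float] | None    # ms; None when no cluster formed
    n_perm: int
    cluster_threshold: float              # pointwise |t| threshold used


@dataclass(frozen=True)
class GazePermResult:
    delta_gaze: float
    delta_gaze_crit: float
    p: float
    statistic: str
    n_perm: int


def _paired_t_rows(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Paired t per time point for every sign-flip row, vectorized.

    signs: (P, n) in {-1, +1}; diffs: (n, T).  Sign flips leave the squared
    values unchanged, so only the means move.
    """
    n = diffs.shape[0]
    means = signs @ diffs / n                       # (P, T)
    sumsq = np.sum(diffs ** 2, axis=0)              # (T,)
    var = (sumsq - n * means ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def _max_cluster_mass(tvals: np.ndarray, thr: float) -> np.ndarray:
    """|mass| of the strongest sign-consistent cluster per row, vectorized.

    A cluster is a contiguous run of samples whose t exceeds ``thr`` with a
    common sign; its mass is the summed t over the run.  Implemented with a
    cumulative-sum-with-reset trick so no Python loop over rows is needed.
    """
    tvals = np.atleast_2d(tvals)

    def one_sided(v: np.ndarray) -> np.ndarray:
        m = v > thr
        vm = np.where(m, v, 0.0)
        cs = np.cumsum(vm, axis=1)
        # cumulative sum frozen at the last sub-threshold sample = run baseline
        base = np.maximum.accumulate(np.where(m, -np.inf, cs), axis=1)
        base = np.where(np.isneginf(base), 0.0, base)
        run = np.where(m, cs - base, 0.0)
        return run.max(axis=1)

    return np.maximum(one_sided(tvals), one_sided(-tvals))


def _observed_clusters(t: np.ndarray, times: np.ndarray, thr: float):
    """List of (mass, (start_ms, end_ms)) for sign-consistent clusters."""
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[splits + 1]))
        ends = np.concatenate((idx[splits], [idx[-1]]))
        for a, b in zip(starts, ends):
            clusters.append((float(np.sum(t[a:b + 1])),
                             (float(times[a]), float(times[b]))))
    return clusters


def cluster_permutation(tc: AlignedTimecourses, n_perm: int = 1000,
                        alpha_cf: float = 0.05,
                        seed: int | np.random.Generator = 0) -> ClusterResult:
    """Cluster-based permutation test on paired condition time courses."""
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    diffs = tc.cond_a - tc.cond_b
    n, T = diffs.shape
    thr = float(stats.t.ppf(1 - alpha_cf / 2, n - 1))
    t_obs = _paired_t_rows(np.ones((1, n)), diffs)[0]
    clusters = _observed_clusters(t_obs, tc.times, thr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm_t = _paired_t_rows(signs.astype(float), diffs)
    perm_max = _max_cluster_mass(perm_t, thr)
    t_crit = float(np.percentile(perm_max, 95))
    if not clusters:
        return ClusterResult(t_sum=0.0, t_crit=t_crit, p=1.0, window=None,
                             n_perm=n_perm, cluster_threshold=thr)
    mass, window = max(clusters, key=lambda c: abs(c[0]))
    b = int(np.sum(perm_max >= abs(mass)))
    return ClusterResult(t_sum=float(mass), t_crit=t_crit,
                         p=(b + 1) / (n_perm + 1), window=window,
                         n_perm=n_perm, cluster_threshold=thr)


def gaze_label_permutation(points_a: np.ndarray, points_b: np.ndarray,
                           statistic: str = "centroid_distance",
                           region_point: tuple[float, float] | None = None,
                           n_perm: int = 1000,
                           seed: int | np.random.Generator = 0) -> GazePermResult:
    """Within-participant label-permutation test on paired gaze positions.

    ``points_a``/``points_b``: (n, 2) mean gaze positions per participant
    under the two intended percepts.  Statistics:

    * ``centroid_distance`` — Euclidean distance between the two condition
      mean positions;
    * ``mean_region_distance_diff`` — |difference of the mean distances to
      ``region_point``| (required for this variant).
    """
    a = np.atleast_2d(np.asarray(points_a, float))
    b = np.atleast_2d(np.asarray(points_b, float))
    if a.shape != b.shape or a.shape[0] < 2 or a.shape[1] != 2:
        raise ValueError("need matching (n>=2, 2) point arrays")
    n = a.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = (rng.integers(0, 2, size=(n_perm, n)) * 2 - 1).astype(float)

    if statistic == "centroid_distance":
        d = a - b                                   # (n, 2)
        obs = float(np.hypot(*d.mean(axis=0)))
        perm_means = signs @ d / n                  # (P, 2)
        perm = np.hypot(perm_means[:, 0], perm_means[:, 1])
    elif statistic == "mean_region_distance_diff":
        if region_point is None:
            raise ValueError("region_point required for mean_region_distance_diff")
        rx, ry = region_point
        da = np.hypot(a[:, 0] - rx, a[:, 1] - ry)
        db = np.hypot(b[:, 0] - rx, b[:, 1] - ry)
        diff = da - db
        obs = float(abs(diff.mean()))
        perm = np.abs(signs @ diff / n)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    crit = float(np.percentile(perm, 95))
    if obs == 0.0:
        return GazePermResult(delta_gaze=0.0, delta_gaze_crit=crit, p=1.0,
                              statistic=statistic, n_perm=n_perm)
    cnt = int(np.sum(perm >= obs))
    return GazePermResult(delta_gaze=obs, delta_gaze_crit=crit,
                          p=(cnt + 1) / (n_perm + 1), statistic=statistic,
                          n_perm=n_perm)


def distance_to_region(trace, region_point: tuple[float, float]) -> np.ndarray:
    """Per-sample Euclidean gaze distance (deg) to a diagnostic image point."""
    rx, ry = region_point
    if not (np.isfinite(rx) and np.isfinite(ry)):
        raise ValueError("region point must be finite")
    return np.hypot(trace.x - rx, trace.y - ry)


def align_to_reversals(times: np.ndarray, series: np.ndarray,
                       reversal_times: np.ndarray,
                       window: tuple[float, float] = (-1000.0, 1000.0),
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Slice a distance series around each reversal.

    Returns ``(rel_times, matrix, n_dropped)``: one row per reversal on a
    common axis ``rel_times`` (ms relative to the reversal); reversals whose
    window would extend past the recording edges are dropped and counted.
    Rows are later averaged within participant before the group-level test.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    if times.size != series.size:
        raise ValueError("times and series must have equal length")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    n_pre = int(round(-window[0] / dt))
    n_post = int(round(window[1] / dt))
    rel = np.arange(-n_pre, n_post + 1) * dt
    rows, dropped = [], 0
    for rt in np.asarray(reversal_times, float):
        c = int(round((rt - times[0]) / dt))
        if c - n_pre < 0 or c + n_post >= times.size:
            dropped += 1
            continue
        rows.append(series[c - n_pre: c + n_post + 1])
    mat = np.asarray(rows) if rows else np.empty((0, rel.size))
    return rel, mat, dropped
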