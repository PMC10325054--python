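"""Whisker-tip kinematics under airflow.

The central statistic is the per-frame tip displacement: the Euclidean
distance of the tracked tip from its coordinate-wise median position,

    d_t = sqrt((X - x_t)^2 + (Y - y_t)^2),

where (X, Y) = (median x, median y).  On an anesthetized (static) head
this isolates wind-driven jitter from the resting position.  The module
also provides per-whisker summaries and rank order, Kruskal-Wallis
comparison across whiskers with Tukey or Dunn post hoc, high/low wind
displacement ratios with a signed-rank test against 1, ex vivo bending
angles measured at a fraction of the whisker arc length, and rise-time
characterization of the wind stimulus itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stats import dunn_posthoc, signed_rank_test, RankTestResult


@dataclass
class WhiskerTrajectory:
    """2-D tip time series of one whisker at a fixed frame rate."""

    whisker_id: str
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 100.0
    likelihood: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D and equally long")
        if self.x.size < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.likelihood is not None:
            self.likelihood = np.asarray(self.likelihood, dtype=float)
            if self.likelihood.shape != self.x.shape:
                raise ValueError("likelihood must match trajectory length")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class DisplacementSeries:
    """Per-frame tip distance from the median position (units preserved)."""

    whisker_id: str
    d: np.ndarray
    median_x: float
    median_y: float


@dataclass
class WhiskerShape:
    """Planar whisker polyline, ordered from base to tip (mm)."""

    whisker_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("shape needs at least 2 points")
        if self.arc_length() <= 0:
            raise ValueError("degenerate shape: zero arc length")

    def arc_length(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def point_at_fraction(self, fraction: float) -> np.ndarray:
        """Point at ``fraction`` of total arc length, by linear
        interpolation along the polyline segments."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        seg = np.diff(self.points, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        target = fraction * cum[-1]
        i = int(np.searchsorted(cum, target, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        if seg_len[i] == 0:
            return self.points[i].copy()
        t = (target - cum[i]) / seg_len[i]
        return self.points[i] + t * seg[i]


@dataclass
class KruskalResult:
    H: float
    p: float
    df: int
    n_total: int
    posthoc: pd.DataFrame | None = None


def displacement_series(
    traj: WhiskerTrajectory,
    likelihood_threshold: float | None = None,
    calibration: float = 1.0,
) -> DisplacementSeries:
    """Tip displacement from the median position.

    ``likelihood_threshold`` optionally masks frames whose tracking
    likelihood falls below it (masked frames get NaN displacement and are
    excluded from the median).  ``calibration`` converts coordinate units
    (e.g. cm per pixel); default 1.0 is unit passthrough.
    """
    x = traj.x * calibration
    y = traj.y * calibration
    valid = np.ones(x.size, dtype=bool)
    if likelihood_threshold is not None and traj.likelihood is not None:
        valid = traj.likelihood >= likelihood_threshold
        if not valid.any():
            raise ValueError(
                f"no frames of {traj.whisker_id!r} pass likelihood threshold"
            )
    mx = float(np.median(x[valid]))
    my = float(np.median(y[valid]))
    d = np.hypot(x - mx, y - my)
    d[~valid] = np.nan
    return DisplacementSeries(
        whisker_id=traj.whisker_id, d=d, median_x=mx, median_y=my
    )


def summarize_displacement(
    series: Sequence[DisplacementSeries], mode: str = "mean_sem"
) -> pd.DataFrame:
    """Per-whisker displacement summary and rank order.

    ``mode`` selects the center/spread pair: "mean_sem" or "median_iqr".
    Rank 1 is the largest center.
    """
    if len(series) < 1:
        raise ValueError("need at least one displacement series")
    if mode not in ("mean_sem", "median_iqr"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for s in series:
        d = s.d[~np.isnan(s.d)]
        if mode == "mean_sem":
            center = float(d.mean())
            spread = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        else:
            center = float(np.median(d))
            q25, q75 = np.percentile(d, [25, 75])
            spread = float(q75 - q25)
        rows.append(
            {"whisker_id": s.whisker_id, "center": center, "spread": spread, "n": d.size}
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["center"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def compare_whiskers(
    groups: Mapping[str, np.ndarray], posthoc: str | None = "tukey"
) -> KruskalResult:
    """Kruskal-Wallis omnibus across whiskers on pooled per-frame values.

    ``posthoc`` is "tukey" (on the raw values, via statsmodels),
    "dunn" (rank-based, Bonferroni-adjusted), or None.  The pairwise
    result is a tidy DataFrame with columns group_a, group_b, p.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 whisker groups")
    arrays = {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        arrays[g] = v
    H, p = sps.kruskal(*arrays.values())
    n_total = sum(v.size for v in arrays.values())
    ph = None
    if posthoc == "tukey":
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[g] * v.size for g, v in arrays.items()])
        res = pairwise_tukeyhsd(values, labels)
        pairs = list(combinations(res.groupsunique, 2))
        ph = pd.DataFrame(
            {
                "group_a": [a for a, _ in pairs],
                "group_b": [b for _, b in pairs],
                "p": res.pvalues,
            }
        )
    elif posthoc == "dunn":
        pairs = dunn_posthoc(arrays)
        ph = pd.DataFrame(
            [{"group_a": a, "group_b": b, "p": pv} for (a, b), pv in pairs.items()]
        )
    elif posthoc is not None:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return KruskalResult(
        H=float(H), p=float(p), df=len(arrays) - 1, n_total=n_total, posthoc=ph
    )


def displacement_ratio(
    high: pd.DataFrame, low: pd.DataFrame
) -> tuple[pd.DataFrame, RankTestResult]:
    """Per-whisker high/low displacement ratio plus a two-sided
    signed-rank test of the ratios against 1.

    ``high`` and ``low`` are summary tables from
    :func:`summarize_displacement` over the same whisker set.
    """
    hs = high.set_index("whisker_id")["center"]
    ls = low.set_index("whisker_id")["center"]
    if set(hs.index) != set(ls.index):
        raise ValueError("high and low summaries must cover the same whiskers")
    ls = ls.reindex(hs.index)
    if (ls <= 0).any():
        bad = list(ls.index[ls <= 0])
        raise ValueError(f"zero or negative low-wind center for {bad}; ratio undefined")
    ratio = hs / ls
    table = pd.DataFrame({"whisker_id": ratio.index, "ratio": ratio.values})
    test = signed_rank_test(ratio.values - 1.0)
    return table, test


def bending_angle(
    rest: WhiskerShape,
    deflected: WhiskerShape,
    fraction: float = 0.75,
    base_tolerance: float = 1e-6,
) -> float:
    """Unsigned bending angle (degrees) at the whisker base.

    Locates the point at ``fraction`` of total arc length on each shape
    and returns the angle between the two base-to-point radii.  Both
    shapes must share the base point (within ``base_tolerance`` relative
    to the rest arc length).
    """
    base_r = rest.points[0]
    base_d = deflected.points[0]
    scale = max(rest.arc_length(), 1e-300)
    if np.hypot(*(base_r - base_d)) > base_tolerance * max(scale, 1.0):
        raise ValueError("shapes do not share a base point; register them first")
    u = rest.point_at_fraction(fraction) - base_r
    v = deflected.point_at_fraction(fraction) - base_d
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate radius: fraction point coincides with base")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def wind_rise_time(
    trace: np.ndarray,
    threshold_fraction: float,
    sample_rate: float = 100.0,
    steady_window: float | None = None,
) -> float | None:
    """Time (s) at which the wind trace first exceeds a fraction of its
    steady-state mean; None if the threshold is never reached.

    The steady state is the mean over the final ``steady_window`` seconds
    (default: the last half of the trace).  The crossing is refined by
    linear interpolation between the bracketing samples, so it is exact
    to within one sample period.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    n = trace.size
    if steady_window is None:
        tail = trace[n // 2 :]
    else:
        k = max(1, int(round(steady_window * sample_rate)))
        tail = trace[-k:]
    steady = float(tail.mean())
    thr = threshold_fraction * steady
    above = trace > thr
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    lo, hi = trace[i - 1], trace[i]
    frac = 0.0 if hi == lo else (thr - lo) / (hi - lo)
    return float((i - 1 + frac) / sample_rate)
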