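"""Whisker and follicle morphometrics.

Covers the length / base-diameter ratio, the ring-wulst aperture angle,
fold-change normalization against the long supra-orbital (lSO) whisker,
Pearson correlations, and a permutation test that asks whether a scalar
whisker property (ratio, aperture) is spatially structured on the pad:
for a candidate arrangement (arcs, rows, semicircles, oblique bands) the
statistic is the mean of within-group sample variances, and the null is
built by shuffling the assignment of values to pad positions.  A small
observed statistic relative to the shuffle null means the arrangement
captures real spatial structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layout import ArrangementScheme

#: n! limit below which the shuffle null is enumerated exactly.
EXACT_ENUMERATION_LIMIT = 362_880  # 9!


@dataclass
class MorphometryRecord:
    """Length (mm), base diameter (um) and ring-wulst aperture (deg) of
    one whisker sample; the ratio is derived, never stored."""

    whisker_id: str
    length: float
    base_diameter: float
    ring_wulst_aperture: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.whisker_id}: length must be positive")
        if self.base_diameter <= 0:
            raise ValueError(f"{self.whisker_id}: base diameter must be positive")
        if self.ring_wulst_aperture is not None and not (
            0 <= self.ring_wulst_aperture < 360
        ):
            raise ValueError(f"{self.whisker_id}: aperture must be in [0, 360)")

    @property
    def ratio(self) -> float:
        """Length / base-diameter ratio (mm per um)."""
        return self.length / self.base_diameter


def records_to_frame(records: Sequence[MorphometryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "whisker_id": [r.whisker_id for r in records],
            "length_mm": [r.length for r in records],
            "diameter_um": [r.base_diameter for r in records],
            "ratio": [r.ratio for r in records],
            "aperture_deg": [r.ring_wulst_aperture for r in records],
        }
    )


@dataclass
class ShuffleResult:
    """Outcome of the arrangement shuffle test."""

    arrangement: str
    observed: float
    null_distribution: np.ndarray
    p: float
    n_shuffles: int
    seed: int | None
    exact: bool = False


def mean_within_group_variance(
    values: Mapping[str, float], scheme: ArrangementScheme
) -> float:
    """Unweighted mean of per-group sample variances (ddof=1).

    Groups with fewer than two valued members are skipped (a singleton
    has no defined sample variance).
    """
    by_group: dict[str, list[float]] = {}
    for w, v in values.items():
        if w not in scheme.groups:
            raise KeyError(f"whisker {w!r} has no group in scheme {scheme.name!r}")
        by_group.setdefault(scheme.groups[w], []).append(float(v))
    variances = [
        np.var(g, ddof=1) for g in by_group.values() if len(g) >= 2
    ]
    if not variances:
        raise ValueError("no group with >= 2 valued members")
    return float(np.mean(variances))


def _group_matrix(
    whiskers: Sequence[str], scheme: ArrangementScheme
) -> list[np.ndarray]:
    """Index arrays of groups with >= 2 members among ``whiskers``."""
    by_group: dict[str, list[int]] = {}
    for i, w in enumerate(whiskers):
        by_group.setdefault(scheme.groups[w], []).append(i)
    idx = [np.asarray(v) for v in by_group.values() if len(v) >= 2]
    if not idx:
        raise ValueError("no group with >= 2 valued members")
    return idx


def _mean_group_var_matrix(perms: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Statistic for each row of a (n_perms, n_values) matrix."""
    acc = np.zeros(perms.shape[0])
    for idx in group_idx:
        acc += perms[:, idx].var(axis=1, ddof=1)
    return acc / len(group_idx)


def shuffle_arrangement_test(
    values: Mapping[str, float],
    scheme: ArrangementScheme,
    n_shuffles: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> ShuffleResult:
    """Permutation test of spatial structure under one arrangement.

    The null permutes the assignment of values to (valued) pad positions
    uniformly at random and recomputes the mean within-group variance.
    One-sided p (small = structured): with Monte-Carlo shuffles the
    add-one convention p = (1 + #{null <= observed}) / (1 + n_shuffles)
    is used; with ``exact=True`` (feasible for <= 9 valued positions) the
    null is the full assignment enumeration and p is the raw proportion.
    """
    if len(values) < 3:
        raise ValueError("need values for at least 3 whiskers")
    whiskers = list(values)
    vals = np.asarray([values[w] for w in whiskers], dtype=float)
    group_idx = _group_matrix(whiskers, scheme)
    observed = float(_mean_group_var_matrix(vals[None, :], group_idx)[0])
    tol = 1e-12 * max(1.0, abs(observed))
    if exact:
        n = vals.size
        if math.factorial(n) > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration infeasible for {n} positions"
            )
        null = np.array(
            [
                _mean_group_var_matrix(np.asarray(p, dtype=float)[None, :], group_idx)[0]
                for p in permutations(vals)
            ]
        )
        p = float((null <= observed + tol).mean())
        return ShuffleResult(
            arrangement=scheme.name,
            observed=observed,
            null_distribution=null,
            p=p,
            n_shuffles=null.size,
            seed=None,
            exact=True,
        )
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # one argsort per shuffle, vectorized
    perm_idx = np.argsort(rng.random((n_shuffles, vals.size)), axis=1)
    null = _mean_group_var_matrix(vals[perm_idx], group_idx)
    p = float((1 + (null <= observed + tol).sum()) / (1 + n_shuffles))
    return ShuffleResult(
        arrangement=scheme.name,
        observed=observed,
        null_distribution=null,
        p=p,
        n_shuffles=n_shuffles,
        seed=seed,
        exact=False,
    )


def select_optimal_arrangement(
    values: Mapping[str, float],
    schemes: Sequence[ArrangementScheme],
    n_shuffles: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ArrangementScheme, dict[str, ShuffleResult]]:
    """Run the shuffle test for every scheme; the arrangement with the
    least observed mean within-group variance is the optimal one.

    Ties in the observed statistic resolve to the earliest scheme in the
    declared order.
    """
    if len(schemes) < 2:
        raise ValueError("need at least 2 schemes to compare")
    if rng is None:
        rng = np.random.default_rng(seed)
    results = {
        s.name: shuffle_arrangement_test(values, s, n_shuffles=n_shuffles, rng=rng)
        for s in schemes
    }
    best = min(schemes, key=lambda s: (results[s.name].observed,))
    return best, results


def fold_change_vs_reference(
    values: Mapping[str, np.ndarray | float], reference: str = "lSO"
) -> dict[str, np.ndarray]:
    """Divide every whisker's values by the mean value of the reference
    whisker (default lSO)."""
    if reference not in values:
        raise KeyError(f"reference whisker {reference!r} has no values")
    ref = np.atleast_1d(np.asarray(values[reference], dtype=float))
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ValueError("reference mean is zero; fold change undefined")
    return {
        w: np.atleast_1d(np.asarray(v, dtype=float)) / ref_mean
        for w, v in values.items()
    }


def aperture_angle(ring_points: np.ndarray, shaft_center: np.ndarray) -> float:
    """Ring-wulst aperture: the largest angular gap (degrees) between
    consecutive ring points, seen from the hair-shaft center.

    A closed ring sampled densely gives a small aperture; a C-shaped
    (open) ring gives a large one.  Invariant under rotation about the
    center and under uniform scaling.
    """
    pts = np.asarray(ring_points, dtype=float)
    center = np.asarray(shaft_center, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("ring_points must be an (N, 2) array")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 ring points")
    rel = pts - center
    radii = np.hypot(rel[:, 0], rel[:, 1])
    if np.all(radii == 0):
        raise ValueError("all ring points coincide with the shaft center")
    rel = rel[radii > 0]
    ang = np.sort(np.arctan2(rel[:, 1], rel[:, 0]))
    gaps = np.diff(ang)
    wrap = 2 * np.pi - (ang[-1] - ang[0])
    return float(np.degrees(max(gaps.max(initial=0.0), wrap)))


def correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p on pairwise-complete pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
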