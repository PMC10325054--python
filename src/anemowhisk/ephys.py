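"""Cortical wind-response analysis.

Peri-stimulus spike counts are taken in 1-s bins spanning -4 to +4 s
around wind onset (half-open bins [t, t+1); the onset belongs to the
first post bin).  On top of those counts the module provides:

* z-scoring of the trial-averaged response against the 4 baseline bins;
* Poisson-GLM classification of each post-onset second as excited,
  inhibited or unresponsive relative to baseline (period-factor
  regression, baseline as reference level, per-coefficient Wald test);
* population response percentages per region, condition and second;
* response latency: the post-onset bin holding the z-score maximum,
  provided that maximum exceeds 2 SD;
* plug-in mutual information (bits) between the binary stimulus variable
  (wind of one condition vs no wind) and the discretized spike count,
  per post-onset second, normalized by a baseline bias floor; and a
  population signed-rank test of normalized information against 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as sps_chi2

from .stats import signed_rank_test

POST_SECONDS = (1, 2, 3, 4)


@dataclass
class UnitSpikeTrain:
    """Spike times (s, sorted ascending) of one sorted unit."""

    unit_id: str
    region: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.isnan(self.spike_times).any():
            raise ValueError(f"{self.unit_id}: NaN spike times")
        if (np.diff(self.spike_times) < 0).any():
            raise ValueError(f"{self.unit_id}: spike times must be sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError(f"{self.unit_id}: negative spike times")


@dataclass
class WindEpochSeries:
    """Wind-stimulus schedule: onsets (s), speeds (m/s; 0 = no wind) and
    the shared epoch duration."""

    onsets: np.ndarray
    speeds: np.ndarray
    duration: float = 10.0
    pre_window: float = 4.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.onsets.shape != self.speeds.shape:
            raise ValueError("onsets and speeds must align")
        order = np.argsort(self.onsets)
        self.onsets = self.onsets[order]
        self.speeds = self.speeds[order]
        starts = self.onsets - self.pre_window
        ends = self.onsets + self.duration
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("epochs overlap (including the pre-stimulus window)")

    def select(self, speed: float) -> "WindEpochSeries":
        mask = np.isclose(self.speeds, speed)
        if not mask.any():
            raise ValueError(f"no epochs at speed {speed}")
        return WindEpochSeries(
            onsets=self.onsets[mask],
            speeds=self.speeds[mask],
            duration=self.duration,
            pre_window=self.pre_window,
        )

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class BinnedResponse:
    """Per-epoch spike counts in 1-s bins around onset.

    ``counts`` has shape (n_epochs, n_bins); with the default window
    (-4, +4) there are 8 bins, the first 4 being baseline.
    """

    unit_id: str
    counts: np.ndarray
    window: tuple[float, float] = (-4.0, 4.0)
    bin_width: float = 1.0
    epoch_speeds: np.ndarray | None = None

    @property
    def n_baseline_bins(self) -> int:
        return int(round(-self.window[0] / self.bin_width))

    def baseline_counts(self) -> np.ndarray:
        return self.counts[:, : self.n_baseline_bins]

    def post_counts(self) -> np.ndarray:
        return self.counts[:, self.n_baseline_bins :]


@dataclass
class ZScoreResult:
    unit_id: str
    z: np.ndarray | None
    baseline_mean: float
    baseline_sd: float
    degenerate: bool
    n_baseline_bins: int = 4

    def post_z(self) -> np.ndarray:
        if self.z is None:
            raise ValueError("degenerate unit has no z-scores")
        return self.z[self.n_baseline_bins :]


@dataclass
class ResponseClassification:
    """Per post-onset-second label for one unit."""

    unit_id: str
    labels: dict[int, str]  # second -> excited | inhibited | none
    p_values: dict[int, float]
    alpha: float
    converged: bool = True


@dataclass
class MIResult:
    unit_id: str
    condition: str
    per_second_mi: np.ndarray  # bits, seconds 1-4
    baseline_mi: np.ndarray  # bits, one per baseline second
    normalized: np.ndarray | None  # per-second / mean baseline


def bin_spikes(
    unit: UnitSpikeTrain,
    epochs: WindEpochSeries,
    window: tuple[float, float] = (-4.0, 4.0),
    bin_width: float = 1.0,
) -> BinnedResponse:
    """Count spikes in half-open bins [t, t+bin) around each onset."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("invalid window")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.empty((len(epochs), n_bins), dtype=int)
    t = unit.spike_times
    for i, onset in enumerate(epochs.onsets):
        rel = t[(t >= onset + lo) & (t < onset + hi)] - onset
        # half-open [e, e+1): searchsorted with side='right' on left edges
        counts[i] = np.histogram(rel, bins=edges)[0]
    return BinnedResponse(
        unit_id=unit.unit_id,
        counts=counts,
        window=window,
        bin_width=bin_width,
        epoch_speeds=epochs.speeds.copy(),
    )


def zscore_response(binned: BinnedResponse) -> ZScoreResult:
    """z-score the trial-averaged per-bin counts against baseline bins.

    Baseline mean and SD are taken across the baseline bins' trial
    averages (ddof=1).  Silent or perfectly flat baselines are flagged
    degenerate instead of yielding infinite z.
    """
    nb = binned.n_baseline_bins
    if nb < 2:
        raise ValueError("need at least 2 baseline bins")
    avg = binned.counts.mean(axis=0)
    mu = float(avg[:nb].mean())
    sd = float(avg[:nb].std(ddof=1))
    if sd == 0:
        return ZScoreResult(
            binned.unit_id, None, mu, sd, degenerate=True, n_baseline_bins=nb
        )
    return ZScoreResult(
        binned.unit_id, (avg - mu) / sd, mu, sd, degenerate=False, n_baseline_bins=nb
    )


def classify_response_glm(
    binned: BinnedResponse, alpha: float = 0.05
) -> ResponseClassification:
    """Classify each post-onset second as excited / inhibited / none.

    Poisson regression of per-epoch per-bin counts on a 5-level period
    factor (baseline = reference; seconds 1-4), log link.  Each post
    second's coefficient gets a Wald test against baseline; when a post
    bin is entirely silent (complete separation, Wald degenerate) the
    test falls back to the likelihood-ratio test for that coefficient.
    """
    if binned.counts.shape[0] < 2:
        raise ValueError("need at least 2 epochs")
    nb = binned.n_baseline_bins
    n_post = binned.counts.shape[1] - nb
    y = binned.counts.reshape(-1)
    n_epochs = binned.counts.shape[0]
    period = np.tile(
        np.concatenate([np.zeros(nb, dtype=int), np.arange(1, n_post + 1)]), n_epochs
    )
    X = np.column_stack(
        [np.ones(y.size)] + [(period == k).astype(float) for k in range(1, n_post + 1)]
    )
    labels: dict[int, str] = {}
    pvals: dict[int, float] = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    except Exception:
        return ResponseClassification(
            binned.unit_id, {}, {}, alpha=alpha, converged=False
        )
    if not np.isfinite(fit.params).all():
        return ResponseClassification(
            binned.unit_id, {}, {}, alpha=alpha, converged=False
        )
    for k in range(1, n_post + 1):
        coef = fit.params[k]
        p = float(fit.pvalues[k])
        post_total = binned.counts[:, nb + k - 1].sum()
        if post_total == 0 and binned.baseline_counts().sum() > 0:
            # complete separation: the Wald SE explodes, so test the
            # coefficient by likelihood ratio.  With a free dummy for an
            # all-zero bin the full-model likelihood supremum is the fit
            # on the remaining rows (the zero bin contributes log 1 = 0).
            keep = period != k
            Xk = np.delete(X, k, axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sup = sm.GLM(
                    y[keep], Xk[keep], family=sm.families.Poisson()
                ).fit()
                red = sm.GLM(y, Xk, family=sm.families.Poisson()).fit()
            lr = 2.0 * (sup.llf - red.llf)
            p = float(sps_chi2.sf(max(lr, 0.0), df=1))
            coef = -np.inf  # an all-zero bin with active baseline is suppression
        pvals[k] = p
        if p < alpha:
            labels[k] = "excited" if coef > 0 else "inhibited"
        else:
            labels[k] = "none"
    return ResponseClassification(binned.unit_id, labels, pvals, alpha=alpha)


def response_percentages(
    classifications: Sequence[ResponseClassification],
    regions: Mapping[str, str],
) -> pd.DataFrame:
    """Percentage of units excited / inhibited per region and second.

    ``regions`` maps unit_id -> region label.  Units that failed to
    classify (non-convergence) are excluded from the denominator.
    """
    ok = [c for c in classifications if c.converged and c.labels]
    if not ok:
        raise ValueError("no classified units")
    rows = []
    by_region: dict[str, list[ResponseClassification]] = {}
    for c in ok:
        by_region.setdefault(regions[c.unit_id], []).append(c)
    for region, cls in by_region.items():
        n = len(cls)
        for sec in POST_SECONDS:
            exc = sum(c.labels.get(sec) == "excited" for c in cls)
            inh = sum(c.labels.get(sec) == "inhibited" for c in cls)
            rows.append(
                {
                    "region": region,
                    "second": sec,
                    "pct_excited": 100.0 * exc / n,
                    "pct_inhibited": 100.0 * inh / n,
                    "n_units": n,
                }
            )
    return pd.DataFrame(rows)


def response_latency(z: ZScoreResult, threshold: float = 2.0) -> int | None:
    """Latency bin (1-4) where the post-onset z-score peaks, if that peak
    exceeds ``threshold``; ties break to the earliest bin."""
    if z.degenerate:
        return None
    post = z.post_z()
    m = post.max()
    if m <= threshold:
        return None
    return int(np.argmax(post)) + 1


def mi_from_joint(table: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint count table.

    Rows index the response symbol r, columns the stimulus s.  Computed
    as sum_r sum_s P(r) P(s|r) log2(P(s|r) / P(s)); zero cells and empty
    rows contribute nothing.
    """
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("empty joint table")
    p_rs = t / total
    p_r = p_rs.sum(axis=1, keepdims=True)
    p_s = p_rs.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(p_r > 0, p_rs / p_r, 0.0)
        logterm = np.where(cond > 0, np.log2(cond / p_s), 0.0)
    return float(max(0.0, (p_r * cond * logterm).sum()))


def _mi_two_sample(a: np.ndarray, b: np.ndarray, cap: int) -> float:
    """MI between a binary class label and capped integer counts, from
    the two count samples ``a`` (class 1) and ``b`` (class 0)."""
    a = np.minimum(a, cap)
    b = np.minimum(b, cap)
    table = np.zeros((cap + 1, 2))
    np.add.at(table[:, 1], a, 1)
    np.add.at(table[:, 0], b, 1)
    return mi_from_joint(table)


def mutual_information(
    binned: BinnedResponse,
    condition: Literal["low", "high"],
    cap: int = 10,
) -> MIResult:
    """Per-second stimulus information of one unit under one condition.

    ``binned`` must hold epochs of a single wind speed.  For each
    post-onset second the stimulus variable is binary (wind of this
    condition vs no wind); the no-wind sample pools that unit's baseline
    bins.  Counts are capped at ``cap`` (tail pooled) to limit plug-in
    bias.  The baseline information values, computed per baseline second
    against the remaining baseline bins, estimate the estimator's bias
    floor and provide the normalizer.
    """
    if binned.counts.shape[0] < 2:
        raise ValueError("need at least 2 epochs")
    base = binned.baseline_counts()
    post = binned.post_counts()
    no_wind = base.reshape(-1)
    per_second = np.array(
        [_mi_two_sample(post[:, k], no_wind, cap) for k in range(post.shape[1])]
    )
    nb = base.shape[1]
    baseline_mi = np.array(
        [
            _mi_two_sample(
                base[:, b],
                base[:, [j for j in range(nb) if j != b]].reshape(-1),
                cap,
            )
            for b in range(nb)
        ]
    )
    floor = float(baseline_mi.mean())
    normalized = per_second / floor if floor > 0 else None
    return MIResult(
        unit_id=binned.unit_id,
        condition=condition,
        per_second_mi=per_second,
        baseline_mi=baseline_mi,
        normalized=normalized,
    )


def normalized_mi_test(
    mi_results: Sequence[MIResult], alpha_bonferroni: float = 0.003
) -> pd.DataFrame:
    """Two-tailed signed-rank test of normalized information against 1,
    per post-onset second, across units; significance at the
    Bonferroni-corrected alpha."""
    usable = [m for m in mi_results if m.normalized is not None]
    if len(usable) < 5:
        raise ValueError("need >= 5 units with defined normalized MI")
    rows = []
    for k in range(4):
        vals = np.array([m.normalized[k] for m in usable])
        res = signed_rank_test(vals - 1.0)
        rows.append(
            {
                "second": k + 1,
                "n_units": vals.size,
                "median_normalized_mi": float(np.median(vals)),
                "p": res.p,
                "significant": res.p < alpha_bonferroni,
            }
        )
    return pd.DataFrame(rows)
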