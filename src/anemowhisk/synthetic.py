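"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one recording modality of a wind-sensing study:

* whisker-tip trajectories: isotropic Gaussian jitter of each tip around
  a fixed base point (anesthetized head), with per-whisker, per-wind-speed
  amplitude — lSO strictly maximal at low wind by default;
* whisker/follicle morphometry: a hierarchical Gaussian model whose
  whisker-type level carries the configured length-diameter correlation,
  with the lSO ratio boosted to the pad maximum and the ring-wulst
  aperture anticorrelated with the ratio;
* spike trains: inhomogeneous-Poisson units per cortical region
  (excited / inhibited / unresponsive) whose rate is modulated by a
  per-second gain profile during wind epochs, on a balanced randomized
  schedule of low / high / no-wind blocks;
* behavior trials: multinomial toward/away/none draws per trial with
  treatment-dependent probabilities, balanced stimulus sides, and paired
  lidocaine/Ringer sessions per animal;
* wind traces: first-order exponential rise toward the mean speed plus
  white turbulence noise.

All generators are deterministic given (config, seed): pass an explicit
``rng`` to chain several generators off one stream, or omit it to derive
a fresh stream from ``cfg.seed``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .config import SimConfig
from .ephys import UnitSpikeTrain, WindEpochSeries
from .kinematics import WhiskerTrajectory
from .layout import default_layout
from .morphometrics import MorphometryRecord

#: pixels per grid unit when placing whisker base points
GRID_SCALE = 50.0


def _rng(cfg: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return cfg.rng() if rng is None else rng


def gen_whisker_trajectories(
    cfg: SimConfig,
    wind_speed: float,
    rng: np.random.Generator | None = None,
) -> list[WhiskerTrajectory]:
    """Tip trajectories for every configured whisker at one wind speed.

    ``wind_speed`` selects the amplitude column: 0 (still air, no
    jitter), 0.5 (low) or 1.5 m/s (high).
    """
    cfg.validate()
    if wind_speed not in (0.0, 0.5, 1.5):
        raise ValueError("wind_speed must be one of 0, 0.5, 1.5 m/s")
    rng = _rng(cfg, rng)
    layout = default_layout()
    out = []
    for w, (lo, hi) in cfg.whisker_amplitudes.items():
        if w not in layout.positions:
            raise ValueError(f"unknown whisker id {w!r} in amplitude map")
        amp = 0.0 if wind_speed == 0.0 else (lo if wind_speed == 0.5 else hi)
        r, c = layout.positions[w]
        base = np.array([c * GRID_SCALE, r * GRID_SCALE])
        jitter = rng.normal(0.0, 1.0, size=(cfg.n_frames, 2)) * amp
        out.append(
            WhiskerTrajectory(
                whisker_id=w,
                x=base[0] + jitter[:, 0],
                y=base[1] + jitter[:, 1],
                frame_rate=cfg.frame_rate,
            )
        )
    return out


def gen_morphology_table(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[MorphometryRecord]:
    """Morphometry samples with the configured correlation structure.

    Whisker-type means for (length, diameter) are drawn from a bivariate
    Gaussian carrying ``type_var_fraction`` of the total variance, with
    the type-level correlation inflated so the pooled samples hit the
    configured ``r_length_diameter``; within-type noise is independent.
    The lSO type mean is then boosted to the maximal ratio.  Apertures
    are generated from the (negated, standardized) type ratio plus noise
    so the aperture-ratio correlation matches ``r_aperture_ratio``.
    Values are clipped at a small positive floor.
    """
    cfg.validate()
    mp = cfg.morph_params
    rng = _rng(cfg, rng)
    whiskers = list(default_layout().whiskers)
    f = mp.type_var_fraction
    rho_type = mp.r_length_diameter / f
    cov = np.array(
        [
            [f * mp.sd_length**2, rho_type * f * mp.sd_length * mp.sd_diameter],
            [rho_type * f * mp.sd_length * mp.sd_diameter, f * mp.sd_diameter**2],
        ]
    )
    type_means = rng.multivariate_normal(
        [mp.mean_length, mp.mean_diameter], cov, size=len(whiskers)
    )
    # force lSO to the extreme length/diameter ratio
    i_lso = whiskers.index("lSO")
    boost = np.sqrt(mp.lso_ratio_boost)
    ratios = type_means[:, 0] / np.maximum(type_means[:, 1], 1e-9)
    i_max = int(np.argmax(ratios))
    # move lSO to the current maximum and push beyond it
    type_means[i_lso] = type_means[i_max] * [boost, 1.0 / boost]
    noise_sd = np.array(
        [np.sqrt(1 - f) * mp.sd_length, np.sqrt(1 - f) * mp.sd_diameter]
    )
    # aperture driven by the standardized type ratio (anticorrelation for
    # negative r: high ratio -> closed ring-wulst, small aperture)
    ratios = type_means[:, 0] / np.maximum(type_means[:, 1], 1e-9)
    z_ratio = (ratios - ratios.mean()) / max(ratios.std(), 1e-12)
    rho = np.clip(mp.r_aperture_ratio / f, -1.0, 1.0)
    ap_type = mp.mean_aperture + mp.sd_aperture * np.sqrt(f) * (
        rho * z_ratio
        + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(0, 1, len(whiskers))
    )
    records = []
    for i, w in enumerate(whiskers):
        for _ in range(mp.n_per_whisker):
            length, diam = type_means[i] + rng.normal(0, 1, 2) * noise_sd
            aperture = ap_type[i] + rng.normal(0, np.sqrt(1 - f) * mp.sd_aperture)
            records.append(
                MorphometryRecord(
                    whisker_id=w,
                    length=max(length, 1e-3),
                    base_diameter=max(diam, 1e-3),
                    ring_wulst_aperture=float(np.clip(aperture, 0.0, 359.999)),
                )
            )
    return records


def gen_epoch_schedule(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> WindEpochSeries:
    """Balanced randomized sequence of low / high / no-wind blocks."""
    ep = cfg.epoch_params
    rng = _rng(cfg, rng)
    conditions = list(ep.speeds) + ([0.0] if ep.include_no_wind else [])
    speeds = np.repeat(conditions, ep.n_per_speed).astype(float)
    rng.shuffle(speeds)
    onsets = ep.start_offset + np.arange(speeds.size) * (ep.duration + ep.gap)
    return WindEpochSeries(onsets=onsets, speeds=speeds, duration=ep.duration)


def _unit_rate_per_second(
    cfg: SimConfig, kind: str, epochs: WindEpochSeries, total_s: int
) -> np.ndarray:
    """Piecewise-constant rate (Hz) on a 1-s grid for one unit."""
    ep = cfg.ephys_params
    rate = np.full(total_s, ep.baseline_rate)
    if kind == "null":
        return rate
    profile = np.asarray(ep.gain_profile)
    for onset, speed in zip(epochs.onsets, epochs.speeds):
        if speed == 0.0:
            continue
        scale = ep.speed_gain_scale.get(float(speed), 1.0)
        for k, g in enumerate(profile):
            sec = int(round(onset)) + k
            if sec >= total_s:
                continue
            eff = 1.0 + (g - 1.0) * scale
            if kind == "excited":
                rate[sec] = ep.baseline_rate * eff
            else:  # inhibited
                rate[sec] = ep.baseline_rate / max(eff, 1e-12)
    return rate


def _poisson_train(rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact inhomogeneous-Poisson sample for a piecewise-constant rate
    on a 1-s grid: per-second Poisson counts with uniform placement."""
    counts = rng.poisson(rate)
    times = []
    for sec, c in enumerate(counts):
        if c:
            times.append(sec + rng.random(c))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def gen_spike_trains(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[UnitSpikeTrain], WindEpochSeries]:
    """Unit populations per region plus their shared wind schedule.

    Within each region the first round(frac_excited * n) units are
    excited, the next round(frac_inhibited * n) inhibited, the rest
    unresponsive; unit ids encode region and index.
    """
    cfg.validate()
    rng = _rng(cfg, rng)
    epochs = gen_epoch_schedule(cfg, rng)
    total_s = int(np.ceil(epochs.onsets[-1] + epochs.duration + cfg.epoch_params.gap))
    units = []
    ep = cfg.ephys_params
    for region, n in ep.n_units.items():
        n_exc = int(round(ep.frac_excited.get(region, 0.0) * n))
        n_inh = int(round(ep.frac_inhibited.get(region, 0.0) * n))
        for i in range(n):
            kind = "excited" if i < n_exc else "inhibited" if i < n_exc + n_inh else "null"
            rate = _unit_rate_per_second(cfg, kind, epochs, total_s)
            units.append(
                UnitSpikeTrain(
                    unit_id=f"{region}_{i:03d}",
                    region=region,
                    spike_times=_poisson_train(rate, rng),
                )
            )
    return units, epochs


def gen_behavior_trials(
    cfg: SimConfig,
    conditions: Iterable[tuple[str, str]] | None = None,
    n_animals: int | None = None,
    paired: tuple[str, str] | None = None,
    stimulus_type: str = "cardboard",
    animal_prefix: str = "rat",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Scored turning trials as a tidy table.

    Two usage modes:

    * ``conditions`` — independent cohorts, one per (stimulus_type,
      treatment) pair, each with ``n_animals`` fresh animals;
    * ``paired`` — a single cohort where every animal runs one session
      under each of the two treatments (e.g. ("lidocaine", "ringer")).

    Defaults generate one untreated cohort per configured stimulus type.
    Trial counts per session are drawn uniformly from ``trials_range``;
    stimulus sides are balanced within a session and shuffled.
    """
    cfg.validate()
    bp = cfg.behavior_params
    rng = _rng(cfg, rng)
    n_animals = bp.n_animals if n_animals is None else n_animals
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rows: list[dict] = []

    def run_session(animal: str, stim: str, treatment: str) -> None:
        probs = bp.response_probs.get((stim, treatment))
        if probs is None:
            raise KeyError(f"no response probabilities for ({stim!r}, {treatment!r})")
        lo, hi = bp.trials_range
        n_trials = int(rng.integers(lo, hi + 1))
        sides = np.array(["left", "right"])[
            rng.permutation(np.arange(n_trials) % 2)
        ]
        responses = rng.choice(list("012"), size=n_trials, p=list(probs))
        mapping = {"0": "toward", "1": "away", "2": "none"}
        for t in range(n_trials):
            rows.append(
                {
                    "animal_id": animal,
                    "trial_index": t,
                    "stimulus_side": sides[t],
                    "stimulus_type": stim,
                    "treatment": treatment,
                    "response": mapping[responses[t]],
                }
            )

    if paired is not None:
        ta, tb = paired
        for a in range(n_animals):
            animal = f"{animal_prefix}{a:02d}"
            for treatment in (ta, tb):
                run_session(animal, stimulus_type, treatment)
    else:
        if conditions is None:
            conditions = [
                (s, t) for (s, t) in bp.response_probs if t == "none"
            ]
        animal_counter = 0
        for stim, treatment in conditions:
            for _ in range(n_animals):
                animal = f"{animal_prefix}{animal_counter:02d}"
                animal_counter += 1
                run_session(animal, stim, treatment)
    return pd.DataFrame(rows)


def gen_wind_trace(
    cfg: SimConfig,
    mean_speed: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Wind-speed trace (m/s): first-order rise toward ``mean_speed``
    with additive white turbulence noise (clipped at 0)."""
    cfg.validate()
    if mean_speed < 0:
        raise ValueError("mean_speed must be >= 0")
    wp = cfg.wind_params
    rng = _rng(cfg, rng)
    t = np.arange(0, wp.duration, 1.0 / wp.sample_rate)
    trace = mean_speed * (1.0 - np.exp(-t / wp.tau))
    if wp.noise_sd > 0 and mean_speed > 0:
        trace = trace + rng.normal(0, wp.noise_sd, t.size)
    return np.clip(trace, 0.0, None)
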