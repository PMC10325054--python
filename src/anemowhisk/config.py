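"""Simulation and run configuration.

:class:`SimConfig` bundles every knob of the synthetic-data generator.
Defaults encode the study conditions the analyses assume: 100 fps video,
10-s wind epochs at 0.5 and 1.5 m/s (12-30 per speed), 13-20 behavior
trials per session, and a whisker-amplitude map in which the long
supra-orbital (lSO) whisker is the most wind-responsive.  All randomness
flows from the single integer ``seed`` through one numpy Generator that
the generator functions create (or accept) explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .layout import DEFAULT_WHISKERS

#: Whiskers whose displacement increases strongly from low to high wind.
WIND_SENSITIVE = (
    "lSO", "sSO", "alpha", "beta", "delta",
    "A1", "A2", "A3", "B1", "B2", "B3", "B4", "C1",
)


def default_amplitudes() -> dict[str, tuple[float, float]]:
    """Per-whisker (low-wind, high-wind) tip-jitter SD, in pixels.

    lSO is strictly maximal at low wind, followed by the straddlers
    alpha/beta and A1; anterior C-E row whiskers barely move.  High-wind
    amplitude is 3x low for the wind-sensitive subset and 1.3x otherwise.
    """
    low = {
        "lSO": 1.0, "sSO": 0.30,
        "alpha": 0.60, "beta": 0.55, "gamma": 0.30, "delta": 0.25,
        "A1": 0.50, "A2": 0.30, "A3": 0.20, "A4": 0.10,
        "B1": 0.30, "B2": 0.25, "B3": 0.15, "B4": 0.10,
        "C1": 0.25, "C2": 0.10, "C3": 0.08, "C4": 0.06,
        "D1": 0.15, "D2": 0.08, "D3": 0.06, "D4": 0.05,
        "E1": 0.12, "E2": 0.06, "E3": 0.05, "E4": 0.05,
    }
    out = {}
    for w in DEFAULT_WHISKERS:
        hi = low[w] * (3.0 if w in WIND_SENSITIVE else 1.3)
        out[w] = (low[w], hi)
    return out


@dataclass
class MorphParams:
    """Morphometry sampling: lengths (mm), base diameters (um), ring-wulst
    aperture (deg), with configurable cross-whisker correlations."""

    mean_length: float = 25.0
    sd_length: float = 8.0
    mean_diameter: float = 100.0
    sd_diameter: float = 30.0
    r_length_diameter: float = 0.83
    mean_aperture: float = 180.0
    sd_aperture: float = 60.0
    r_aperture_ratio: float = -0.66
    n_per_whisker: int = 4
    #: fraction of total variance carried by the whisker-type level
    type_var_fraction: float = 0.9
    #: multiplicative boost of the lSO length/diameter ratio
    lso_ratio_boost: float = 2.0

    def validate(self) -> None:
        for name in ("sd_length", "sd_diameter", "sd_aperture"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r_length_diameter", "r_aperture_ratio"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 < self.type_var_fraction <= 1:
            raise ValueError("type_var_fraction must be in (0, 1]")
        if abs(self.r_length_diameter) >= self.type_var_fraction:
            raise ValueError(
                "target correlation not achievable: needs "
                "|r_length_diameter| < type_var_fraction"
            )
        if self.n_per_whisker < 1:
            raise ValueError("n_per_whisker must be >= 1")


@dataclass
class EphysParams:
    """Inhomogeneous-Poisson unit populations per cortical region."""

    n_units: dict[str, int] = field(default_factory=lambda: {"SO": 24, "pad": 24})
    baseline_rate: float = 5.0  # Hz
    #: multiplicative rate gain over post-onset seconds 1-4 (high wind)
    gain_profile: tuple[float, float, float, float] = (2.5, 3.0, 1.5, 1.2)
    #: per-speed scaling of (gain - 1); high wind is the full profile
    speed_gain_scale: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.6, 1.5: 1.0}
    )
    frac_excited: dict[str, float] = field(
        default_factory=lambda: {"SO": 0.30, "pad": 0.08}
    )
    frac_inhibited: dict[str, float] = field(
        default_factory=lambda: {"SO": 0.08, "pad": 0.12}
    )

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if any(g < 0 for g in self.gain_profile):
            raise ValueError("gains must be >= 0")
        if len(self.gain_profile) != 4:
            raise ValueError("gain_profile covers post-onset seconds 1-4")
        for region in self.n_units:
            fe = self.frac_excited.get(region, 0.0)
            fi = self.frac_inhibited.get(region, 0.0)
            if fe < 0 or fi < 0 or fe + fi > 1:
                raise ValueError(f"invalid excited/inhibited fractions for {region}")


@dataclass
class EpochParams:
    """Wind-epoch schedule: balanced randomized blocks of low / high /
    no-wind, 10 s each, separated by a configurable gap."""

    duration: float = 10.0
    n_per_speed: int = 20
    gap: float = 10.0
    speeds: tuple[float, ...] = (0.5, 1.5)
    include_no_wind: bool = True
    start_offset: float = 6.0

    def validate(self) -> None:
        if self.duration <= 0 or self.n_per_speed < 1:
            raise ValueError("invalid epoch duration or count")
        if self.gap < 4.0:
            raise ValueError("gap must leave room for the 4-s pre-window")


@dataclass
class BehaviorParams:
    """Multinomial turning-response generator settings.

    ``response_probs`` maps (stimulus_type, treatment) to the
    (p_toward, p_away, p_none) triple.  Defaults follow the observed
    turning statistics this pipeline is designed to detect: a strong
    toward-bias for untreated animals, a stronger one for cardboard
    flaps, reduced toward-rates after wind-whisker trimming (20% vs 29%)
    and under lidocaine vs Ringer (18% vs 23%).
    """

    n_animals: int = 7
    trials_range: tuple[int, int] = (13, 20)
    response_probs: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: {
            ("hand", "none"): (0.31, 0.07, 0.62),
            ("cardboard", "none"): (0.50, 0.07, 0.43),
            ("cardboard", "wind_trim"): (0.20, 0.10, 0.70),
            ("cardboard", "nonwind_trim"): (0.29, 0.10, 0.61),
            ("cardboard", "lidocaine"): (0.18, 0.08, 0.74),
            ("cardboard", "ringer"): (0.23, 0.08, 0.69),
        }
    )

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        lo, hi = self.trials_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid trials_range")
        for key, triple in self.response_probs.items():
            arr = np.asarray(triple, dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"probabilities for {key} must be >= 0 and sum to 1")


@dataclass
class WindTraceParams:
    """First-order rise toward the mean speed plus white turbulence noise.

    The default time constant puts the 80%-of-mean crossing at exactly
    1.5 s in the noise-free limit (tau = 1.5 / ln 5)."""

    tau: float = 1.5 / math.log(5.0)
    noise_sd: float = 0.05
    duration: float = 10.0
    sample_rate: float = 100.0

    def validate(self) -> None:
        if self.tau <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("tau, duration and sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimConfig:
    """Top-level synthetic-data configuration (single seed)."""

    seed: int = 0
    frame_rate: float = 100.0
    n_frames: int = 6000
    whisker_amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=default_amplitudes
    )
    morph_params: MorphParams = field(default_factory=MorphParams)
    ephys_params: EphysParams = field(default_factory=EphysParams)
    epoch_params: EpochParams = field(default_factory=EpochParams)
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    wind_params: WindTraceParams = field(default_factory=WindTraceParams)

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.n_frames < 1:
            raise ValueError("frame_rate and n_frames must be positive")
        for w, (lo, hi) in self.whisker_amplitudes.items():
            if lo < 0 or hi < 0:
                raise ValueError(f"negative amplitude for whisker {w!r}")
        self.morph_params.validate()
        self.ephys_params.validate()
        self.epoch_params.validate()
        self.behavior_params.validate()
        self.wind_params.validate()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        # tuple-keyed dict is not YAML-representable; flatten
        data["behavior_params"]["response_probs"] = {
            f"{s}/{t}": list(v)
            for (s, t), v in self.behavior_params.response_probs.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(data), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        probs = data.get("behavior_params", {}).pop("response_probs", None)
        cfg = cls(
            seed=data.get("seed", 0),
            frame_rate=data.get("frame_rate", 100.0),
            n_frames=data.get("n_frames", 6000),
            whisker_amplitudes={
                k: tuple(v) for k, v in data.get(
                    "whisker_amplitudes", default_amplitudes()
                ).items()
            },
            morph_params=MorphParams(**data.get("morph_params", {})),
            ephys_params=_ephys_from_dict(data.get("ephys_params", {})),
            epoch_params=_epoch_from_dict(data.get("epoch_params", {})),
            behavior_params=BehaviorParams(
                **{k: v for k, v in data.get("behavior_params", {}).items()}
            ),
            wind_params=WindTraceParams(**data.get("wind_params", {})),
        )
        if probs is not None:
            cfg.behavior_params.response_probs = {
                tuple(k.split("/", 1)): tuple(v) for k, v in probs.items()
            }
        cfg.validate()
        return cfg


def _plain(obj):
    """Recursively convert tuples and numpy scalars to YAML-safe types."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _ephys_from_dict(d: Mapping) -> EphysParams:
    d = dict(d)
    if "gain_profile" in d:
        d["gain_profile"] = tuple(d["gain_profile"])
    if "speed_gain_scale" in d:
        d["speed_gain_scale"] = {float(k): float(v) for k, v in d["speed_gain_scale"].items()}
    return EphysParams(**d)


def _epoch_from_dict(d: Mapping) -> EpochParams:
    d = dict(d)
    if "speeds" in d:
        d["speeds"] = tuple(d["speeds"])
    return EpochParams(**d)
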