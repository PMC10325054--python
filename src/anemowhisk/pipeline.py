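"""End-to-end orchestration: simulate (or load) inputs, run every
analysis stage, and write tidy CSV outputs plus a markdown report.

Stages run in order kinematics -> morphometrics -> ephys -> behavior;
a failing stage aborts the run with the stage named.  Every output
table carries the run seed and a hash of the configuration so two runs
are bit-comparable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, io, kinematics, morphometrics, synthetic
from . import ephys as ephys_mod
from .config import SimConfig
from .layout import default_layout

log = logging.getLogger("anemowhisk")


@dataclass
class RunConfig:
    """Pipeline run settings; input paths default to simulation."""

    out_dir: str = "anemowhisk_out"
    seed: int = 0
    dlc_path: str | None = None
    morphometry_path: str | None = None
    spikes_path: str | None = None
    epochs_path: str | None = None
    behavior_path: str | None = None
    calibration_cm_per_px: float = 1.0
    likelihood_threshold: float | None = None
    alpha: float = 0.05
    n_shuffles: int = 10_000
    posthoc: str = "tukey"
    mi_cap: int = 10
    stages: tuple[str, ...] = ("kinematics", "morphometrics", "ephys", "behavior")
    sim: SimConfig = field(default_factory=SimConfig)

    def config_hash(self) -> str:
        # out_dir is a run location, not part of the scientific config
        payload = {
            k: str(v) for k, v in self.__dict__.items() if k not in ("sim", "out_dir")
        }
        text = yaml.safe_dump(payload, sort_keys=True) + str(self.sim)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stamp(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    table = table.copy()
    table["seed"] = cfg.seed
    table["config_hash"] = cfg.config_hash()
    return table


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the requested stages; returns a map of output name -> path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.sim.seed = cfg.seed
    rng = np.random.default_rng(cfg.seed)
    outputs: dict[str, Path] = {}
    report_lines = [
        "# anemowhisk pipeline report",
        f"- version: {__version__}",
        f"- seed: {cfg.seed}",
        f"- config hash: {cfg.config_hash()}",
        f"- stages: {', '.join(cfg.stages)}",
    ]

    def save(name: str, table: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        _stamp(table, cfg).to_csv(path, index=False)
        outputs[name] = path

    for stage in cfg.stages:
        log.info("stage: %s", stage)
        try:
            if stage == "kinematics":
                _stage_kinematics(cfg, rng, save, report_lines)
            elif stage == "morphometrics":
                _stage_morphometrics(cfg, rng, save, report_lines)
            elif stage == "ephys":
                _stage_ephys(cfg, rng, save, report_lines)
            elif stage == "behavior":
                _stage_behavior(cfg, rng, save, report_lines)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.md").write_text("\n".join(report_lines) + "\n", encoding="utf-8")
    outputs["report"] = out / "report.md"
    return outputs


def _stage_kinematics(cfg, rng, save, report) -> None:
    summaries = {}
    for label, speed in (("low", 0.5), ("high", 1.5)):
        if cfg.dlc_path is not None and label == "low":
            trajs = io.read_dlc_csv(cfg.dlc_path)
        else:
            trajs = synthetic.gen_whisker_trajectories(cfg.sim, speed, rng)
        series = [
            kinematics.displacement_series(
                t,
                likelihood_threshold=cfg.likelihood_threshold,
                calibration=cfg.calibration_cm_per_px,
            )
            for t in trajs
        ]
        summary = kinematics.summarize_displacement(series, mode="mean_sem")
        summaries[label] = summary
        save(f"displacement_{label}", summary)
        groups = {s.whisker_id: s.d[~np.isnan(s.d)] for s in series}
        kw = kinematics.compare_whiskers(groups, posthoc=None)
        report.append(
            f"- kinematics[{label}]: top whisker = "
            f"{summary.iloc[0]['whisker_id']}, Kruskal-Wallis "
            f"H({kw.df}, {kw.n_total}) = {kw.H:.1f}, p = {kw.p:.3g}"
        )
    ratio_table, ratio_test = kinematics.displacement_ratio(
        summaries["high"], summaries["low"]
    )
    save("displacement_ratio", ratio_table)
    report.append(
        f"- displacement ratio vs 1: signed-rank p = {ratio_test.p:.4g} "
        f"(n = {ratio_test.n})"
    )


def _stage_morphometrics(cfg, rng, save, report) -> None:
    if cfg.morphometry_path is not None:
        records = io.read_morphometry_csv(cfg.morphometry_path)
    else:
        records = synthetic.gen_morphology_table(cfg.sim, rng)
    table = morphometrics.records_to_frame(records)
    save("morphometry", table)
    r_ld, p_ld = morphometrics.correlate(
        table["length_mm"].to_numpy(), table["diameter_um"].to_numpy()
    )
    report.append(f"- morphometrics: length-diameter r = {r_ld:.2f} (p = {p_ld:.2g})")
    ratios = table.groupby("whisker_id")["ratio"].mean().to_dict()
    layout = default_layout()
    best, results = morphometrics.select_optimal_arrangement(
        ratios, layout.all_schemes(), n_shuffles=cfg.n_shuffles, rng=rng
    )
    scheme_table = pd.DataFrame(
        [
            {
                "arrangement": name,
                "observed_mean_variance": res.observed,
                "p": res.p,
                "n_shuffles": res.n_shuffles,
            }
            for name, res in results.items()
        ]
    )
    save("arrangement_shuffle", scheme_table)
    report.append(f"- optimal arrangement for ratio: {best.name}")
    if table["aperture_deg"].notna().any():
        r_ar, p_ar = morphometrics.correlate(
            table["aperture_deg"].to_numpy(), table["ratio"].to_numpy()
        )
        report.append(f"- aperture-ratio r = {r_ar:.2f} (p = {p_ar:.2g})")


def _stage_ephys(cfg, rng, save, report) -> None:
    if cfg.spikes_path is not None and cfg.epochs_path is not None:
        units = io.read_spikes_csv(cfg.spikes_path)
        epochs = io.read_epochs_csv(cfg.epochs_path)
    else:
        units, epochs = synthetic.gen_spike_trains(cfg.sim, rng)
    regions = {u.unit_id: u.region for u in units}
    rows_cls, rows_mi, rows_lat = [], [], []
    pct_frames = []
    for label, speed in (("low", 0.5), ("high", 1.5)):
        sel = epochs.select(speed)
        classifications = []
        mi_results = []
        for u in units:
            binned = ephys_mod.bin_spikes(u, sel)
            cls = ephys_mod.classify_response_glm(binned, alpha=cfg.alpha)
            classifications.append(cls)
            z = ephys_mod.zscore_response(binned)
            lat = ephys_mod.response_latency(z)
            mi = ephys_mod.mutual_information(binned, label, cap=cfg.mi_cap)
            mi_results.append(mi)
            rows_lat.append(
                {"unit_id": u.unit_id, "condition": label, "latency_s": lat}
            )
            for sec in ephys_mod.POST_SECONDS:
                rows_cls.append(
                    {
                        "unit_id": u.unit_id,
                        "condition": label,
                        "second": sec,
                        "label": cls.labels.get(sec, "failed"),
                        "p": cls.p_values.get(sec, np.nan),
                    }
                )
                if mi.normalized is not None:
                    rows_mi.append(
                        {
                            "unit_id": u.unit_id,
                            "condition": label,
                            "second": sec,
                            "mi_bits": mi.per_second_mi[sec - 1],
                            "normalized_mi": mi.normalized[sec - 1],
                        }
                    )
        pct = ephys_mod.response_percentages(classifications, regions)
        pct["condition"] = label
        pct_frames.append(pct)
        so_units = [m for m in mi_results if regions[m.unit_id] == "SO"]
        if len([m for m in so_units if m.normalized is not None]) >= 5:
            mi_test = ephys_mod.normalized_mi_test(so_units)
            peak = mi_test.loc[mi_test["median_normalized_mi"].idxmax(), "second"]
            report.append(
                f"- ephys[{label}]: SO normalized MI peaks at second {peak}"
            )
    save("response_classification", pd.DataFrame(rows_cls))
    save("response_percentages", pd.concat(pct_frames, ignore_index=True))
    save("latency", pd.DataFrame(rows_lat))
    if rows_mi:
        save("mutual_information", pd.DataFrame(rows_mi))


def _stage_behavior(cfg, rng, save, report) -> None:
    if cfg.behavior_path is not None:
        table = io.read_behavior_csv(cfg.behavior_path)
    else:
        table = synthetic.gen_behavior_trials(cfg.sim, rng=rng)
    save("behavior_trials", table)
    save("turn_summary", behavior.turn_summary(table))
    for stim in sorted(table["stimulus_type"].unique()):
        res = behavior.direction_bias_test(table, stimulus_type=stim)
        report.append(
            f"- behavior[{stim}]: toward {res.n_toward} vs away {res.n_away}, "
            f"chi2 = {res.statistic:.2f}, p = {res.p:.3g}"
        )
    types = set(table["stimulus_type"])
    if {"hand", "cardboard"} <= types:
        fr = behavior.stimulus_strength_comparison(table)
        report.append(f"- hand vs cardboard toward-rate: Fisher p = {fr.p:.3g}")
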