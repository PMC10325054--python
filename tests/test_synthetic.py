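"""Determinism, distributional correctness and parameter recovery of the
synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from anemowhisk.config import SimConfig
from anemowhisk.kinematics import displacement_series, summarize_displacement
from anemowhisk.morphometrics import records_to_frame
from anemowhisk.synthetic import (
    gen_behavior_trials,
    gen_epoch_schedule,
    gen_morphology_table,
    gen_spike_trains,
    gen_whisker_trajectories,
    gen_wind_trace,
)


class TestDeterminism:
    def test_trajectories_identical_across_calls(self, cfg):
        a = gen_whisker_trajectories(cfg, 0.5)
        b = gen_whisker_trajectories(cfg, 0.5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_spikes_identical_across_calls(self, cfg):
        ua, ea = gen_spike_trains(cfg)
        ub, eb = gen_spike_trains(cfg)
        np.testing.assert_array_equal(ea.onsets, eb.onsets)
        np.testing.assert_array_equal(ea.speeds, eb.speeds)
        for a, b in zip(ua, ub):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_morphology_behavior_wind_identical(self, cfg):
        ma = records_to_frame(gen_morphology_table(cfg))
        mb = records_to_frame(gen_morphology_table(cfg))
        pd.testing.assert_frame_equal(ma, mb)
        pd.testing.assert_frame_equal(gen_behavior_trials(cfg), gen_behavior_trials(cfg))
        np.testing.assert_array_equal(
            gen_wind_trace(cfg, 0.5), gen_wind_trace(cfg, 0.5)
        )

    def test_different_seed_differs(self, cfg):
        a = gen_whisker_trajectories(cfg, 0.5)[0]
        cfg.seed += 1
        b = gen_whisker_trajectories(cfg, 0.5)[0]
        assert not np.array_equal(a.x, b.x)


class TestTrajectories:
    def test_zero_amplitude_zero_displacement(self, cfg):
        cfg.whisker_amplitudes["C3"] = (0.0, 0.0)
        trajs = {t.whisker_id: t for t in gen_whisker_trajectories(cfg, 0.5)}
        d = displacement_series(trajs["C3"]).d
        np.testing.assert_array_equal(d, 0.0)

    def test_unknown_whisker_rejected(self, cfg):
        cfg.whisker_amplitudes["Z9"] = (1.0, 1.0)
        with pytest.raises(ValueError, match="Z9"):
            gen_whisker_trajectories(cfg, 0.5)

    def test_invalid_wind_speed_rejected(self, cfg):
        with pytest.raises(ValueError):
            gen_whisker_trajectories(cfg, 1.0)

    def test_lso_ranks_first_across_seeds(self):
        """With lSO amplitude strictly maximal the displacement rank of
        lSO is 1 in nearly every seeded run."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_frames=600)
            series = [
                displacement_series(t)
                for t in gen_whisker_trajectories(cfg, 0.5)
            ]
            summary = summarize_displacement(series)
            wins += summary.iloc[0]["whisker_id"] == "lSO"
        assert wins >= 0.95 * n_seeds


class TestMorphology:
    def test_target_correlation_recovered(self):
        rs = []
        for seed in range(15):
            cfg = SimConfig(seed=seed)
            fr = records_to_frame(gen_morphology_table(cfg))
            by_type = fr.groupby("whisker_id")[["length_mm", "diameter_um"]].mean()
            rs.append(np.corrcoef(by_type.length_mm, by_type.diameter_um)[0, 1])
        assert abs(np.median(rs) - 0.83) < 0.15

    def test_zero_target_correlation(self):
        """With target r = 0 the sampled correlation stays near zero at
        the rate the exact null distribution of Pearson r predicts.

        lSO is excluded: its ratio is boosted by construction (the
        deliberately extreme whisker) and sits outside the correlation
        model."""
        n_seeds, hits = 30, 0
        n_types = None
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed)
            cfg.morph_params.r_length_diameter = 0.0
            fr = records_to_frame(gen_morphology_table(cfg))
            by_type = (
                fr[fr.whisker_id != "lSO"]
                .groupby("whisker_id")[["length_mm", "diameter_um"]]
                .mean()
            )
            n_types = len(by_type)
            r = np.corrcoef(by_type.length_mm, by_type.diameter_um)[0, 1]
            hits += abs(r) < 0.3
        # oracle: under H0, r*sqrt(n-2)/sqrt(1-r^2) ~ t_{n-2}
        df = n_types - 2
        t_crit = 0.3 * np.sqrt(df) / np.sqrt(1 - 0.3**2)
        p_in = sps.t.cdf(t_crit, df) - sps.t.cdf(-t_crit, df)
        sd = np.sqrt(n_seeds * p_in * (1 - p_in))
        assert abs(hits - n_seeds * p_in) <= 2.58 * sd + 1

    def test_aperture_anticorrelated_with_ratio(self, cfg):
        fr = records_to_frame(gen_morphology_table(cfg))
        r = np.corrcoef(fr.aperture_deg, fr.ratio)[0, 1]
        assert r < -0.3

    def test_lso_has_maximal_mean_ratio(self):
        for seed in range(10):
            fr = records_to_frame(gen_morphology_table(SimConfig(seed=seed)))
            assert fr.groupby("whisker_id").ratio.mean().idxmax() == "lSO"

    def test_invalid_params_rejected(self, cfg):
        cfg.morph_params.sd_length = 0.0
        with pytest.raises(ValueError):
            gen_morphology_table(cfg)
        cfg.morph_params.sd_length = 8.0
        cfg.morph_params.r_length_diameter = 1.2
        with pytest.raises(ValueError):
            gen_morphology_table(cfg)


class TestSpikeTrains:
    def test_epoch_schedule_balanced_and_spaced(self, cfg):
        epochs = gen_epoch_schedule(cfg)
        counts = pd.Series(epochs.speeds).value_counts()
        assert set(counts.index) == {0.0, 0.5, 1.5}
        assert (counts == cfg.epoch_params.n_per_speed).all()
        gaps = np.diff(epochs.onsets)
        assert (gaps >= cfg.epoch_params.duration + 4.0).all()

    def test_null_units_poisson_rate(self, cfg):
        cfg.ephys_params.frac_excited = {"SO": 0.0, "pad": 0.0}
        cfg.ephys_params.frac_inhibited = {"SO": 0.0, "pad": 0.0}
        units, epochs = gen_spike_trains(cfg)
        span = epochs.onsets[-1] + epochs.duration
        for u in units[:4]:
            n = np.sum(u.spike_times < span)
            expected = cfg.ephys_params.baseline_rate * span
            assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_null_unit_isi_exponential(self):
        """KS test of null-unit inter-spike intervals against the
        exponential law holds in nearly all seeds."""
        passes, n_seeds = 0, 40
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed)
            cfg.ephys_params.n_units = {"SO": 1}
            cfg.ephys_params.frac_excited = {"SO": 0.0}
            cfg.ephys_params.frac_inhibited = {"SO": 0.0}
            cfg.epoch_params.n_per_speed = 10
            units, _ = gen_spike_trains(cfg)
            isi = np.diff(units[0].spike_times)
            p = sps.kstest(
                isi, "expon", args=(0, 1 / cfg.ephys_params.baseline_rate)
            ).pvalue
            passes += p > 0.01
        assert passes >= 0.9 * n_seeds

    def test_excited_gain_matches_analytic_mean(self):
        cfg = SimConfig(seed=5)
        cfg.ephys_params.n_units = {"SO": 1}
        cfg.ephys_params.frac_excited = {"SO": 1.0}
        cfg.ephys_params.frac_inhibited = {"SO": 0.0}
        cfg.ephys_params.gain_profile = (2.0, 2.0, 1.0, 1.0)
        cfg.ephys_params.speed_gain_scale = {0.5: 1.0, 1.5: 1.0}
        cfg.epoch_params.n_per_speed = 50
        units, epochs = gen_spike_trains(cfg)
        u = units[0]
        counts = []
        for onset, speed in zip(epochs.onsets, epochs.speeds):
            if speed == 0.0:
                continue
            counts.append(
                np.sum((u.spike_times >= onset) & (u.spike_times < onset + 2))
            )
        mean = np.mean(counts)
        expected = 2 * 2.0 * cfg.ephys_params.baseline_rate  # 2 s at 2x baseline
        assert abs(mean - expected) < 3 * np.sqrt(expected / len(counts))

    def test_negative_rate_rejected(self, cfg):
        cfg.ephys_params.baseline_rate = -1.0
        with pytest.raises(ValueError):
            gen_spike_trains(cfg)


class TestBehaviorTrials:
    def test_degenerate_probabilities_all_toward(self, cfg):
        cfg.behavior_params.response_probs[("hand", "none")] = (1.0, 0.0, 0.0)
        t = gen_behavior_trials(cfg, conditions=[("hand", "none")])
        assert (t["response"] == "toward").all()

    def test_symmetric_probabilities_balance(self):
        cfg = SimConfig(seed=9)
        cfg.behavior_params.response_probs[("hand", "none")] = (0.3, 0.3, 0.4)
        cfg.behavior_params.trials_range = (100, 100)
        t = gen_behavior_trials(cfg, conditions=[("hand", "none")], n_animals=10)
        n_to = (t.response == "toward").sum()
        n_aw = (t.response == "away").sum()
        n_react = n_to + n_aw
        assert abs(n_to - n_react / 2) < 3 * np.sqrt(n_react * 0.25)

    def test_sides_balanced_within_session(self, cfg):
        t = gen_behavior_trials(cfg)
        for _, sub in t.groupby(["animal_id", "treatment"]):
            counts = sub["stimulus_side"].value_counts()
            assert abs(counts.get("left", 0) - counts.get("right", 0)) <= 1

    def test_paired_design_two_sessions_per_animal(self, cfg):
        t = gen_behavior_trials(cfg, paired=("lidocaine", "ringer"), n_animals=8)
        per = t.groupby("animal_id")["treatment"].nunique()
        assert len(per) == 8 and (per == 2).all()

    def test_invalid_inputs_rejected(self, cfg):
        with pytest.raises(ValueError):
            gen_behavior_trials(cfg, n_animals=0)
        cfg.behavior_params.response_probs[("hand", "none")] = (0.5, 0.2, 0.2)
        with pytest.raises(ValueError):
            gen_behavior_trials(cfg)


class TestWindTrace:
    def test_noise_free_80pct_crossing(self, cfg):
        from anemowhisk.kinematics import wind_rise_time

        cfg.wind_params.noise_sd = 0.0
        cfg.wind_params.duration = 60.0
        trace = gen_wind_trace(cfg, 0.5)
        rt = wind_rise_time(
            trace, 0.8, sample_rate=cfg.wind_params.sample_rate, steady_window=5.0
        )
        assert rt == pytest.approx(1.5, abs=0.05)

    def test_zero_mean_speed_identically_zero(self, cfg):
        np.testing.assert_array_equal(gen_wind_trace(cfg, 0.0), 0.0)

    def test_noise_free_trace_monotone(self, cfg):
        cfg.wind_params.noise_sd = 0.0
        trace = gen_wind_trace(cfg, 1.5)
        assert (np.diff(trace) >= 0).all()
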