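"""Synthetic cohort generator: paradigm timing, cardiac series, effects."""

import numpy as np
import pytest

from herpipeline.core_io import BlockType, Condition, Group
from herpipeline.epochs import EffectLevel, epoch_heartbeat_post_stimulus, subject_effect
from herpipeline.cardiac import HeartbeatSeries
from herpipeline.sim import (
    EffectSpec,
    SimConfig,
    generate_event_stream,
    simulate_cardiac,
    simulate_cohort,
    simulate_subject,
)


class TestEventStream:
    @pytest.mark.parametrize(
        "block,freq_cond,rare_cond",
        [
            (BlockType.XX, Condition.LSGS, Condition.LDGD),
            (BlockType.XY, Condition.LDGS, Condition.LSGD),
        ],
    )
    def test_block_condition_semantics(self, block, freq_cond, rare_cond):
        events = generate_event_stream(block, 50, 0.2, seed=0)
        by_trial = {}
        for e in events:
            by_trial.setdefault(e.trial_id, e.condition)
        conds = list(by_trial.values())
        assert conds.count(rare_cond) == 10  # round(0.2 * 50)
        assert conds.count(freq_cond) == 40

    def test_fifth_sound_600ms_after_first(self):
        events = generate_event_stream(BlockType.XX, 20, 0.2, fs=250.0, soa_ms=150.0, seed=1)
        for tid in range(20):
            trial = sorted(
                (e for e in events if e.trial_id == tid), key=lambda e: e.sound_index
            )
            # 4 x 150 ms = 600 ms = 150 samples at 250 Hz
            assert trial[4].onset_sample - trial[0].onset_sample == 150

    def test_intertrial_gap_within_configured_range(self):
        events = generate_event_stream(BlockType.XY, 60, 0.2, fs=250.0, seed=2)
        fifth = sorted((e for e in events if e.sound_index == 5), key=lambda e: e.onset_sample)
        first = sorted((e for e in events if e.sound_index == 1), key=lambda e: e.onset_sample)
        for f5, nxt in zip(fifth[:-1], first[1:]):
            gap_ms = (nxt.onset_sample - f5.onset_sample) * 4.0
            # tone (50 ms) + ITI in [1350, 1650], half-sample slack
            assert 1400 - 2 <= gap_ms <= 1700 + 2

    def test_rare_fraction_bounds(self):
        with pytest.raises(ValueError):
            generate_event_stream(BlockType.XX, 10, 1.5, seed=0)


class TestCardiac:
    def test_zero_sd_gives_exact_intervals(self):
        _, peaks = simulate_cardiac(20.0, 250.0, 800.0, 0.0, seed=0)
        assert np.all(np.diff(peaks) == 200)

    def test_beat_count_matches_duration(self):
        _, peaks = simulate_cardiac(10.0, 250.0, 1000.0, 0.0, seed=0)
        assert abs(len(peaks) - 10) <= 1

    def test_peaks_are_trace_maxima(self):
        trace, peaks = simulate_cardiac(30.0, 250.0, 900.0, 40.0, seed=3, noise_sd=0.0)
        for p in peaks:
            lo, hi = p - 15, p + 16
            assert trace[p] == trace[lo:hi].max()

    def test_determinism(self):
        t1, p1 = simulate_cardiac(15.0, 250.0, 800.0, 60.0, seed=9)
        t2, p2 = simulate_cardiac(15.0, 250.0, 800.0, 60.0, seed=9)
        assert np.array_equal(t1, t2) and np.array_equal(p1, p2)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_cardiac(10.0, 250.0, 800.0, -1.0, seed=0)


class TestSubject:
    def test_determinism(self):
        cfg = SimConfig(n_channels=16, trials_per_block=10, n_blocks_xx=1, n_blocks_xy=1)
        r1, g1 = simulate_subject(cfg, Group.MCS, seed=5)
        r2, g2 = simulate_subject(cfg, Group.MCS, seed=5)
        assert np.array_equal(r1.eeg, r2.eeg)
        assert np.array_equal(g1.true_rpeak_samples, g2.true_rpeak_samples)

    def test_unknown_group_rejected(self):
        cfg = SimConfig(n_channels=16, trials_per_block=5)
        with pytest.raises(ValueError):
            simulate_subject(cfg, Group.UNKNOWN, seed=0)

    def test_planted_her_local_amplitude_recovered(self):
        """A 5 uV heartbeat-locked deviant increment over 400-412 ms shows
        up in the subject-level HER local contrast at 5 +- 0.5 uV."""
        cfg = SimConfig(
            n_channels=16, trials_per_block=90, n_blocks_xx=1, n_blocks_xy=1,
            noise_sd_uv=1.0, noise_ar=0.0, artifact_gain=0.0, her_var_sd_uv=0.0,
            her_local=EffectSpec(5.0, (400.0, 412.0), 8, 0),
            her_global=EffectSpec(0.0, (112.0, 130.0), 8, 0),
        )
        rec, gt = simulate_subject(cfg, Group.MCS, seed=21)
        hb = HeartbeatSeries(gt.true_rpeak_samples, fs=cfg.fs)
        her = epoch_heartbeat_post_stimulus(rec, hb)
        eff = subject_effect(her, EffectLevel.LOCAL)
        chans = gt.planted_effect_windows["her_local"]["channels"]
        w = slice(100, 103)  # 400-412 ms at 250 Hz
        assert abs(eff.map[chans, w].mean() - 5.0) < 0.5

    def test_zero_amplitude_effects_give_null_contrast(self):
        cfg = SimConfig(
            n_channels=16, trials_per_block=60, n_blocks_xx=1, n_blocks_xy=1,
            noise_sd_uv=1.0, artifact_gain=0.0, her_var_sd_uv=0.0,
            erp_local=EffectSpec(0.0, (236.0, 328.0), 8, 0),
            erp_global=EffectSpec(0.0, (800.0, 850.0), 8, 0),
            her_local=EffectSpec(0.0, (400.0, 412.0), 8, 0),
            her_global=EffectSpec(0.0, (112.0, 130.0), 8, 0),
        )
        rec, gt = simulate_subject(cfg, Group.MCS, seed=2)
        hb = HeartbeatSeries(gt.true_rpeak_samples, fs=cfg.fs)
        her = epoch_heartbeat_post_stimulus(rec, hb)
        eff = subject_effect(her, EffectLevel.LOCAL)
        # expectation zero: mean over the whole map is a tight average
        assert abs(eff.map.mean()) < 0.1


class TestCohort:
    def test_manifest_counts_and_labels(self):
        cfg = SimConfig(n_mcs=3, n_uws=2, n_channels=16, trials_per_block=5,
                        n_blocks_xx=1, n_blocks_xy=1, seed=1)
        manifest = simulate_cohort(cfg)
        labels = [s["group"] for s in manifest["subjects"]]
        assert labels == ["MCS"] * 3 + ["UWS"] * 2

    def test_control_subjects_get_half_the_blocks(self):
        cfg = SimConfig(n_mcs=1, n_uws=0, n_control=1, n_channels=16,
                        trials_per_block=10, n_blocks_xx=2, n_blocks_xy=2, seed=1)
        manifest = simulate_cohort(cfg)
        patient = manifest["subjects"][0]["recording"]
        control = manifest["subjects"][1]["recording"]
        n_trials = lambda r: len({e.trial_id for e in r.events})
        assert n_trials(patient) == 40 and n_trials(control) == 20

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(n_mcs=0, n_uws=0, n_control=0))

    def test_cohort_determinism_on_disk(self, tmp_path):
        cfg = SimConfig(n_mcs=1, n_uws=1, n_channels=16, trials_per_block=5,
                        n_blocks_xx=1, n_blocks_xy=1, seed=4)
        m1 = simulate_cohort(cfg, tmp_path / "a")
        m2 = simulate_cohort(cfg, tmp_path / "b")
        for s1, s2 in zip(m1["subjects"], m2["subjects"]):
            b1 = open(s1["truth"], "rb").read()
            b2 = open(s2["truth"], "rb").read()
            assert b1 == b2
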