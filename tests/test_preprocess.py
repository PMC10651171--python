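"""Filtering, channel rejection, ICA-ECG recovery, interpolation, CAR."""

import numpy as np
import pytest

from herpipeline.cardiac import detect_rpeaks
from herpipeline.core_io import Group, Recording, SensorLayout, build_neighbor_graph
from herpipeline.preprocess import (
    CardiacComponentError,
    bandpass_filter,
    extract_ica_ecg,
    interpolate_low_correlation_channels,
    reject_channels_zscore,
    rereference_and_subset,
    weighted_neighbor_correlation,
)
from herpipeline.sim import SimConfig, hemispherical_layout, qrs_template, simulate_subject

FS = 250.0


def _rec(eeg, fs=FS):
    lay = hemispherical_layout(eeg.shape[0])
    return Recording("p", Group.MCS, np.asarray(eeg, float), fs, lay)


def _steady(x, fs=FS, skip_s=2.0):
    k = int(skip_s * fs)
    return x[:, k:-k]


class TestBandpass:
    @pytest.mark.parametrize("design", ["butter", "fir"])
    def test_dc_removed(self, design):
        rec = _rec(np.full((3, 5000), 100.0))
        out = bandpass_filter(rec, design=design)
        assert np.abs(_steady(out.eeg)).max() < 0.1  # < 1e-3 of input

    @pytest.mark.parametrize("design", ["butter", "fir"])
    def test_passband_gain_near_unity(self, design):
        t = np.arange(20000) / FS
        rec = _rec(np.tile(np.sin(2 * np.pi * 10 * t), (3, 1)))
        out = bandpass_filter(rec, design=design)
        amp = np.abs(_steady(out.eeg, skip_s=8.0)).max()
        assert 0.95 <= amp <= 1.05

    @pytest.mark.parametrize("design", ["butter", "fir"])
    def test_stopband_attenuation(self, design):
        t = np.arange(20000) / FS
        rec = _rec(np.tile(np.sin(2 * np.pi * 50 * t), (3, 1)))
        out = bandpass_filter(rec, design=design)
        assert np.abs(_steady(out.eeg, skip_s=8.0)).max() < 0.1

    def test_linearity(self, rng):
        x = rng.normal(0, 1, (3, 4000))
        y = rng.normal(0, 1, (3, 4000))
        fa = bandpass_filter(_rec(2.0 * x + 3.0 * y)).eeg
        fb = 2.0 * bandpass_filter(_rec(x)).eeg + 3.0 * bandpass_filter(_rec(y)).eeg
        assert np.allclose(fa, fb, atol=1e-8)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec(np.zeros((3, 1000))), high_hz=130.0)


class TestChannelRejection:
    def test_identical_channels_not_rejected(self):
        rec = _rec(np.ones((8, 2000)))
        out, rep = reject_channels_zscore(rec)
        assert rep.rejected_channels_zscore == []
        assert out.n_channels == 8

    def test_single_loud_channel_rejected_first(self, rng):
        eeg = rng.normal(0, 1, (32, 5000))
        eeg[7] *= 50.0
        out, rep = reject_channels_zscore(_rec(eeg))
        assert rep.rejected_channels_zscore[0] == "E8"
        assert "E8" not in out.layout.names

    def test_two_outliers_rejected_iteratively(self, rng):
        eeg = rng.normal(0, 1, (32, 5000))
        eeg[3] *= 50.0
        eeg[11] *= 20.0
        _, rep = reject_channels_zscore(_rec(eeg))
        assert {"E4", "E12"} <= set(rep.rejected_channels_zscore)

    def test_fixpoint(self, rng):
        eeg = rng.normal(0, 1, (32, 5000))
        eeg[0] *= 30.0
        out, _ = reject_channels_zscore(_rec(eeg))
        out2, rep2 = reject_channels_zscore(out)
        assert rep2.rejected_channels_zscore == []
        assert np.array_equal(out2.eeg, out.eeg)


@pytest.fixture(scope="module")
def subject():
    cfg = SimConfig(n_channels=24, trials_per_block=20, n_blocks_xx=1,
                    n_blocks_xy=1, seed=17)
    rec, gt = simulate_subject(cfg, Group.MCS, seed=17)
    return cfg, rec, gt


class TestIcaEcg:
    def test_rpeaks_recovered_within_4ms(self, subject):
        cfg, rec, gt = subject
        filtered = bandpass_filter(rec)
        _, ecg, report = extract_ica_ecg(filtered, seed=0)
        hb = detect_rpeaks(ecg, cfg.fs)
        tp = np.asarray(gt.true_rpeak_samples)
        d = np.abs(tp[:, None] - hb.rpeak_samples[None, :]).min(axis=1)
        assert (d <= 1).mean() >= 0.99  # 1 sample = 4 ms at 250 Hz

    def test_cleaned_recording_loses_cardiac_artifact(self, subject):
        cfg, rec, gt = subject
        filtered = bandpass_filter(rec)
        cleaned, _, _ = extract_ica_ecg(filtered, seed=0)
        tpl = qrs_template(cfg.fs)
        half = len(tpl) // 2
        train = np.zeros(rec.n_samples)
        for p in gt.true_rpeak_samples:
            train[p - half:p + half + 1] += tpl
        worst = np.argmax(gt.cardiac_mixing)
        before = abs(np.corrcoef(filtered.eeg[worst], train)[0, 1])
        after = abs(np.corrcoef(cleaned.eeg[worst], train)[0, 1])
        assert after <= 0.2 * before

    def test_no_cardiac_artifact_raises(self):
        cfg = SimConfig(n_channels=16, trials_per_block=20, n_blocks_xx=1,
                        n_blocks_xy=1, artifact_gain=0.0, her_var_sd_uv=0.0, seed=3)
        rec, _ = simulate_subject(cfg, Group.MCS, seed=3)
        with pytest.raises(CardiacComponentError):
            extract_ica_ecg(bandpass_filter(rec), seed=0)


class TestInterpolation:
    def test_channel_identical_to_neighbors_retained(self, rng):
        common = rng.normal(0, 1, 3000)
        eeg = np.tile(common, (16, 1))
        lay = hemispherical_layout(16)
        rec = Recording("p", Group.MCS, eeg, FS, lay)
        g = build_neighbor_graph(lay, 6.0)
        wc = weighted_neighbor_correlation(rec, g)
        assert np.nanmin(wc) > 0.999
        _, rep = interpolate_low_correlation_channels(rec, g)
        assert rep.interpolated_channels == []

    def test_inverse_distance_weighting_arithmetic(self, rng):
        """Two neighbours at 2 cm (r=0.9) and 4 cm (r=0.3) give a weighted
        mean of (0.9/2 + 0.3/4)/(1/2 + 1/4) = 0.70, below the 0.80 bar."""
        n = 20000
        z = rng.normal(0, 1, (3, n))
        # build signals with prescribed pairwise correlations to channel 0
        x0 = z[0]
        x1 = 0.9 * x0 + np.sqrt(1 - 0.9 ** 2) * z[1]
        x2 = 0.3 * x0 + np.sqrt(1 - 0.3 ** 2) * z[2]
        lay = SensorLayout(["c0", "c1", "c2"],
                           np.array([[0.0, 0, 0], [2.0, 0, 0], [-4.0, 0, 0]]))
        rec = Recording("p", Group.MCS, np.vstack([x0, x1, x2]), FS, lay)
        g = build_neighbor_graph(lay, 4.0)
        wc = weighted_neighbor_correlation(rec, g, weighting="inverse")
        expect = (0.9 / 2 + 0.3 / 4) / (1 / 2 + 1 / 4)
        assert abs(wc[0] - expect) < 0.02

    def test_noise_channel_interpolated(self, rng):
        common = rng.normal(0, 1, (1, 4000))
        eeg = common + rng.normal(0, 0.2, (32, 4000))
        eeg[5] = rng.normal(0, 1, 4000)  # replace with independent noise
        lay = hemispherical_layout(32)
        rec = Recording("p", Group.MCS, eeg, FS, lay)
        g = build_neighbor_graph(lay, 6.0)
        out, rep = interpolate_low_correlation_channels(rec, g)
        assert "E6" in rep.interpolated_channels
        # interpolated channel now tracks the common signal
        assert np.corrcoef(out.eeg[5], common[0])[0, 1] > 0.8


class TestRereference:
    def test_column_means_zero(self, rng):
        rec = _rec(rng.normal(3.0, 5.0, (16, 2000)))
        out = rereference_and_subset(rec)
        assert np.abs(out.eeg.mean(axis=0)).max() < 1e-9

    def test_idempotent(self, rng):
        rec = _rec(rng.normal(0, 5.0, (16, 2000)))
        once = rereference_and_subset(rec)
        twice = rereference_and_subset(once)
        assert np.allclose(once.eeg, twice.eeg, atol=1e-12)

    def test_subset_order_and_size(self, rng):
        rec = _rec(rng.normal(0, 1, (70, 1000)))
        subset = [f"E{i + 1}" for i in range(64)]
        out = rereference_and_subset(rec, subset)
        assert out.layout.names == subset
        assert out.eeg.shape == (64, 1000)

    def test_missing_subset_channel_named(self, rng):
        rec = _rec(rng.normal(0, 1, (8, 500)))
        with pytest.raises(ValueError, match="E99"):
            rereference_and_subset(rec, ["E1", "E99"])
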