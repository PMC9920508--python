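"""Tests for R-peak detection, pulse-wave feature points and PTT extraction."""

import numpy as np
import pytest

from pttbp.detect import (
    BeatAnnotation,
    QualityFlag,
    compute_ptt,
    detect_mic_features,
    detect_r_peaks,
)
from pttbp.preprocess import MIC_BAND, FilterSpec, bandpass
from pttbp.synthetic_data import (
    DEFAULT_ECG_NOISE,
    DEFAULT_MIC_NOISE,
    ChannelNoise,
    ScenarioSpec,
    generate_ecg,
    generate_mic,
)

FS = 1000.0


class TestDetectRPeaks:
    def test_clean_record_all_peaks_within_5ms(self):
        sc = ScenarioSpec(duration=10.0)
        ecg, r_times = generate_ecg(sc)
        peaks = detect_r_peaks(ecg, FS)
        assert len(peaks) == 10
        assert np.all(np.abs(peaks / FS - r_times) <= 0.005)

    def test_flat_signal_yields_no_peaks(self):
        assert detect_r_peaks(np.zeros(5000), FS).size == 0

    def test_noisy_record_matches_clean_count_and_timing(self):
        sc = ScenarioSpec(duration=10.0)
        _, r_times = generate_ecg(sc)
        noisy_sc = ScenarioSpec(
            duration=10.0, ecg_noise=ChannelNoise(white=0.11), random_seed=1
        )  # white sigma = 10% of the 1.1 mV R amplitude
        ecg, _ = generate_ecg(noisy_sc)
        peaks = detect_r_peaks(ecg, FS)
        assert len(peaks) == len(r_times)
        assert np.all(np.abs(peaks / FS - r_times) <= 0.005)

    def test_refractory_period_enforced(self):
        sc = ScenarioSpec(duration=20.0, heart_rate=100.0, ptt1=0.2, ptt2=0.27)
        ecg, _ = generate_ecg(sc)
        peaks = detect_r_peaks(ecg, FS)
        assert np.all(np.diff(peaks) >= 0.25 * FS)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(500), FS)


class TestDetectMicFeatures:
    def test_programmed_beat_annotated_at_exact_offsets(self):
        sc = ScenarioSpec(
            duration=3.0, heart_rate=30.0, first_beat_time=1.0, ptt1=0.222, ptt2=0.292
        )
        mic = generate_mic([1.0], sc)
        (ann,) = detect_mic_features(mic, FS, [1000])
        assert ann.quality_flag is QualityFlag.OK
        assert ann.mic_neg_index == 1222
        assert ann.mic_pos_index == 1292

    def test_all_zero_channel_flagged_no_feature(self):
        anns = detect_mic_features(np.zeros(5000), FS, [500, 1500])
        assert all(a.quality_flag is QualityFlag.NO_MIC_FEATURE for a in anns)

    def test_equal_minima_take_earlier_index(self):
        mic = np.zeros(2000)
        mic[1200] = -1.0
        mic[1300] = -1.0
        mic[1350] = 0.5
        (ann,) = detect_mic_features(mic, FS, [1000])
        assert ann.mic_neg_index == 1200

    def test_extremum_on_window_boundary_flagged(self):
        mic = np.zeros(2000)
        mic[1100] = -1.0  # exactly at r + t_min
        mic[1200] = 0.5
        (ann,) = detect_mic_features(mic, FS, [1000])
        assert ann.quality_flag is QualityFlag.OUT_OF_BOUNDS

    def test_empty_r_peaks_empty_annotations(self):
        assert detect_mic_features(np.zeros(3000), FS, []) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            detect_mic_features(np.zeros(3000), FS, [1000], window=(0.5, 0.1))

    def test_annotation_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            BeatAnnotation(r_index=100, mic_neg_index=90, mic_pos_index=120)


class TestComputePTT:
    def test_sample_arithmetic(self):
        ann = BeatAnnotation(r_index=1000, mic_neg_index=1222, mic_pos_index=1292)
        series = compute_ptt([ann], FS)
        assert series.ptt1[0] == pytest.approx(0.222)
        assert series.ptt2[0] == pytest.approx(0.292)
        assert series.beat_time[0] == pytest.approx(1.0)

    def test_bounds_filter_drops_short_ptt1(self):
        ann = BeatAnnotation(r_index=1000, mic_neg_index=1050, mic_pos_index=1292)
        assert len(compute_ptt([ann], FS)) == 0

    def test_flagged_beats_dropped(self):
        ann = BeatAnnotation(r_index=1000, quality_flag=QualityFlag.NO_MIC_FEATURE)
        assert len(compute_ptt([ann], FS)) == 0

    def test_empty_in_empty_out(self):
        assert len(compute_ptt([], FS)) == 0


def _recover_ptts(scenario, subject=None):
    """Run the full detect path (band-passed channels) on a scenario."""
    ecg, r_times = generate_ecg(scenario)
    mic = generate_mic(scenario.r_times(), scenario, subject)
    ecg_f = bandpass(ecg, FS, FilterSpec(5.0, 40.0, order=2))
    mic_f = bandpass(mic, FS, FilterSpec(*MIC_BAND))
    peaks = detect_r_peaks(ecg_f, FS)
    anns = detect_mic_features(mic_f, FS, peaks)
    return r_times, compute_ptt(anns, FS)


class TestEndToEndRecovery:
    def test_clean_round_trip_100_beats_within_2ms(self):
        """>= 100 seeded clean beats spanning ptt1 in [0.15, 0.35] s all
        recover their programmed transit times within +/- 2 ms."""
        rng = np.random.default_rng(42)
        sc_probe = ScenarioSpec(duration=101.0)
        n = len(sc_probe.r_times())
        assert n >= 100
        ptt1 = rng.uniform(0.15, 0.35, n)
        ptt2 = ptt1 + rng.uniform(0.05, 0.12, n)
        sc = ScenarioSpec(duration=101.0, ptt1=ptt1, ptt2=ptt2)
        r_times, series = _recover_ptts(sc)
        assert len(series) == n
        order = np.abs(series.beat_time[:, None] - r_times[None, :]).argmin(axis=1)
        assert np.all(np.abs(series.ptt1 - ptt1[order]) <= 0.002)
        assert np.all(np.abs(series.ptt2 - ptt2[order]) <= 0.002)

    def test_default_noise_round_trip_95_percent_within_2ms(self):
        rng = np.random.default_rng(43)
        sc_probe = ScenarioSpec(duration=101.0)
        n = len(sc_probe.r_times())
        ptt1 = rng.uniform(0.15, 0.35, n)
        ptt2 = ptt1 + rng.uniform(0.05, 0.12, n)
        sc = ScenarioSpec(
            duration=101.0,
            ptt1=ptt1,
            ptt2=ptt2,
            ecg_noise=DEFAULT_ECG_NOISE,
            mic_noise=DEFAULT_MIC_NOISE,
            random_seed=7,
        )
        r_times, series = _recover_ptts(sc)
        order = np.abs(series.beat_time[:, None] - r_times[None, :]).argmin(axis=1)
        good = (np.abs(series.ptt1 - ptt1[order]) <= 0.002) & (
            np.abs(series.ptt2 - ptt2[order]) <= 0.002
        )
        assert good.sum() >= 0.95 * n

    def test_beat_times_strictly_increasing(self):
        sc = ScenarioSpec(duration=20.0)
        _, series = _recover_ptts(sc)
        assert np.all(np.diff(series.beat_time) > 0)
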