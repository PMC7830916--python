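"""Signal-cleaning operators: conversion, motion handling, filtering."""

import numpy as np
import pytest

import nirsnet as nn
from nirsnet.preprocess import (
    bandpass_array,
    detect_motion_array,
    detrend_poly_array,
    spline_correct_array,
    wavelet_filter_array,
)
from nirsnet.series import ArtifactMask, HemoglobinSeries, RawIntensitySeries

FS = 8.7


def make_series(data, fs=FS):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return HemoglobinSeries(hbo=data, hbr=-0.7 * data, sampling_rate=fs)


class TestOpticalConversion:
    def test_constant_intensity_gives_zero_od(self):
        raw = RawIntensitySeries(np.full((2, 100, 3), 5.0), FS)
        od = nn.intensity_to_od(raw)
        np.testing.assert_allclose(od.data, 0.0, atol=1e-12)

    def test_tenfold_intensity_gives_od_minus_one(self):
        data = np.ones((1, 100, 3))
        data[0, 50, :] = 10.0
        # reference is the temporal mean, so compute expected directly
        raw = RawIntensitySeries(data, FS)
        od = nn.intensity_to_od(raw)
        expected = -np.log10(data[0, 50, 0] / data[0, :, 0].mean())
        assert od.data[0, 50, 0] == pytest.approx(expected)
        assert od.data[0, 50, 0] < -0.9  # ~ -1 up to the mean shift

    def test_sinusoidal_intensity_od_mean_near_zero(self):
        t = np.arange(1000) / FS
        data = 5.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t)
        raw = RawIntensitySeries(np.tile(data, (1, 1, 3)).reshape(1, -1, 3), FS)
        od = nn.intensity_to_od(raw)
        assert abs(od.data.mean()) < 1e-4

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            RawIntensitySeries(np.zeros((1, 10, 3)), FS)

    def test_mbll_round_trip_recovers_concentrations(self, rng):
        from nirsnet.preprocess import DEFAULT_DPF, EXTINCTION_MM_CM

        hbo = rng.normal(0, 1.0, 200)
        hbr = rng.normal(0, 0.5, 200)
        eps = np.array([EXTINCTION_MM_CM[w] for w in (780.0, 805.0, 830.0)])
        A = eps * 3.0 * np.asarray(DEFAULT_DPF)[:, None]
        od_data = (np.column_stack([hbo, hbr]) @ A.T)[None, :, :]
        od = nn.OpticalDensitySeries(od_data, FS)
        hemo = nn.od_to_hemoglobin(od)
        np.testing.assert_allclose(hemo.hbo[0], hbo, atol=1e-10)
        np.testing.assert_allclose(hemo.hbr[0], hbr, atol=1e-10)

    def test_mbll_hbo_only_signal_gives_zero_hbr(self):
        from nirsnet.preprocess import DEFAULT_DPF, EXTINCTION_MM_CM

        eps = np.array([EXTINCTION_MM_CM[w] for w in (780.0, 805.0, 830.0)])
        A = eps * 3.0 * np.asarray(DEFAULT_DPF)[:, None]
        hbo = np.sin(np.linspace(0, 6, 100))
        od_data = (np.column_stack([hbo, np.zeros(100)]) @ A.T)[None, :, :]
        hemo = nn.od_to_hemoglobin(nn.OpticalDensitySeries(od_data, FS))
        np.testing.assert_allclose(hemo.hbr[0], 0.0, atol=1e-10)

    def test_zero_od_gives_zero_concentration(self):
        hemo = nn.od_to_hemoglobin(nn.OpticalDensitySeries(np.zeros((2, 50, 3)), FS))
        np.testing.assert_allclose(hemo.hbo, 0.0)
        np.testing.assert_allclose(hemo.hbr, 0.0)


class TestTrim:
    def test_trim_30s_of_8min_recording(self):
        series = make_series(np.zeros((48, 4176)))
        out = nn.trim_edges(series, 30.0)
        assert out.n_samples == 3654  # 4176 − 2·round(30·8.7)

    def test_zero_trim_is_noop(self):
        series = make_series(np.arange(100.0))
        out = nn.trim_edges(series, 0.0)
        np.testing.assert_array_equal(out.hbo, series.hbo)

    def test_too_short_recording_rejected(self):
        series = make_series(np.zeros(int(50 * FS)))
        with pytest.raises(ValueError):
            nn.trim_edges(series, 30.0)


class TestMotionDetection:
    def test_flat_signal_gives_empty_mask(self):
        mask = detect_motion_array(np.zeros((3, 200)), FS)
        assert not mask.mask.any()

    def test_step_flagged(self):
        x = np.zeros((1, 400))
        x[0, 200:] = 0.5
        mask = detect_motion_array(x, FS, amp_thresh=0.1)
        w = int(round(FS))
        assert mask.mask[0, 195:205].any()
        # flagged region is local to the step, not the whole record
        assert not mask.mask[0, : 200 - 3 * w].any()

    def test_injected_spikes_detected_on_generator_output(self, montage):
        config = nn.CohortConfig(n_asd=2, n_td=1, duration=240.0, seed=31,
                                 artifact_rate=4.0)
        subjects, truth = nn.simulate_cohort(config, montage)
        hits = total = 0
        for s in subjects:
            n0 = len(truth.artifact_log)
            rec = nn.simulate_recording(s, montage, config, truth)
            events = truth.artifact_log[n0:]
            mask = nn.detect_motion(rec)
            fs = rec.sampling_rate
            for ev in events:
                if ev.kind != "spike":
                    continue
                total += 1
                i0 = int(ev.onset * fs)
                i1 = int((ev.onset + ev.duration) * fs) + 1
                window = mask.mask[:, i0:i1]
                if window.any(axis=1).mean() >= 0.5:
                    hits += 1
        assert total >= 5
        assert hits / total >= 0.9


class TestSplineCorrection:
    def test_empty_mask_is_noop(self, rng):
        x = rng.normal(size=(2, 300))
        out = spline_correct_array(x, np.zeros_like(x, dtype=bool), FS)
        np.testing.assert_array_equal(out, x)

    def test_step_artifact_amplitude_reduced(self):
        n = 600
        t = np.arange(n) / FS
        clean = np.sin(2 * np.pi * 0.03 * t)
        x = clean.copy()
        x[300:330] += 5.0  # boxcar artifact inside the mask
        mask = np.zeros((1, n), dtype=bool)
        mask[0, 295:335] = True
        out = spline_correct_array(x[None, :], mask, FS)[0]
        step_before = np.max(np.abs(np.diff(x[290:340])))
        step_after = np.max(np.abs(np.diff(out[290:340])))
        assert step_after <= 0.2 * step_before

    def test_segment_boundaries_continuous(self):
        n = 500
        x = np.full(n, 1.0)
        bump = 3.0 * np.sin(np.linspace(0, np.pi, 40))
        x[200:240] += bump  # artifact entirely inside the mask
        mask = np.zeros((1, n), dtype=bool)
        mask[0, 198:242] = True
        out = spline_correct_array(x[None, :], mask, FS)[0]
        sd = x.std()
        assert abs(out[198] - out[197]) < 0.01 * sd
        assert abs(out[241] - out[242]) < 0.01 * sd
        # unmasked samples untouched
        np.testing.assert_array_equal(out[:198], x[:198])
        np.testing.assert_array_equal(out[242:], x[242:])

    def test_fully_masked_channel_rejected(self):
        x = np.zeros((1, 100))
        with pytest.raises(ValueError):
            spline_correct_array(x, np.ones_like(x, dtype=bool), FS)


class TestWaveletFilter:
    def test_low_frequency_sinusoid_preserved(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = wavelet_filter_array(x, FS, alpha=0.1)
        r = np.corrcoef(out[0], x[0])[0, 1]
        assert r >= 0.99

    def test_isolated_spike_suppressed(self):
        t = np.arange(2000) / FS
        base = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        x = base.copy()
        x[1000] += 5.0  # single-sample impulse
        out = wavelet_filter_array(x[None, :], FS, alpha=0.1)[0]
        resid = out - base
        assert np.abs(resid[990:1010]).max() <= 0.1 * 5.0

    def test_alpha_zero_is_identity(self, rng):
        x = rng.normal(size=(2, 512))
        out = wavelet_filter_array(x, FS, alpha=0.0)
        np.testing.assert_allclose(out, x, atol=1e-10)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,lo,hi",
        [(0.05, 0.9, 1.1), (0.2, 0.0, 0.1)],
        ids=["passband_tone", "stopband_tone"],
    )
    def test_tone_gains(self, freq, lo, hi):
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)[None, :]
        out = bandpass_array(x, FS)
        # measure gain away from filter edge transients
        core = slice(len(t) // 4, 3 * len(t) // 4)
        gain = out[0, core].std() / x[0, core].std()
        assert lo <= gain <= (hi if hi > 0 else np.inf)
        if hi:
            assert gain <= hi

    def test_constant_signal_removed(self):
        x = np.full((1, 2000), 3.7)
        out = bandpass_array(x, FS)
        assert np.abs(out).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_array(np.zeros((1, 100)), FS, low=0.1, high=5.0)


class TestDetrendAndBaseline:
    def test_cubic_annihilated(self):
        t = np.linspace(-1, 1, 500)
        x = (2.0 + t - 3.0 * t**2 + 0.5 * t**3)[None, :]
        out = detrend_poly_array(x, order=3)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_sinusoid_survives_detrending(self):
        t = np.arange(3000) / FS
        sine = np.sin(2 * np.pi * 0.05 * t)
        x = (sine + 0.001 * t**3 - 0.01 * t**2)[None, :]
        out = detrend_poly_array(x, order=3)
        assert np.corrcoef(out[0], sine)[0, 1] >= 0.99

    def test_order_zero_removes_mean(self, rng):
        x = rng.normal(5.0, 1.0, size=(3, 200))
        out = detrend_poly_array(x, order=0)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)

    def test_baseline_correction_zeroes_first_sample_and_is_idempotent(self, rng):
        series = make_series(rng.normal(size=(4, 100)))
        once = nn.baseline_correct(series)
        np.testing.assert_allclose(once.hbo[:, 0], 0.0)
        np.testing.assert_allclose(once.hbr[:, 0], 0.0)
        twice = nn.baseline_correct(once)
        np.testing.assert_array_equal(twice.hbo, once.hbo)


class TestArtifactFraction:
    @pytest.mark.parametrize(
        "fill,expected", [(False, 0.0), (True, 100.0)], ids=["empty", "full"]
    )
    def test_extremes(self, fill, expected):
        mask = ArtifactMask(np.full((4, 100), fill))
        assert nn.artifact_fraction(mask) == expected

    def test_half_masked(self):
        m = np.zeros((2, 100), dtype=bool)
        m[:, :50] = True
        assert nn.artifact_fraction(ArtifactMask(m)) == pytest.approx(50.0)


class TestFullChain:
    def test_chain_preserves_band_limited_ground_truth(self, montage):
        """On artifact-free input the cleaned signal must track the
        band-limited latent signal (correlation ≥ 0.95)."""
        config = nn.CohortConfig(
            n_asd=1, n_td=1, duration=480.0, seed=41, artifact_rate=0.0,
            noise=nn.NoiseSpec(pink=0.0, cardiac=0.4, respiratory=0.3,
                               mayer=0.0, white=0.05),
        )
        subjects, truth = nn.simulate_cohort(config, montage)
        series = nn.simulate_subject_series(subjects[0], montage, config, truth)
        result = nn.clean_series(series)
        # ground truth: the noiseless latent component (same seed, zero noise
        # amplitudes) processed with the same trim + band-pass
        clean_cfg = nn.CohortConfig(
            n_asd=1, n_td=1, duration=480.0, seed=41, artifact_rate=0.0,
            noise=nn.NoiseSpec(pink=0, cardiac=0, respiratory=0, mayer=0, white=0),
        )
        clean_subjects, clean_truth = nn.simulate_cohort(clean_cfg, montage)
        latent = nn.simulate_subject_series(
            clean_subjects[0], montage, clean_cfg, clean_truth
        )
        truth_band = bandpass_array(
            nn.trim_edges(latent, 30.0).hbo, latent.sampling_rate
        )
        r = [
            np.corrcoef(result.series.hbo[c], truth_band[c])[0, 1]
            for c in range(4)
        ]
        assert min(r) >= 0.95

    def test_chain_is_shape_preserving_and_finite(self, mini_cohort, montage):
        config, subjects, truth = mini_cohort
        series = nn.simulate_recording(subjects[0], montage, config, truth)
        result = nn.clean_series(series, nn.PreprocessConfig(trim_s=10.0))
        expected = series.n_samples - 2 * int(round(10.0 * series.sampling_rate))
        assert result.series.hbo.shape == (48, expected)
        assert np.all(np.isfinite(result.series.hbo))
        assert 0.0 <= result.artifact_percent <= 100.0
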