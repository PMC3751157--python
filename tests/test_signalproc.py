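"""Signal processing: baseline, noise center, peaks, spectral separation,
artifact classification, lane finding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strexpert import (ColorMatrices, Peak, RawTrace, SpectralError,
                       apply_color_correction, classify_artifacts,
                       estimate_color_matrix, estimate_noise_center,
                       find_lane_centers, find_peaks, subtract_baseline)
from strexpert.simulate import default_bleed_matrix


def gaussian_trace(specs, n=2000, channel_count=4):
    """specs: list of (channel, apex_scan, height, fwhm_scans)."""
    y = np.zeros((channel_count, n))
    x = np.arange(n)
    for ch, apex, h, fwhm in specs:
        sigma = fwhm / 2.3548
        y[ch] += h * np.exp(-0.5 * ((x - apex) / sigma) ** 2)
    return RawTrace(y)


def brute_force_baseline(channels, window):
    half = window // 2
    out = np.empty_like(channels)
    n = channels.shape[1]
    for ch in range(channels.shape[0]):
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[ch, i] = channels[ch, i] - channels[ch, lo:hi].min()
    return out


class TestBaseline:
    def test_constant_trace_goes_to_zero(self):
        trace = RawTrace(np.full((4, 100), 37.0))
        out = subtract_baseline(trace, 5)
        assert np.all(out.channels == 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), window=st.sampled_from([1, 3, 5, 9, 51]))
    def test_matches_brute_force_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 500, size=(4, 200))
        got = subtract_baseline(RawTrace(y), window).channels
        assert np.array_equal(got, brute_force_baseline(y, window))

    def test_idempotent_when_window_min_zero(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 100, size=(4, 300))
        once = subtract_baseline(RawTrace(y), 5)
        twice = subtract_baseline(once, 5)
        zero_min = brute_force_baseline(once.channels, 5) == once.channels
        assert np.array_equal(twice.channels[zero_min], once.channels[zero_min])

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_rejects_even_or_nonpositive_window(self, window):
        with pytest.raises(ValueError):
            subtract_baseline(RawTrace(np.zeros((4, 10))), window)

    def test_rejects_window_longer_than_trace(self):
        with pytest.raises(ValueError):
            subtract_baseline(RawTrace(np.zeros((4, 10))), 11)


class TestNoiseCenter:
    def test_symmetric_noise_centers_near_zero(self):
        rng = np.random.default_rng(1)
        trace = RawTrace(rng.normal(0, 10, size=(4, 5000)))
        se = 10 / np.sqrt(5000)
        assert abs(estimate_noise_center(trace, 0)) < 3 * 1.2533 * se

    def test_peaks_do_not_shift_center(self, rules):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 8, size=(4, 4000))
        baseline_center = np.median(noise[0])
        trace = gaussian_trace([(0, 500, 2000, 6), (0, 1500, 3000, 6),
                                (0, 2500, 1500, 6)], n=4000)
        trace.channels += noise
        peaks = find_peaks(trace, rules)
        center = estimate_noise_center(trace, 0, peaks)
        assert abs(center - baseline_center) < 1.0

    def test_all_zero_trace(self):
        assert estimate_noise_center(RawTrace(np.zeros((4, 100))), 0) == 0.0

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            estimate_noise_center(RawTrace(np.zeros((4, 0))), 0)


class TestFindPeaks:
    def test_analytical_threshold_is_strict(self, rules):
        at = rules.analytical_threshold_rfu
        excluded = find_peaks(gaussian_trace([(0, 500, at, 6)]), rules)
        retained = find_peaks(gaussian_trace([(0, 500, at + 1, 6)]), rules)
        assert excluded == []
        assert len(retained) == 1 and retained[0].apex_scan == 500

    def test_all_zero_trace_is_empty(self, rules):
        assert find_peaks(RawTrace(np.zeros((4, 500))), rules) == []

    def test_recovers_known_apexes(self, rules):
        truth = [(0, 300, 900, 6), (0, 900, 1200, 6), (1, 1500, 600, 6)]
        peaks = find_peaks(gaussian_trace(truth), rules)
        assert len(peaks) == 3
        for (ch, apex, h, _), p in zip(sorted(truth, key=lambda t: t[1]), peaks):
            assert p.channel == ch and abs(p.apex_scan - apex) <= 1
            assert abs(p.height - h) / h < 0.05

    def test_count_monotone_in_threshold(self, rules):
        rng = np.random.default_rng(3)
        specs = [(0, int(s), float(h), 6.0)
                 for s, h in zip(rng.uniform(100, 1900, 12),
                                 rng.uniform(100, 2000, 12))]
        trace = gaussian_trace(specs)
        counts = []
        for at in [50, 150, 400, 800, 1500]:
            r = rules.model_copy(update={"analytical_threshold_rfu": float(at),
                                         "het_min_rfu": float(at) + 200})
            counts.append(len(find_peaks(trace, r)))
        assert counts == sorted(counts, reverse=True)


class TestSpectralSeparation:
    def test_pure_dyes_give_identity(self, rules):
        specs = [(ch, 300 + 400 * ch, 1000, 6) for ch in range(4)]
        trace = gaussian_trace(specs)
        m = estimate_color_matrix(trace, find_peaks(trace, rules))
        assert np.allclose(m.ratio_matrix, np.eye(4), atol=1e-9)

    def test_recovers_known_bleed_matrix(self, rules):
        bleed = default_bleed_matrix()
        pure = gaussian_trace([(ch, 250 + 350 * ch + 40 * k, 1200, 6)
                               for ch in range(4) for k in range(3)])
        mixed = RawTrace(bleed @ pure.channels)
        m = estimate_color_matrix(mixed, find_peaks(mixed, rules))
        assert np.allclose(m.ratio_matrix, bleed, atol=1e-6)
        recovered = apply_color_correction(mixed, m)
        assert np.allclose(recovered.channels, pure.channels, atol=1e-6)

    def test_correction_inverts_ratio_matrix(self, rules):
        bleed = default_bleed_matrix()
        pure = gaussian_trace([(ch, 300 + 400 * ch, 1000, 6) for ch in range(4)])
        mixed = RawTrace(bleed @ pure.channels)
        m = estimate_color_matrix(mixed, find_peaks(mixed, rules))
        assert np.allclose(m.correction_matrix @ m.ratio_matrix, np.eye(4),
                           atol=1e-8)

    def test_identity_correction_is_noop(self):
        trace = gaussian_trace([(0, 500, 800, 6)])
        m = ColorMatrices(np.eye(4), np.eye(4))
        assert np.array_equal(apply_color_correction(trace, m).channels,
                              trace.channels)

    def test_zero_trace_stays_zero(self):
        m = ColorMatrices.from_ratio(default_bleed_matrix())
        out = apply_color_correction(RawTrace(np.zeros((4, 50))), m)
        assert np.all(out.channels == 0)

    def test_insufficient_diversity_raises(self, rules):
        trace = gaussian_trace([(0, 400, 1000, 6), (0, 900, 900, 6)])
        with pytest.raises(SpectralError, match="spectral diversity"):
            estimate_color_matrix(trace, find_peaks(trace, rules))


class TestClassifyArtifacts:
    def test_two_scan_peak_is_spike(self, rules):
        peaks = [Peak(0, 100, 500, 2.0, span_scans=2)]
        assert "spike" in classify_artifacts(peaks, rules, 6.0)[0].flags

    def test_three_scan_peak_is_not_spike(self, rules):
        peaks = [Peak(0, 100, 500, 3.0, span_scans=3)]
        assert "spike" not in classify_artifacts(peaks, rules, 6.0)[0].flags

    def test_wide_peak_is_dye_blob(self, rules):
        peaks = [Peak(0, 100, 500, 2.5 * 6.0, span_scans=15)]
        assert "dye_blob" in classify_artifacts(peaks, rules, 6.0)[0].flags

    def test_nominal_width_is_clean(self, rules):
        peaks = [Peak(0, 100, 500, 6.0, span_scans=6)]
        assert classify_artifacts(peaks, rules, 6.0)[0].flags == set()

    def test_pull_up_from_coincident_tall_peak(self, rules):
        peaks = [Peak(0, 100, 100.0 * rules.pullup_height_multiple, 6.0,
                      span_scans=6),
                 Peak(1, 101, 100.0, 6.0, span_scans=6)]
        out = classify_artifacts(peaks, rules, 6.0)
        assert "pull_up" in out[1].flags and "pull_up" not in out[0].flags


class TestLaneFinding:
    @staticmethod
    def triangle_waveform(centers, n=600, halfwidth=20):
        y = np.zeros(n)
        x = np.arange(n)
        for c in centers:
            y += np.clip(1 - np.abs(x - c) / halfwidth, 0, None)
        return y

    def test_six_clean_lanes(self):
        centers = [50, 150, 250, 350, 450, 550]
        assert find_lane_centers(self.triangle_waveform(centers), 6) == centers

    def test_noisy_lanes_within_one_sample(self):
        centers = [50, 150, 250, 350, 450, 550]
        rng = np.random.default_rng(4)
        y = self.triangle_waveform(centers) + rng.normal(0, 0.1, 600)
        found = find_lane_centers(y, 6)
        assert all(abs(f - c) <= 1 for f, c in zip(found, centers))

    def test_single_lane(self):
        assert find_lane_centers(self.triangle_waveform([300]), 1) == [300]

    def test_too_few_features_raises(self):
        with pytest.raises(ValueError, match="detectable"):
            find_lane_centers(self.triangle_waveform([300]), 3)
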