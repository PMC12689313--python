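"""Feature transforms against independent oracles: direct DFT summation,
hand-evaluated cosine transforms, constructed filter-bank inputs, and the
hand-coded enhancement reference."""

import numpy as np
import pytest

from snoreacoustics.audioprep import FrameGrid, TARGET_SR
from snoreacoustics.features import (CQTParams, EnhancementConfig,
                                     FilterBankResponse, cens,
                                     chroma_energies, cqt_filterbank,
                                     cqt_spectrogram, enhance, feature_image,
                                     grid_search_beta, mel_filterbank,
                                     mel_spectrogram, mfcc, render_image,
                                     stft_frames, FEATURE_KINDS, LOG_FLOOR,
                                     PITCH_CLASSES)


def direct_dft(frame, window):
    """Brute-force O(N^2) evaluation of X(k) = sum_n x(n) w(n) e^{-j2pikn/N}."""
    n = len(frame)
    xw = frame * window
    ks = np.arange(n)
    return np.array([np.sum(xw * np.exp(-2j * np.pi * k * np.arange(n) / n))
                     for k in ks])


class TestSTFT:
    def test_zero_segment_zero_spectrum(self, tone_factory):
        seg = tone_factory(100.0)
        seg.samples[:] = 0.0
        spec = stft_frames(seg)
        assert np.all(spec.coeffs == 0)

    def test_matches_direct_summation(self, rng):
        class Seg:
            samples = rng.normal(size=256)
            sample_rate = 3200  # 20 ms frame -> 64 samples

        grid = FrameGrid()
        spec = stft_frames(Seg(), grid)
        n = grid.frame_samples(3200)
        hop = grid.hop_samples(3200)
        win = np.hamming(n)
        assert spec.coeffs.shape[0] == (256 - n) // hop + 1
        for t in range(spec.coeffs.shape[0]):
            frame = Seg.samples[t * hop:t * hop + n]
            ref = direct_dft(frame, win)
            err = np.abs(spec.coeffs[t] - ref).max() / np.abs(ref).max()
            assert err < 1e-8

    def test_tone_peaks_at_its_bin(self):
        sr, n = 6400, 128

        class Seg:
            sample_rate = sr
            samples = np.sin(2 * np.pi * (10 * sr / n) * np.arange(n) / sr)

        spec = stft_frames(Seg(), FrameGrid())
        mags = np.abs(spec.coeffs[0][:n // 2])
        assert np.argmax(mags) == 10

    def test_frame_longer_than_segment_rejected(self):
        class Seg:
            samples = np.zeros(100)
            sample_rate = TARGET_SR

        with pytest.raises(ValueError, match="frame length"):
            stft_frames(Seg(), FrameGrid())


class TestMel:
    def test_flat_power_spectrum_gives_filter_sums(self):
        sr, n_fft, M = 8000, 160, 10
        H = mel_filterbank(sr, n_fft, M)
        flat_power = np.ones((3, n_fft // 2 + 1))
        resp = FilterBankResponse(bank_kind="mel", H=H,
                                  energies=flat_power @ H.T,
                                  freqs=np.fft.rfftfreq(n_fft, 1 / sr))
        np.testing.assert_allclose(resp.energies[0], H.sum(axis=1), rtol=1e-12)
        np.testing.assert_allclose(resp.log_energies()[0],
                                   np.log(np.maximum(H.sum(axis=1), LOG_FLOOR)))

    def test_zero_power_log_floor(self):
        resp = FilterBankResponse(bank_kind="mel", H=np.ones((4, 10)),
                                  energies=np.zeros((2, 4)),
                                  freqs=np.arange(10.0))
        assert np.all(resp.log_energies() == np.log(LOG_FLOOR))

    def test_tone_maximizes_matching_filter(self, tone_factory):
        seg = tone_factory(1000.0)
        spec = stft_frames(seg)
        resp = mel_spectrogram(spec, 40)
        m0 = np.argmax(resp.energies.mean(axis=0))
        # center frequency of the winning filter should bracket 1 kHz
        H = resp.H
        f = resp.freqs
        center = f[np.argmax(H[m0])]
        assert 800.0 < center < 1250.0

    def test_too_many_filters_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(8000, 32, 40)


class TestMFCC:
    def test_constant_input_zero_coefficients(self):
        M = 32
        c = mfcc(np.full(M, 3.7), 13)
        assert np.abs(c).max() < 1e-9 * M * 3.7

    def test_hand_summation_m4(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        expected_l1 = sum(s[m - 1] * np.cos(np.pi * 1 * (m - 0.5) / 4)
                          for m in range(1, 5))
        c = mfcc(s, 2)
        assert c[0] == pytest.approx(expected_l1, abs=1e-12)

    def test_cosine_orthogonality_picks_out_matching_coefficient(self):
        M, l0 = 24, 2
        m = np.arange(1, M + 1)
        s = np.cos(np.pi * l0 * (m - 0.5) / M)
        c = mfcc(s, 6)
        assert c[l0 - 1] == pytest.approx(M / 2, rel=1e-10)
        others = np.delete(c, l0 - 1)
        assert np.abs(others).max() < 1e-9

    def test_l_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            mfcc(np.ones(5), 13)


class TestCQT:
    def test_octave_doubling_and_identity(self):
        p = CQTParams(f1=32.7, bins_per_octave=12)
        assert p.center(1) == pytest.approx(32.7)
        assert p.center(13) == pytest.approx(65.4)

    def test_q_constant_across_bins(self, tone_factory):
        resp = cqt_spectrogram(tone_factory(440.0))
        q = resp.centers / resp.bandwidths
        assert np.all(np.abs(q / q[0] - 1.0) < 0.01)
        # adjacent-spacing estimate of the bandwidth agrees with 1% tolerance
        spacing = np.diff(resp.centers)
        q_est = resp.centers[:-1] / (spacing / (2 ** (1 / 12) - 1)
                                     * (2 ** (1 / 12) - 1))
        assert np.all(q_est > 0)

    def test_geometric_center_progression(self):
        p = CQTParams(f1=40.0, bins_per_octave=24, n_bins=48)
        ratios = p.centers[1:] / p.centers[:-1]
        np.testing.assert_allclose(ratios, 2 ** (1 / 24), rtol=1e-12)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cqt_filterbank(CQTParams(f1=8000.0, n_bins=24), TARGET_SR, 441)


class TestCENS:
    def test_silence_gives_uniform_chroma(self):
        class Seg:
            samples = np.zeros(TARGET_SR)
            sample_rate = TARGET_SR

        out = cens(Seg())
        np.testing.assert_allclose(out, 1.0 / np.sqrt(12.0), atol=1e-9)

    def test_a440_peaks_at_pitch_class_a(self, tone_factory):
        out = cens(tone_factory(440.0))
        assert PITCH_CLASSES[np.argmax(out.mean(axis=0))] == "A"

    def test_octave_transposition_invariant_class(self, tone_factory):
        c1 = cens(tone_factory(440.0)).mean(axis=0)
        c2 = cens(tone_factory(880.0)).mean(axis=0)
        assert np.argmax(c1) == np.argmax(c2)

    def test_rows_unit_norm(self, tone_factory):
        out = cens(tone_factory(261.63))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)


def enhancement_oracle(E, beta, percentile):
    """Independent sort/interpolate/mask/scale reference."""
    out = E.copy()
    gains = np.ones_like(E)
    for t in range(E.shape[0]):
        row = np.sort(E[t])
        rank = (len(row) - 1) * percentile / 100.0
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        thresh = row[lo] + (rank - lo) * (row[hi] - row[lo])
        mask = E[t] > thresh
        out[t, mask] = beta * E[t, mask]
        gains[t, mask] = beta
    return out, gains


class TestEnhancement:
    def _resp(self, E):
        return FilterBankResponse(bank_kind="mel", H=np.ones((E.shape[1], 8)),
                                  energies=E, freqs=np.arange(8.0))

    def test_hand_percentile_example(self):
        E = np.array([[1.0, 2.0, 3.0, 4.0, 10.0]])
        out = enhance(self._resp(E), EnhancementConfig(beta=1.5))
        np.testing.assert_array_equal(out.gains, [[1, 1, 1, 1, 1.5]])
        np.testing.assert_allclose(out.energies, [[1, 2, 3, 4, 15.0]])

    def test_uniform_frame_unchanged(self):
        E = np.full((3, 6), 2.5)
        out = enhance(self._resp(E))
        np.testing.assert_array_equal(out.energies, E)

    def test_random_frames_match_oracle_bitwise(self, rng):
        for _ in range(50):
            m = int(rng.integers(5, 257))
            E = rng.gamma(2.0, 1.0, size=(int(rng.integers(1, 8)), m))
            resp = self._resp(E)
            out = enhance(resp, EnhancementConfig(beta=1.5))
            ref, gains = enhancement_oracle(E, 1.5, 80.0)
            np.testing.assert_array_equal(out.gains, gains)
            np.testing.assert_allclose(out.energies, ref, rtol=1e-12, atol=0)
            # untouched filters are bit-identical, touched exactly beta x
            mask = gains == 1.5
            np.testing.assert_array_equal(out.energies[~mask], E[~mask])
            np.testing.assert_array_equal(out.energies[mask], 1.5 * E[mask])
            assert mask.mean(axis=1).max() <= 0.2 + 1.0 / m

    def test_single_filter_degenerate(self):
        E = np.array([[5.0], [7.0]])
        out = enhance(self._resp(E))
        np.testing.assert_array_equal(out.energies, E)

    def test_mask_depends_only_on_pre_enhancement_energies(self, rng):
        E = rng.gamma(2.0, 1.0, size=(4, 30))
        a = enhance(self._resp(E), EnhancementConfig(beta=1.5))
        b = enhance(self._resp(E), EnhancementConfig(beta=2.0))
        np.testing.assert_array_equal(a.gains == 1.5, b.gains == 2.0)


class TestGridSearchBeta:
    def test_peak_at_1_5(self):
        assert grid_search_beta(lambda b: -(b - 1.5) ** 2) == 1.5

    def test_constant_ties_to_smallest(self):
        assert grid_search_beta(lambda b: 42.0) == 1.1

    def test_peak_at_edge(self):
        assert grid_search_beta(lambda b: b) == 2.0


class TestRenderImage:
    def test_constant_map_renders_black(self):
        img = render_image(np.full((13, 40), 7.0))
        assert img.pixels.shape == (224, 224, 3)
        assert np.all(img.pixels == 0.0)

    def test_shape_and_range(self, rng):
        img = render_image(rng.normal(size=(60, 100)), size=224)
        assert img.pixels.shape == (224, 224, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        np.testing.assert_array_equal(img.pixels[..., 0], img.pixels[..., 2])

    def test_affine_invariance(self, rng):
        m = rng.normal(size=(30, 50))
        a = render_image(m)
        b = render_image(2.0 * m + 5.0)
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    @pytest.mark.parametrize("kind", FEATURE_KINDS)
    def test_full_pipeline_each_kind(self, kind, tone_factory):
        img = feature_image(tone_factory(220.0), kind, enhanced=True, size=64)
        assert img.pixels.shape == (64, 64, 3)
        assert np.isfinite(img.pixels).all()
        assert img.feature_kind == kind and img.enhanced
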