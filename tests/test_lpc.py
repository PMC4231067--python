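"""LPC estimation: autocorrelation, Levinson-Durbin vs direct Yule-Walker,
spectra, the fitness factor, and parameter recovery on known all-pole filters."""

import numpy as np
import pytest
from scipy.linalg import solve_toeplitz
from scipy.signal import lfilter
from scipy.signal.windows import hamming

from pcgclassify import (
    InputError,
    LPCCoefficients,
    Spectrum,
    autocorrelate,
    extract_coefficients,
    extract_features,
    filter_spectrum,
    fitness_factor,
    levinson_durbin,
    signal_spectrum,
)


def random_stable_ar24(rng, rmin=0.5, rmax=0.8):
    """[1, a1..a24] with 12 well-separated conjugate pole pairs."""
    base = np.linspace(0.08, 0.92, 12) * np.pi
    angles = base + rng.uniform(-0.03, 0.03, 12) * np.pi
    radii = rng.uniform(rmin, rmax, 12)
    poles = np.concatenate(
        [radii * np.exp(1j * angles), radii * np.exp(-1j * angles)]
    )
    return np.real(np.poly(poles))


class TestAutocorrelate:
    def test_matches_brute_force_sum(self, rng):
        x = rng.standard_normal(400)
        xw = x * hamming(400, sym=False)
        r = autocorrelate(x, 10)
        brute = np.array([np.sum(xw[: 400 - k] * xw[k:]) for k in range(11)]) / 400
        np.testing.assert_allclose(r, brute, atol=1e-12)

    def test_white_noise_decorrelates(self, rng):
        x = rng.standard_normal(20000)
        r = autocorrelate(x, 24)
        w = hamming(20000, sym=False)
        assert r[0] == pytest.approx(np.mean(w**2), rel=0.05)
        assert np.all(np.abs(r[1:] / r[0]) < 0.1)

    def test_silent_segment_rejected(self):
        with pytest.raises(InputError):
            autocorrelate(np.zeros(100), 10)

    def test_short_segment_rejected(self):
        with pytest.raises(InputError, match="25"):
            autocorrelate(np.ones(20), 24)


class TestLevinsonDurbin:
    def test_first_order_by_hand(self):
        c = levinson_durbin(np.array([1.0, 0.5]), 1)
        assert c.a[0] == pytest.approx(-0.5)
        assert c.gain == pytest.approx(0.75)

    def test_white_noise_needs_no_prediction(self):
        c = levinson_durbin(np.array([1.0] + [0.0] * 24), 24)
        np.testing.assert_array_equal(c.a, np.zeros(24))
        assert c.gain == 1.0

    @pytest.mark.parametrize("order", [1, 2, 5, 12, 24])
    def test_equals_direct_yule_walker_solve(self, order, rng):
        for _ in range(20):
            x = rng.standard_normal(512)
            r = autocorrelate(x, order)
            c = levinson_durbin(r, order)
            direct = solve_toeplitz(r[:order], -r[1 : order + 1])
            np.testing.assert_allclose(c.a, direct, atol=1e-8)
            assert c.gain >= 0

    def test_non_psd_sequence_rejected(self):
        from pcgclassify import NumericalError

        with pytest.raises(NumericalError):
            levinson_durbin(np.array([1.0, 0.99, 0.2, -0.9]), 3)

    def test_estimates_are_stable_filters(self, rng):
        x = rng.standard_normal(1024)
        c = levinson_durbin(autocorrelate(x, 24), 24)
        roots = np.roots(np.concatenate([[1.0], c.a]))
        assert np.max(np.abs(roots)) < 1.0 + 1e-6


class TestSpectra:
    def test_trivial_filter_is_flat(self):
        c = LPCCoefficients(4, np.zeros(4), 1.0)
        spec = filter_spectrum(c, 4000.0)
        np.testing.assert_allclose(spec.magnitudes, 1.0)

    def test_resonance_peaks_at_pole_frequency(self):
        fs, f0 = 4000.0, 100.0
        pole = 0.98 * np.exp(2j * np.pi * f0 / fs)
        a = np.real(np.poly([pole, pole.conj()]))[1:]
        spec = filter_spectrum(LPCCoefficients(2, a, 1.0), fs, 512)
        peak = spec.frequencies[np.argmax(spec.magnitudes)]
        assert abs(peak - f0) <= fs / (2 * 512) + 1e-9

    def test_matches_term_by_term_evaluation(self, rng):
        a = rng.uniform(-0.2, 0.2, 8)
        c = LPCCoefficients(8, a, 2.0)
        spec = filter_spectrum(c, 4000.0, 64)
        for i in [0, 13, 37, 63]:
            w = 2 * np.pi * spec.frequencies[i] / 4000.0
            A = 1.0 + sum(a[k - 1] * np.exp(-1j * w * k) for k in range(1, 9))
            assert spec.magnitudes[i] == pytest.approx(2.0 / abs(A), rel=1e-10)

    def test_signal_spectrum_finds_sinusoids(self):
        fs = 4000.0
        t = np.arange(2000) / fs
        spec = signal_spectrum(np.sin(2 * np.pi * 200 * t), fs)
        assert abs(spec.frequencies[np.argmax(spec.magnitudes)] - 200) <= fs / (2 * 512)

        two = signal_spectrum(
            np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 300 * t), fs
        )
        idx = np.argsort(two.magnitudes)[-2:]
        found = sorted(two.frequencies[idx])
        assert abs(found[0] - 50) < 8 and abs(found[1] - 300) < 8

    def test_signal_spectrum_is_linear(self, rng):
        x = rng.standard_normal(1000)
        s1 = signal_spectrum(x, 4000.0)
        s2 = signal_spectrum(2 * x, 4000.0)
        np.testing.assert_allclose(s2.magnitudes, 2 * s1.magnitudes, rtol=1e-10)

    def test_empty_segment_rejected(self):
        with pytest.raises(InputError):
            signal_spectrum(np.array([]), 4000.0)


class TestFitnessFactor:
    def test_identical_spectra_score_100(self, rng):
        m = rng.uniform(0.1, 1.0, 512)
        s = Spectrum(np.linspace(0, 2000, 512), m)
        assert fitness_factor(s, s) == pytest.approx(100.0)

    def test_hand_computed_example(self):
        f = np.arange(4.0)
        hs = Spectrum(f, np.array([1, 0.5, 0.25, 0.125]))
        hf = Spectrum(f, np.array([1, 0.4, 0.25, 0.125]))
        assert fitness_factor(hf, hs) == pytest.approx(100 * (1 - 0.1 / 1.875))

    def test_zero_filter_spectrum_scores_0(self):
        f = np.arange(4.0)
        assert fitness_factor(
            Spectrum(f, np.zeros(4)), Spectrum(f, np.array([1, 0.5, 0.25, 0.125]))
        ) == pytest.approx(100 * (1 - 1.875 / 1.875))

    def test_grid_mismatch_rejected(self):
        a = Spectrum(np.linspace(0, 2000, 16), np.ones(16))
        b = Spectrum(np.linspace(0, 1000, 16), np.ones(16))
        with pytest.raises(InputError):
            fitness_factor(a, b)


class TestExtractFeatures:
    def test_white_noise_gives_near_zero_coefficients(self, rng):
        feats = extract_features(rng.standard_normal(20000), 24)
        assert feats.shape == (24,)
        assert np.all(np.abs(feats) < 0.1)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(2000)
        np.testing.assert_allclose(
            extract_features(x, 24), extract_features(3.7 * x, 24), atol=1e-9
        )

    def test_determinism(self, rng):
        x = rng.standard_normal(2000)
        np.testing.assert_array_equal(extract_features(x, 24), extract_features(x, 24))

    def test_parameter_recovery_on_known_filters(self):
        """Noise driven through known stable AR(24) filters is recovered."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            a_true = random_stable_ar24(rng)
            x = lfilter([1.0], a_true, rng.standard_normal(8192))
            est = extract_coefficients(x, 24)
            rmse = np.sqrt(np.mean((est.a - a_true[1:]) ** 2))
            assert rmse < 0.05

    def test_spectral_match_converges_with_signal_length(self):
        """The fitted spectrum approaches the true one as data grows; at
        ~10^6 samples the match exceeds 99 %."""
        rng = np.random.default_rng(5)
        a_true = random_stable_ar24(rng)
        true_spec = filter_spectrum(LPCCoefficients(24, a_true[1:], 1.0), 4000.0)
        ffs = []
        for n in (8192, 2**17, 2**20):
            x = lfilter([1.0], a_true, rng.standard_normal(n))
            est = extract_coefficients(x, 24)
            ffs.append(fitness_factor(filter_spectrum(est, 4000.0), true_spec))
        assert ffs[0] < ffs[1] < ffs[2]
        assert ffs[2] >= 99.0

    def test_model_order_improves_spectral_match(self, dataset72):
        """Richer all-pole models track heart-tone spectra better (5 < 18 < 24)."""
        means = {}
        for order in (5, 18, 24):
            scores = []
            for rec, _ in dataset72.samples[:24]:
                ss = signal_spectrum(rec.samples, rec.sample_rate)
                c = extract_coefficients(rec.samples, order)
                scores.append(
                    fitness_factor(filter_spectrum(c, rec.sample_rate), ss)
                )
            means[order] = np.mean(scores)
        assert means[5] <= means[18] <= means[24]
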