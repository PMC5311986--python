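import numpy as np
import pytest

from freqclust import SiftConfig, decompose, envelope_mean, find_extrema, is_imf, sift
from freqclust import gen_oscillation, white_noise_series, hwf
from freqclust.emd import MonotonicSignalError

from ._reference_emd import reference_emd


class TestFindExtrema:
    def test_alternating_signal(self):
        maxima, minima = find_extrema(np.array([0, 1, 0, -1, 0, 1, 0], dtype=float))
        assert list(maxima) == [1, 5]
        assert list(minima) == [3]

    def test_monotone_ramp_has_none(self):
        maxima, minima = find_extrema(np.linspace(0, 1, 20))
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_maximum_at_midpoint(self):
        maxima, minima = find_extrema(np.array([0, 1, 1, 0], dtype=float))
        assert list(maxima) == [1]
        assert minima.size == 0

    def test_wide_plateau_midpoint(self):
        maxima, _ = find_extrema(np.array([0, 2, 2, 2, 2, 2, 0], dtype=float))
        assert list(maxima) == [3]

    def test_plateau_minimum(self):
        _, minima = find_extrema(np.array([1, 0, 0, 1], dtype=float))
        assert list(minima) == [1]

    def test_endpoints_never_extrema(self):
        maxima, minima = find_extrema(np.array([5, 1, 5], dtype=float))
        assert 0 not in maxima and 2 not in maxima


class TestEnvelopeMean:
    def test_near_zero_for_pure_sinusoid(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 20)
        m = envelope_mean(x)
        assert np.max(np.abs(m[30:-30])) < 0.05

    def test_tracks_constant_offset(self):
        t = np.arange(400)
        m = envelope_mean(np.sin(2 * np.pi * t / 20) + 3.0)
        assert np.all(np.abs(m[30:-30] - 3.0) < 0.05)

    def test_translation_equivariance(self):
        t = np.arange(300)
        x = np.sin(2 * np.pi * t / 25) + 0.3 * np.sin(2 * np.pi * t / 7)
        assert np.allclose(envelope_mean(x + 5.0), envelope_mean(x) + 5.0, atol=1e-9)

    def test_monotonic_signal_flagged(self):
        with pytest.raises(MonotonicSignalError):
            envelope_mean(np.linspace(0, 1, 50))


class TestIsImf:
    def test_pure_sinusoid_is_imf(self):
        t = np.arange(400)
        assert is_imf(np.sin(2 * np.pi * t / 20))

    def test_offset_sinusoid_is_not(self):
        t = np.arange(400)
        assert not is_imf(np.sin(2 * np.pi * t / 20) + 2.0)

    def test_linear_ramp_is_not(self):
        assert not is_imf(np.linspace(-1, 1, 50))


class TestSift:
    def test_imf_input_is_fixed_point(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 20)
        out = sift(x)
        assert np.allclose(out, x, atol=1e-6)

    def test_output_balances_extrema_and_zero_crossings(self):
        x = white_noise_series(220, 0.5, seed=11).values
        out = sift(x)
        maxima, minima = find_extrema(out)
        s = np.sign(out)
        zc = np.count_nonzero(np.diff(s[s != 0]))
        assert abs((maxima.size + minima.size) - zc) <= 1

    def test_two_tone_first_imf_matches_fast_component(self):
        fs, n = 0.5, 500
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 0.1 * t) + 0.5 * np.sin(2 * np.pi * 0.02 * t)
        imf1 = decompose(x, fs=fs).imfs[0]
        assert np.corrcoef(imf1, np.sin(2 * np.pi * 0.1 * t))[0, 1] > 0.95

    def test_nonfinite_input_rejected(self):
        x = np.ones(50)
        x[3] = np.nan
        with pytest.raises(ValueError):
            sift(x)


class TestDecompose:
    def test_monotonic_ramp_yields_no_imfs(self):
        x = np.linspace(0, 1, 64)
        out = decompose(x, fs=0.5)
        assert out.n_imfs == 0
        assert np.array_equal(out.residue, x)

    @pytest.mark.parametrize("seed", range(10))
    def test_reconstruction_identity(self, seed):
        ts = white_noise_series(220, 0.5, seed=seed)
        out = decompose(ts)
        err = np.linalg.norm(out.reconstruct() - ts.values) / np.linalg.norm(ts.values)
        assert err < 1e-8

    def test_amplitude_equivariance(self):
        ts = white_noise_series(220, 0.5, seed=2)
        base = decompose(ts)
        scaled = decompose(5.0 * ts.values, fs=0.5)
        assert scaled.n_imfs == base.n_imfs
        for a, b in zip(base.imfs, scaled.imfs):
            assert np.allclose(5.0 * a, b, rtol=1e-6, atol=1e-8)

    def test_white_noise_median_imf_count(self, noise_ensemble):
        counts = [decompose(ts).n_imfs for ts in noise_ensemble]
        assert np.median(counts) >= 5

    def test_dyadic_filter_bank_on_white_noise(self, noise_ensemble):
        # consecutive IMFs of noise should roughly halve in mean frequency
        freqs = np.full((len(noise_ensemble), 4), np.nan)
        for i, ts in enumerate(noise_ensemble):
            imfs = decompose(ts).imfs
            for j in range(min(4, len(imfs))):
                freqs[i, j] = hwf(imfs[j], ts.fs)
        mean_f = np.nanmean(freqs, axis=0)
        for j in range(3):
            assert 0.35 < mean_f[j + 1] / mean_f[j] < 0.65

    def test_agreement_with_independent_reference_emd(self):
        fs, n = 0.5, 500
        t = np.arange(n) / fs
        for f_hi, f_lo in [(0.1, 0.02), (0.15, 0.03)]:
            x = np.sin(2 * np.pi * f_hi * t) + 0.7 * np.sin(2 * np.pi * f_lo * t)
            mine = decompose(x, fs=fs).imfs[0]
            ref_imfs, _ = reference_emd(x)
            assert np.corrcoef(mine, ref_imfs[0])[0, 1] > 0.9

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SiftConfig(max_sift_iters=0)

    def test_single_tone_decomposes_to_one_dominant_imf(self):
        ts = gen_oscillation(0.05, n=220, fs=0.5)
        out = decompose(ts)
        assert out.n_imfs >= 1
        energy = [float(np.sum(i ** 2)) for i in out.imfs]
        assert energy[0] > 0.95 * sum(energy)
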