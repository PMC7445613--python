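import numpy as np
import pytest

from accelresp import (
    DegeneracyError,
    ParameterError,
    SynthConfig,
    UniformSignal,
    estimate_rr,
    gen_trace,
    real_cepstrum,
    rr_per_min,
    search_range,
    select_quefrency,
)

SR = 500.0


def brute_force_real_cepstrum(x):
    """Independent O(n^2) DFT oracle for the real cepstrum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n)
    F = np.exp(-2j * np.pi * np.outer(k, k) / n) @ x
    logmag = np.log(np.abs(F) + 1e-12)
    c = (np.exp(2j * np.pi * np.outer(k, k) / n) @ logmag) / n
    return np.real(c)


class TestRealCepstrum:
    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(0)
        for n in (32, 64, 100):
            x = rng.standard_normal(n)
            np.testing.assert_allclose(
                real_cepstrum(x), brute_force_real_cepstrum(x), atol=1e-9
            )

    @pytest.mark.parametrize("T", [1842, 1765, 2357, 3181])
    def test_noiseless_periodic_signal_peaks_near_its_period(self, T):
        # decaying-harmonic wave with a period that does not divide the
        # window: leakage smears the rahmonics into well-ordered humps whose
        # argmax sits within a few percent of the true period
        t = np.arange(30000)
        ph = 2 * np.pi * t / T
        x = np.cos(ph) + 0.4 * np.cos(2 * ph) + 0.15 * np.cos(3 * ph)
        c = real_cepstrum(x)
        q = 1251 + int(np.argmax(c[1251:6001]))
        assert abs(q - T) <= 0.05 * T
        q_sel, _, _ = select_quefrency(c, 1251, 6000)
        assert abs(rr_per_min(q_sel, SR) - 60 * SR / T) <= 1.0

    def test_white_noise_cepstrum_is_flat_compared_to_periodic(self):
        def contrast(x):
            c = real_cepstrum(x)
            seg = c[1251:6001]
            return seg.max() / np.median(np.abs(seg))

        rng_ratios = [
            contrast(np.random.default_rng(100 + s).standard_normal(30000))
            for s in range(10)
        ]
        spike = np.zeros(30000)
        spike[::2000] = 1.0
        spike += 0.05 * np.random.default_rng(5).standard_normal(30000)
        assert np.mean(rng_ratios) < 8.0
        assert contrast(spike) > 3.0 * np.mean(rng_ratios)

    def test_scaling_changes_only_the_zeroth_bin(self):
        x = np.random.default_rng(1).standard_normal(4096)
        c1, c2 = real_cepstrum(x), real_cepstrum(2.0 * x)
        np.testing.assert_allclose(c1[1:], c2[1:], atol=1e-9)
        assert abs(c1[0] - c2[0]) > 0.1  # log-amplitude shift lands at q=0

    def test_all_zero_epoch_is_degenerate(self):
        with pytest.raises(DegeneracyError):
            real_cepstrum(np.zeros(1000))


class TestSearchRange:
    @pytest.mark.parametrize(
        "sr,lo,hi,expected",
        [(500, 5, 24, (1251, 6000)), (1000, 5, 24, (2501, 12000))],
    )
    def test_band_endpoints(self, sr, lo, hi, expected):
        assert search_range(sr, lo, hi) == expected

    def test_empty_band_rejected(self):
        with pytest.raises(ParameterError):
            search_range(500, 30, 30)
        with pytest.raises(ParameterError):
            search_range(500, 24, 5)


class TestSelectQuefrency:
    def _cep(self, peaks, n=30000):
        c = np.zeros(n)
        for q, v in peaks.items():
            c[q] = v
        return c

    def test_fundamental_kept_with_confirming_second_rahmonic(self):
        c = self._cep({1667: 1.0, 3334: 0.6})
        assert select_quefrency(c, 1251, 6000) == (1667, 1.0, True)

    def test_strong_subpeak_at_half_quefrency_corrects_the_max(self):
        c = self._cep({3334: 1.0, 1667: 0.8})
        q, ca, found = select_quefrency(c, 1251, 6000)
        assert (q, ca, found) == (1667, 1.0, True)

    def test_weak_subpeak_below_alpha_keeps_the_max(self):
        c = self._cep({3334: 1.0, 1667: 0.5})
        q, ca, found = select_quefrency(c, 1251, 6000)
        assert q == 3334 and not found

    def test_third_rahmonic_corrected_to_fundamental(self):
        c = self._cep({5400: 1.0, 1800: 0.9, 3600: 0.95})
        q, _, found = select_quefrency(c, 1251, 6000)
        assert q == 1800 and found

    def test_plateau_tie_breaks_to_lower_quefrency(self):
        c = np.zeros(30000)
        c[4000:4003] = 1.0  # no sub-peak in range at 2000
        q, _, _ = select_quefrency(c, 1251, 6000, correct_half=False)
        assert q == 4000

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            select_quefrency(np.zeros(100), 50, 200)


class TestRrPerMin:
    @pytest.mark.parametrize(
        "q,expected", [(6000, 5.0), (1251, 23.98), (1765, 17.0)]
    )
    def test_band_conversions(self, q, expected):
        assert rr_per_min(q, 500) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_quefrency_rejected(self):
        with pytest.raises(ParameterError):
            rr_per_min(0, 500)


class TestEstimateRr:
    def test_seventeen_bpm_subject_recovered_per_epoch(self):
        cfg = SynthConfig(
            rr_bpm=17, duration_s=300, snr_db=10, mixing_seed=1, noise_seed=2
        )
        trace, truth = gen_trace(cfg)
        est = estimate_rr(trace)
        n = min(est.per_epoch.size, truth.epoch_rates.size)
        assert np.abs(est.per_epoch[:n] - truth.epoch_rates[:n]).max() <= 1.0
        assert est.mean_rounded == 17

    def test_point_three_hertz_breathing_is_eighteen_bpm(self):
        # 0.3 Hz = 18 breaths/min; harmonic-bearing breath source
        cfg = SynthConfig(
            rr_bpm=18, duration_s=120, snr_db=10, mixing_seed=20, noise_seed=30
        )
        trace, _ = gen_trace(cfg)
        est = estimate_rr(trace)
        assert np.abs(est.per_epoch - 18.0).max() <= 1.0
        assert est.mean_rounded == 18

    def test_all_zero_input_is_degenerate(self):
        sig = UniformSignal(np.zeros((3, 60000)), SR)
        with pytest.raises(DegeneracyError):
            estimate_rr(sig)

    def test_estimates_confined_to_the_band_even_in_pure_noise(self):
        cfg = SynthConfig(
            rr_bpm=17, duration_s=120, snr_db=-20, mixing_seed=5, noise_seed=6
        )
        trace, _ = gen_trace(cfg)
        est = estimate_rr(trace)
        assert np.all((est.per_epoch >= 5.0) & (est.per_epoch <= 24.0))

    def test_epoch_too_short_for_search_range_rejected(self):
        sig = UniformSignal(
            np.random.default_rng(0).standard_normal((3, 60000)), SR
        )
        with pytest.raises(ParameterError):
            estimate_rr(sig, epoch_s=20.0)

    def test_circular_shift_leaves_epoch_estimate_unchanged(self):
        rng = np.random.default_rng(2)
        t = np.arange(30000) / SR
        x = (
            np.sin(2 * np.pi * 0.27 * t)
            + 0.4 * np.sin(4 * np.pi * 0.27 * t)
            + 0.1 * rng.standard_normal(30000)
        )
        lo, hi = search_range(SR)
        q0 = select_quefrency(real_cepstrum(x), lo, hi)[0]
        for shift in (1, 137, 9999):
            q = select_quefrency(real_cepstrum(np.roll(x, shift)), lo, hi)[0]
            assert q == q0
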