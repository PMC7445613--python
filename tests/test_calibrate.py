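import numpy as np
import pytest

from accelresp import (
    DataError,
    DegeneracyError,
    UniformSignal,
    estimate_rr,
    ica_separate,
    pca_first,
    real_cepstrum,
    rss,
    select_respiratory_component,
    take_axis,
)
from accelresp.calibrate import SourceSet

SR = 500.0


def _sources(n=30000, seed=0):
    """Three independent unit-variance sources: a harmonic 0.3 Hz breath-like
    wave, uniform noise, Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / SR
    resp = np.sin(2 * np.pi * 0.3 * t) + 0.3 * np.sin(4 * np.pi * 0.3 * t)
    u = rng.uniform(-1, 1, n)
    g = rng.standard_normal(n)
    S = np.vstack([(s - s.mean()) / s.std() for s in (resp, u, g)])
    return S


class TestIcaSeparate:
    def test_recovers_respiration_from_random_mixture(self):
        S = _sources()
        M = np.random.default_rng(1).standard_normal((3, 3))
        srcset = ica_separate(UniformSignal(M @ S, SR), seed=0)
        best = max(
            abs(np.corrcoef(srcset.sources[i], S[0])[0, 1]) for i in range(3)
        )
        assert best > 0.95

    def test_identity_mixing_returns_sources_up_to_sign_permutation(self):
        S = _sources(seed=2)
        srcset = ica_separate(UniformSignal(S, SR), seed=0)
        for j in range(3):
            best = max(
                abs(np.corrcoef(srcset.sources[i], S[j])[0, 1]) for i in range(3)
            )
            assert best > 0.99

    def test_identical_axes_raise_degeneracy(self):
        x = np.random.default_rng(3).standard_normal(30000)
        sig = UniformSignal(np.vstack([x, x, x]), SR)
        with pytest.raises(DegeneracyError):
            ica_separate(sig)

    def test_matrix_and_moment_invariants(self):
        S = _sources(seed=4)
        M = np.random.default_rng(4).standard_normal((3, 3))
        X = M @ S
        srcset = ica_separate(UniformSignal(X, SR), seed=0)
        np.testing.assert_allclose(
            srcset.mixing @ srcset.unmixing, np.eye(3), atol=1e-6
        )
        assert np.abs(srcset.sources.mean(axis=1)).max() < 1e-8
        np.testing.assert_allclose(srcset.sources.var(axis=1), 1.0, atol=1e-6)
        # mixing @ sources reconstructs the mean-removed input
        recon = srcset.mixing @ srcset.sources + srcset.mean[:, None]
        rms = np.sqrt(np.mean((recon - X) ** 2))
        assert rms < 1e-5

    def test_deterministic_for_fixed_seed(self):
        S = _sources(seed=5)
        sig = UniformSignal(np.random.default_rng(5).standard_normal((3, 3)) @ S, SR)
        a = ica_separate(sig, seed=7)
        b = ica_separate(sig, seed=7)
        np.testing.assert_array_equal(a.sources, b.sources)

    def test_too_short_signal_rejected(self):
        sig = UniformSignal(np.random.default_rng(6).standard_normal((3, 1000)), SR)
        with pytest.raises(DataError):
            ica_separate(sig)


class TestSelectRespiratoryComponent:
    def _srcset(self, comps):
        return SourceSet(
            sources=np.asarray(comps, dtype=float),
            unmixing=np.eye(3),
            mixing=np.eye(3),
            mean=np.zeros(3),
            sr=SR,
            seed=0,
        )

    def test_clean_periodic_component_wins(self):
        rng = np.random.default_rng(7)
        t = np.arange(30000) / SR
        clean = np.sin(2 * np.pi * 0.3 * t) + 0.3 * np.sin(4 * np.pi * 0.3 * t)
        srcset = self._srcset(
            [rng.standard_normal(30000), rng.standard_normal(30000), clean]
        )
        assert select_respiratory_component(srcset, SR, (1251, 6000)) == 2

    def test_near_ties_break_to_lowest_index(self):
        x = np.random.default_rng(8).standard_normal(30000)
        srcset = self._srcset([x, x.copy(), x.copy()])
        assert select_respiratory_component(srcset, SR, (1251, 6000)) == 0

    def test_dominant_cepstral_peak_at_2000_wins(self):
        # component 1: impulse train, cepstral spike at q=2000; others flat
        rng = np.random.default_rng(9)
        spike = np.zeros(30000)
        spike[::2000] = 1.0
        spike += 0.05 * rng.standard_normal(30000)
        srcset = self._srcset(
            [rng.standard_normal(30000), spike, rng.standard_normal(30000)]
        )
        assert select_respiratory_component(srcset, SR, (1251, 6000)) == 1


class TestBaselineCalibrations:
    def test_rss_of_3_4_0_is_5(self):
        sig = UniformSignal(
            np.vstack([np.full(100, 3.0), np.full(100, 4.0), np.zeros(100)]), SR
        )
        np.testing.assert_allclose(rss(sig).data[0], 5.0)

    def test_pca_first_recovers_single_varying_axis(self):
        c = np.sin(np.linspace(0, 20, 5000))
        sig = UniformSignal(np.vstack([c, np.zeros(5000), np.zeros(5000)]), SR)
        pc = pca_first(sig).data[0]
        r = np.corrcoef(pc, c)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_take_axis_returns_named_channel(self):
        data = np.arange(30.0).reshape(3, 10)
        sig = UniformSignal(data, SR)
        np.testing.assert_array_equal(take_axis(sig, "z").data[0], data[2])
        with pytest.raises(DataError):
            take_axis(sig, "w")


def test_rr_estimate_invariant_to_component_sign_and_scale():
    """ICA components are defined up to sign and positive scale; the cepstral
    rate estimate must not depend on either."""
    from accelresp import search_range, select_quefrency

    rng = np.random.default_rng(10)
    t = np.arange(30000) / SR
    x = (
        np.sin(2 * np.pi * 0.28 * t)
        + 0.4 * np.sin(4 * np.pi * 0.28 * t)
        + 0.1 * rng.standard_normal(30000)
    )
    lo, hi = search_range(SR)
    base = select_quefrency(real_cepstrum(x), lo, hi)[0]
    for variant in (-x, 3.7 * x, -0.002 * x):
        assert select_quefrency(real_cepstrum(variant), lo, hi)[0] == base


def test_ica_calibration_beats_rss_on_synthetic_cohort(cohort30):
    """Mean absolute per-epoch error with ICA calibration should not exceed
    the RSS baseline's on the same recordings."""
    assert cohort30.mae("ica") <= cohort30.mae("rss")
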