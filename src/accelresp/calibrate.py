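"""Axis calibration: collapse the 3-axis signal to one respiration channel.

An accelerometer lying on a mattress picks up the breathing motion mixed, with
unknown weights, into all three axes together with environmental noise.  Under
the linear instantaneous model ``A = U S`` (observed axes ``A``, unknown
mixing ``U``, independent sources ``S``), FastICA estimates an unmixing matrix
``W`` so that ``X = W A`` recovers the sources up to sign, scale and
permutation.  The respiration-bearing component is then chosen as the one
whose real cepstrum is most sharply peaked inside the physiological quefrency
range.

Baseline calibrations used for comparison: a single named axis, the per-sample
root sum square (RSS), and the first principal component (PCA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .cepstrum_rr import real_cepstrum
from .errors import DataError, DegeneracyError
from .io_acc import UniformSignal

__all__ = [
    "SourceSet",
    "ica_separate",
    "select_respiratory_component",
    "rss",
    "pca_first",
    "take_axis",
]


@dataclass
class SourceSet:
    """FastICA decomposition of a 3-channel signal.

    ``sources`` holds the estimated independent components (3, n), each with
    zero mean and unit variance; ``unmixing`` (W) maps mean-removed axes to
    sources and ``mixing`` (U = W^-1) maps sources back, so
    ``mixing @ unmixing = I`` and ``mixing @ sources + mean`` reconstructs
    the input.
    """

    sources: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    mean: np.ndarray
    sr: float
    seed: int

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def _check_3ch(signal3: UniformSignal) -> None:
    if signal3.n_channels != 3:
        raise DataError(f"expected 3 channels, got {signal3.n_channels}")


def ica_separate(
    signal3: UniformSignal,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> SourceSet:
    """Separate a 3-channel signal into independent components.

    FastICA with tanh (log-cosh) contrast, symmetric decorrelation and
    eigendecomposition whitening; deterministic for a fixed ``seed``.
    Components are standardised to zero mean and unit variance, with the
    mixing/unmixing matrices rescaled to compensate.

    Raises
    ------
    DataError
        If the input does not have 3 channels or is shorter than 10 s.
    DegeneracyError
        If the channel covariance is (numerically) rank deficient, e.g. two
        identical axes.
    """
    _check_3ch(signal3)
    if signal3.n_samples < 10 * signal3.sr:
        raise DataError(
            f"ICA needs at least 10 s of signal ({int(10 * signal3.sr)} samples), "
            f"got {signal3.n_samples}"
        )
    X = signal3.data  # (3, n)
    cov = np.cov(X)
    eig = np.linalg.eigvalsh(cov)
    if eig[-1] <= 0 or eig[0] / eig[-1] < 1e-10:
        raise DegeneracyError(
            "channel covariance is rank deficient; axes are linearly dependent"
        )
    ica = FastICA(
        n_components=3,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        whiten_solver="eigh",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    S = ica.fit_transform(X.T).T  # (3, n)
    W = ica.components_
    U = ica.mixing_
    mean = ica.mean_
    # Re-standardise exactly (sklearn's unit-variance is only approximate
    # when the solver stops early) and fold the scale into W and U.
    mu = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = (S - mu) / sd
    W = W / sd
    U = U * sd.T
    return SourceSet(
        sources=S, unmixing=W, mixing=U, mean=mean, sr=signal3.sr, seed=seed
    )


def select_respiratory_component(
    srcset: SourceSet, sr: float, sp: tuple[int, int]
) -> int:
    """Index of the component most likely to carry respiration.

    Scores each component by the ratio of its maximum real-cepstrum value
    inside the quefrency search range ``sp = (sp_lo, sp_hi)`` to the median
    absolute in-range cepstrum value; a strongly periodic breathing component
    produces a sharp rahmonic spike while noise components stay flat.  Ties
    break toward the lower index.
    """
    sp_lo, sp_hi = sp
    best_idx, best_score = 0, -np.inf
    for i in range(srcset.n_components):
        c = real_cepstrum(srcset.sources[i])
        seg = c[sp_lo : sp_hi + 1]
        denom = max(float(np.median(np.abs(seg))), 1e-15)
        score = float(seg.max()) / denom
        if score > best_score:
            best_idx, best_score = i, score
    return best_idx


def rss(signal3: UniformSignal) -> UniformSignal:
    """Per-sample root sum square sqrt(x^2 + y^2 + z^2) of the three axes."""
    _check_3ch(signal3)
    out = np.sqrt(np.sum(signal3.data**2, axis=0))
    return UniformSignal(out, sr=signal3.sr, start_time=signal3.start_time)


def pca_first(signal3: UniformSignal, seed: int = 0) -> UniformSignal:
    """First principal-component score series (mean-centred, unscaled)."""
    _check_3ch(signal3)
    pca = PCA(n_components=1, random_state=seed)
    scores = pca.fit_transform(signal3.data.T)[:, 0]
    return UniformSignal(scores, sr=signal3.sr, start_time=signal3.start_time)


_AXES = {"x": 0, "y": 1, "z": 2}


def take_axis(signal3: UniformSignal, axis: str) -> UniformSignal:
    """Return one named axis ('x', 'y' or 'z') unchanged."""
    _check_3ch(signal3)
    if axis not in _AXES:
        raise DataError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return UniformSignal(
        signal3.data[_AXES[axis]], sr=signal3.sr, start_time=signal3.start_time
    )
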