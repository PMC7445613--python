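"""Cepstral respiration-rate estimation.

Breathing at rest is quasi-periodic, so a breathing component shows up in the
real cepstrum — the inverse Fourier transform of the log magnitude spectrum —
as a sharp spike ("rahmonic") at the quefrency equal to the breath period in
samples, with further spikes at its multiples.  The estimator restricts the
search to the quefrency interval SP corresponding to plausible breathing
periods (5–24 breaths/min gives samples 1251–6000 at 500 Hz), picks the
maximum in-range peak, applies a second-harmonic check (a dominant peak at
twice the quefrency of a strong sub-peak means the sub-peak is the true
period), and converts the selected quefrency ``q*`` to a rate::

    RR [breaths/min] = 60 * sr / q*

:func:`estimate_rr` runs the full pipeline: fixed-rate resampling (for raw
traces), 0.4 Hz low-pass, axis calibration (ICA by default), per-epoch
cepstrum and quefrency selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft

from .errors import DataError, DegeneracyError, ParameterError

__all__ = [
    "QuefrencySelection",
    "PipelineConfig",
    "RREstimate",
    "real_cepstrum",
    "search_range",
    "select_quefrency",
    "rr_per_min",
    "estimate_rr",
]


@dataclass
class QuefrencySelection:
    """Outcome of quefrency selection on one epoch.

    ``q_star`` is the selected quefrency in samples, ``ca_max_peak`` the
    cepstrum value at the in-range maximum, ``second_harmonic_found`` whether
    a confirming (or correcting) rahmonic was detected, and ``rr_min`` the
    resulting rate in breaths per minute.
    """

    cepstrum: np.ndarray
    sp_lo: int
    sp_hi: int
    q_star: int
    ca_max_peak: float
    second_harmonic_found: bool
    rr_min: float


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end estimator.

    Defaults mirror the intended deployment: 500 Hz working rate reached via
    a 1000 Hz hold grid, 0.4 Hz respiration low-pass, 60 s epochs, a 5–24
    breaths/min physiological band, and ICA calibration with cepstral
    quefrency selection.
    """

    target_hz: float = 500.0
    up_hz: float = 1000.0
    cutoff_hz: float = 0.4
    epoch_s: float = 60.0
    rr_lo: float = 5.0
    rr_hi: float = 24.0
    alpha: float = 0.7
    tol: float = 0.05
    seed: int = 0
    calibration: str = "ica"  # ica | rss | pca | x | y | z | none
    estimator: str = "cepstrum"  # cepstrum | peak | spectral | autocorr
    ica_per_epoch: bool = False


@dataclass
class RREstimate:
    """Per-epoch respiration rates plus the per-recording summary."""

    per_epoch: np.ndarray
    selections: list
    mean: float
    mean_rounded: int
    calibration: str
    estimator: str
    component_index: int | None
    sr: float


def real_cepstrum(
    x: np.ndarray, eps: float = 1e-12, rel_floor: float = 0.0
) -> np.ndarray:
    """Real cepstrum: Re(IFFT(log(|FFT(x)| + eps))) with a dynamic-range clamp.

    Index ``n`` corresponds to a quefrency of ``n / sr`` seconds.  ``eps``
    keeps the log finite on exactly-zero spectral bins.  ``rel_floor``, if
    positive, clamps the magnitude spectrum from below at ``rel_floor * max``
    (limiting spectral dynamic range); off by default, since for signals with
    a physical noise floor the floor's fine structure is informative (it is
    what makes rahmonic peaks decay with order).

    Raises
    ------
    DegeneracyError
        If the epoch is identically zero (log of a zero spectrum).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError("real_cepstrum expects a single channel")
    if not np.any(x):
        raise DegeneracyError("all-zero epoch has no defined cepstrum")
    spectrum = np.abs(sfft.fft(x))
    if rel_floor > 0:
        spectrum = np.maximum(spectrum, rel_floor * spectrum.max())
    return np.real(sfft.ifft(np.log(spectrum + eps)))


def search_range(
    sr: float, rr_lo: float = 5.0, rr_hi: float = 24.0
) -> tuple[int, int]:
    """Quefrency search interval SP (in samples) for a breathing-rate band.

    The slowest admissible breath (``rr_lo`` breaths/min) sets the upper
    quefrency bound ``round(60*sr/rr_lo)``; the fastest sets the lower bound
    ``floor(60*sr/rr_hi) + 1``.  At 500 Hz with the default 5–24 breaths/min
    band this is (1251, 6000).

    Raises
    ------
    ParameterError
        If the band is invalid or so narrow that the interval is empty.
    """
    if not 0 < rr_lo < rr_hi:
        raise ParameterError(
            f"need 0 < rr_lo < rr_hi, got rr_lo={rr_lo}, rr_hi={rr_hi}"
        )
    if sr <= 0:
        raise ParameterError(f"sr must be positive, got {sr}")
    sp_hi = int(round(60.0 * sr / rr_lo))
    sp_lo = int(math.floor(60.0 * sr / rr_hi)) + 1
    if sp_lo > sp_hi:
        raise ParameterError(
            f"respiration band ({rr_lo}, {rr_hi}) breaths/min yields an empty "
            f"quefrency range ({sp_lo}, {sp_hi}) at sr={sr}"
        )
    return sp_lo, sp_hi


def _has_positive_peak(c: np.ndarray, lo: int, hi: int) -> bool:
    """True if c has a strict positive local maximum with index in [lo, hi]."""
    lo = max(lo, 1)
    hi = min(hi, c.size - 2)
    if hi < lo:
        return False
    seg = c[lo - 1 : hi + 2]
    inner = seg[1:-1]
    return bool(
        np.any((inner > seg[:-2]) & (inner > seg[2:]) & (inner > 0))
    )


def select_quefrency(
    cepstrum: np.ndarray,
    sp_lo: int,
    sp_hi: int,
    alpha: float = 0.7,
    tol: float = 0.05,
    correct_half: bool = True,
    correct_double: bool = False,
    max_subharmonic: int = 3,
) -> tuple[int, float, bool]:
    """Pick the breathing-period quefrency from a real cepstrum.

    Let ``q_max`` be the argmax of the cepstrum on ``[sp_lo, sp_hi]`` (ties
    toward the lower quefrency).  A strongly periodic breath produces
    rahmonics at every multiple of the true period, so ``q_max`` may land on
    the 2nd (or 3rd) rahmonic rather than the fundamental.  When
    ``correct_half`` is set, the sub-quefrencies ``q_max/m`` for
    ``m = 2..max_subharmonic`` are tested in order: if ``q_max/m`` is still
    inside the range and the cepstrum within ``±tol*(q_max/m)`` of it reaches
    at least ``alpha * cepstrum[q_max]``, the selection moves to that
    sub-peak and the harmonic flag is set.  Otherwise ``q_star = q_max`` and
    the flag reports whether a confirming rahmonic (a strict positive local
    peak) exists within ``±tol*2*q_max`` of ``2*q_max`` (evaluated only when
    ``2*q_max`` is below half the cepstrum length).

    ``correct_double`` enables the opposite correction (a strong peak at
    twice ``q_max`` replaces it); off by default.

    Returns ``(q_star, ca_max_peak, second_harmonic_found)`` where
    ``ca_max_peak`` is the cepstrum value at ``q_max``.
    """
    c = np.asarray(cepstrum, dtype=float)
    if not 0 < sp_lo <= sp_hi < c.size:
        raise ParameterError(
            f"search range ({sp_lo}, {sp_hi}) invalid for cepstrum of length {c.size}"
        )
    seg = c[sp_lo : sp_hi + 1]
    q_max = sp_lo + int(np.argmax(seg))
    ca = float(c[q_max])

    if correct_half:
        for m in range(2, max_subharmonic + 1):
            sub = q_max / m
            if sub < sp_lo:
                break
            w = tol * sub
            lo = max(int(math.floor(sub - w)), sp_lo)
            hi = min(int(math.ceil(sub + w)), sp_hi)
            window = c[lo : hi + 1]
            if window.size and float(window.max()) >= alpha * ca:
                q_star = lo + int(np.argmax(window))
                return q_star, ca, True

    if correct_double:
        dbl = 2 * q_max
        if dbl <= sp_hi:
            w = tol * dbl
            lo = max(int(math.floor(dbl - w)), sp_lo)
            hi = min(int(math.ceil(dbl + w)), sp_hi)
            window = c[lo : hi + 1]
            if window.size and float(window.max()) >= alpha * ca:
                q_star = lo + int(np.argmax(window))
                return q_star, ca, True

    found = False
    dbl = 2 * q_max
    if dbl <= c.size // 2:
        w = int(math.ceil(tol * dbl))
        found = _has_positive_peak(c, dbl - w, dbl + w)
    return q_max, ca, found


def rr_per_min(q_star: int, sr: float) -> float:
    """Breaths per minute for a period of ``q_star`` samples: 60*sr/q*."""
    if q_star <= 0:
        raise ParameterError(f"q_star must be positive, got {q_star}")
    return 60.0 * sr / q_star


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _calibrated_channel(filtered, cfg: PipelineConfig):
    """Collapse a filtered 3-channel signal to one channel; returns
    (UniformSignal, component_index or None)."""
    from . import calibrate  # local import: calibrate uses real_cepstrum

    method = cfg.calibration
    if method == "none":
        if filtered.n_channels != 1:
            raise DataError("calibration 'none' requires a single channel")
        return filtered, None
    if method == "ica":
        srcset = calibrate.ica_separate(filtered, seed=cfg.seed)
        sp = search_range(filtered.sr, cfg.rr_lo, cfg.rr_hi)
        idx = calibrate.select_respiratory_component(srcset, filtered.sr, sp)
        from .io_acc import UniformSignal

        return (
            UniformSignal(srcset.sources[idx], sr=filtered.sr,
                          start_time=filtered.start_time),
            idx,
        )
    if method == "rss":
        return calibrate.rss(filtered), None
    if method == "pca":
        return calibrate.pca_first(filtered, seed=cfg.seed), None
    if method in ("x", "y", "z"):
        return calibrate.take_axis(filtered, method), None
    raise ParameterError(f"unknown calibration {method!r}")


def _epoch_rate(x: np.ndarray, sr: float, cfg: PipelineConfig):
    """One epoch -> (rate, QuefrencySelection or None) for cfg.estimator."""
    if cfg.estimator == "cepstrum":
        sp_lo, sp_hi = search_range(sr, cfg.rr_lo, cfg.rr_hi)
        # No mean removal needed: the DC bin shifts every quefrency of the
        # log-spectrum IFFT by the same constant, leaving the argmax intact.
        c = real_cepstrum(x)
        q_star, ca, found = select_quefrency(
            c, sp_lo, sp_hi, alpha=cfg.alpha, tol=cfg.tol
        )
        rr = rr_per_min(q_star, sr)
        return rr, QuefrencySelection(
            cepstrum=c, sp_lo=sp_lo, sp_hi=sp_hi, q_star=q_star,
            ca_max_peak=ca, second_harmonic_found=found, rr_min=rr,
        )
    from . import baseline_rr
    from .io_acc import UniformSignal

    epoch = UniformSignal(x, sr=sr)
    if cfg.estimator == "peak":
        return baseline_rr.rr_peak_count(epoch, rr_hi=cfg.rr_hi), None
    if cfg.estimator == "spectral":
        return baseline_rr.rr_spectral_peak(epoch, rr_lo=cfg.rr_lo, rr_hi=cfg.rr_hi), None
    if cfg.estimator == "autocorr":
        return baseline_rr.rr_autocorr(epoch, rr_lo=cfg.rr_lo, rr_hi=cfg.rr_hi), None
    raise ParameterError(f"unknown estimator {cfg.estimator!r}")


def estimate_rr(data, config: PipelineConfig | None = None, **overrides) -> RREstimate:
    """Full pipeline: trace/signal in, per-epoch breathing rates out.

    ``data`` may be an :class:`~accelresp.io_acc.AccelTrace` (resampled to
    ``target_hz`` first) or an already-uniform :class:`UniformSignal`.
    Keyword overrides are applied on top of ``config``.

    The per-recording summary ``mean_rounded`` is the arithmetic mean of the
    epoch rates rounded half-up to an integer, the granularity at which
    per-minute respiration counts are reported.
    """
    from .io_acc import AccelTrace, to_fixed_rate
    from .preprocess import lowpass, make_epochs

    cfg = config or PipelineConfig()
    if overrides:
        cfg = replace(cfg, **overrides)

    if isinstance(data, AccelTrace):
        signal = to_fixed_rate(data, up_hz=cfg.up_hz, target_hz=cfg.target_hz)
    else:
        signal = data
    if not np.any(signal.data):
        raise DegeneracyError("all-zero input")

    sp_lo, sp_hi = search_range(signal.sr, cfg.rr_lo, cfg.rr_hi)
    n_epoch_samples = int(round(cfg.epoch_s * signal.sr))
    if n_epoch_samples < 2 * sp_hi:
        raise ParameterError(
            f"epoch of {n_epoch_samples} samples cannot resolve quefrencies "
            f"up to {sp_hi}; need at least {2 * sp_hi}"
        )

    filtered = lowpass(signal, cutoff=cfg.cutoff_hz)

    if cfg.ica_per_epoch and cfg.calibration == "ica":
        epochs3 = make_epochs(filtered, epoch_len=cfg.epoch_s)
        rates, selections, idx = [], [], None
        for ep in epochs3:
            chan, idx = _calibrated_channel(ep, cfg)
            rr, sel = _epoch_rate(chan.data[0], chan.sr, cfg)
            rates.append(rr)
            selections.append(sel)
    else:
        chan, idx = _calibrated_channel(filtered, cfg)
        epochs = make_epochs(chan, epoch_len=cfg.epoch_s)
        rates, selections = [], []
        for ep in epochs:
            rr, sel = _epoch_rate(ep.data[0], ep.sr, cfg)
            rates.append(rr)
            selections.append(sel)

    rates = np.asarray(rates, dtype=float)
    mean = float(rates.mean())
    return RREstimate(
        per_epoch=rates,
        selections=selections,
        mean=mean,
        mean_rounded=_round_half_up(mean),
        calibration=cfg.calibration,
        estimator=cfg.estimator,
        component_index=idx,
        sr=signal.sr,
    )
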