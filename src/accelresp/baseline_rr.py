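"""Comparison estimators and the chest-belt reference counter.

Three conventional per-epoch rate estimators operate on the calibrated
channel: peak counting, the highest spectral peak, and the autocorrelation
lag.  All three share the physiological band with the cepstral method: peak
counting enforces a minimum peak distance of ``sr*60/rr_hi`` samples (no two
breaths closer than the fastest admissible breath), and the spectral and
autocorrelation searches are restricted to the band/lag range it implies.

The chest-belt reference is scored the same way breaths are counted
clinically: maximum peaks per 1-minute epoch.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .cepstrum_rr import search_range
from .errors import DataError
from .io_acc import UniformSignal
from .preprocess import lowpass, make_epochs

__all__ = [
    "rr_peak_count",
    "rr_spectral_peak",
    "rr_autocorr",
    "count_belt_peaks",
]


def _min_distance(sr: float, rr_hi: float) -> int:
    return max(1, int(math.ceil(sr * 60.0 / rr_hi)))


def rr_peak_count(epoch: UniformSignal, rr_hi: float = 24.0) -> float:
    """Breaths/min by counting local maxima at least one fastest-breath apart."""
    x = epoch.data[0]
    peaks, _ = sps.find_peaks(x, distance=_min_distance(epoch.sr, rr_hi))
    minutes = epoch.duration / 60.0
    return peaks.size / minutes


def rr_spectral_peak(
    epoch: UniformSignal, rr_lo: float = 5.0, rr_hi: float = 24.0
) -> float:
    """Breaths/min from the largest magnitude-spectrum bin inside the band."""
    x = epoch.data[0]
    x = x - x.mean()
    mag = np.abs(sfft.rfft(x))
    freqs = sfft.rfftfreq(x.size, d=1.0 / epoch.sr)
    band = (freqs >= rr_lo / 60.0) & (freqs <= rr_hi / 60.0)
    if not np.any(band):
        raise DataError("epoch too short to resolve the respiration band")
    f_max = freqs[band][int(np.argmax(mag[band]))]
    return 60.0 * f_max


def rr_autocorr(
    epoch: UniformSignal, rr_lo: float = 5.0, rr_hi: float = 24.0
) -> float:
    """Breaths/min from the best autocorrelation lag inside the band.

    Biased autocorrelation estimate normalised at lag 0; the winning lag
    l* over the band's lag range gives 60*sr/l*.
    """
    x = epoch.data[0]
    x = x - x.mean()
    n = x.size
    ac = sps.correlate(x, x, mode="full", method="fft")[n - 1 :]
    if ac[0] <= 0:
        return 0.0
    ac = ac / ac[0]
    sp_lo, sp_hi = search_range(epoch.sr, rr_lo, rr_hi)
    sp_hi = min(sp_hi, n - 1)
    lag = sp_lo + int(np.argmax(ac[sp_lo : sp_hi + 1]))
    return 60.0 * epoch.sr / lag


def count_belt_peaks(
    belt: UniformSignal,
    epoch_len: float = 60.0,
    rr_hi: float = 24.0,
    cutoff: float = 0.4,
) -> tuple[np.ndarray, int]:
    """Per-epoch breath counts from a chest-belt signal, plus rounded mean.

    The belt trace is low-passed at ``cutoff`` (same respiration band as the
    rest of the pipeline) and cut into ``epoch_len`` epochs; each epoch's
    count is its number of maximum peaks under the minimum-distance rule.

    Returns ``(counts, mean_rounded)`` where ``counts`` has one integer per
    epoch and ``mean_rounded`` is the mean count rounded half-up.

    Raises
    ------
    DataError
        If the belt signal is shorter than one epoch.
    """
    smooth = lowpass(belt, cutoff=cutoff)
    epochs = make_epochs(smooth, epoch_len=epoch_len)
    dist = _min_distance(belt.sr, rr_hi)
    counts = np.array(
        [sps.find_peaks(ep.data[0], distance=dist)[0].size for ep in epochs],
        dtype=int,
    )
    return counts, int(math.floor(counts.mean() + 0.5))
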