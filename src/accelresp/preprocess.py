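"""Band-limiting to the respiration band and epoch segmentation.

Respiration at rest occupies the spectrum below ~0.4 Hz, so the 3-axis signal
is low-passed at that cutoff before any source separation.  The filter is a
4th-order Butterworth applied forward-backward (zero phase), so breath peak
timing is not shifted.  Analysis then proceeds on non-overlapping fixed-length
epochs (60 s by default, the unit of per-minute respiration counting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, ParameterError
from .io_acc import UniformSignal

__all__ = ["EpochSet", "lowpass", "make_epochs"]


@dataclass
class EpochSet:
    """Consecutive non-overlapping windows of a uniform signal.

    ``epochs`` is a list of :class:`UniformSignal` windows of identical
    length ``epoch_len * sr``; a trailing partial window is discarded.
    """

    epochs: list
    epoch_len: float
    sr: float

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i) -> UniformSignal:
        return self.epochs[i]


def lowpass(signal: UniformSignal, cutoff: float = 0.4, order: int = 4) -> UniformSignal:
    """Zero-phase Butterworth low-pass, applied channel-wise.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and cancels group delay.  Edges are reflect-padded by one settle length
    (three time constants of the cutoff) to suppress startup transients.

    Raises
    ------
    ParameterError
        If ``cutoff`` is not strictly inside (0, sr/2).
    """
    if not 0 < cutoff < signal.sr / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={signal.sr / 2} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=signal.sr, output="sos")
    settle = int(3.0 * signal.sr / cutoff)
    padlen = min(signal.n_samples - 1, settle)
    out = sps.sosfiltfilt(sos, signal.data, axis=1, padlen=padlen)
    return UniformSignal(out, sr=signal.sr, start_time=signal.start_time)


def make_epochs(signal: UniformSignal, epoch_len: float = 60.0) -> EpochSet:
    """Cut a signal into non-overlapping epochs of ``epoch_len`` seconds.

    The number of epochs is ``floor(duration / epoch_len)``; trailing samples
    that do not fill a whole epoch are discarded.

    Raises
    ------
    DataError
        If the signal is shorter than one epoch.
    """
    if epoch_len <= 0:
        raise ParameterError(f"epoch_len must be positive, got {epoch_len}")
    n_per = int(round(epoch_len * signal.sr))
    if signal.n_samples < n_per:
        raise DataError(
            f"signal of {signal.n_samples} samples shorter than one "
            f"{epoch_len} s epoch ({n_per} samples)"
        )
    n_epochs = signal.n_samples // n_per
    epochs = [
        UniformSignal(
            signal.data[:, i * n_per : (i + 1) * n_per],
            sr=signal.sr,
            start_time=signal.start_time + i * epoch_len,
        )
        for i in range(n_epochs)
    ]
    return EpochSet(epochs=epochs, epoch_len=epoch_len, sr=signal.sr)
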