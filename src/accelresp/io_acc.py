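"""Timestamped accelerometer I/O and fixed-rate resampling.

Smartphone accelerometers deliver samples at a *nonuniform* rate: the
operating system timestamps each 3-axis sample individually, and intervals
around the nominal period (here ~500 Hz) vary from sample to sample.  All
downstream spectral processing assumes a uniform rate, so the raw trace is
first regularised: the recording is laid out on a dense uniform grid (default
1000 Hz) where each grid point takes the value of the most recent raw sample
at or before it (zero-order hold), and that dense grid is then decimated by
an integer factor back to the working rate (default 500 Hz).

CSV conventions: comma-separated, UTF-8, header row required.  A trace file
has a time column (named ``t`` by default) plus ``x,y,z``; a uniform-signal
file has value columns only, with the rate recorded in a leading comment line
``# sr=500``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "AccelTrace",
    "UniformSignal",
    "read_accel_csv",
    "write_accel_csv",
    "read_uniform_csv",
    "write_uniform_csv",
    "to_fixed_rate",
]


@dataclass
class AccelTrace:
    """Raw nonuniformly timestamped 3-axis accelerometer samples.

    Parameters
    ----------
    timestamps : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    values : ndarray, shape (3, n)
        Axis samples (x, y, z) in m/s^2 or raw sensor units.
    nominal_rate : float
        Advertised mean sampling rate in Hz (metadata only).
    """

    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = 500.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.timestamps.ndim != 1:
            raise DataError("timestamps must be one-dimensional")
        if self.values.shape[1] != self.timestamps.size:
            raise DataError(
                f"values have {self.values.shape[1]} samples but "
                f"{self.timestamps.size} timestamps"
            )
        d = np.diff(self.timestamps)
        bad = np.nonzero(d <= 0)[0]
        if bad.size:
            raise DataError(
                f"timestamps not strictly increasing at row {bad[0] + 1} "
                f"(t={self.timestamps[bad[0] + 1]!r})"
            )

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UniformSignal:
    """Fixed-rate signal with 1..3 channels, channels-first layout.

    ``data`` has shape ``(n_channels, n_samples)``; ``sr`` is the sampling
    rate in Hz and ``start_time`` the absolute time of the first sample.
    """

    data: np.ndarray
    sr: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sr <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.sr}")
        if self.data.ndim != 2:
            raise DataError("data must be (n_channels, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sr

    def channel(self, i: int) -> np.ndarray:
        return self.data[i]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sr


def read_accel_csv(
    path,
    time_unit: str = "s",
    time_col: str = "t",
    nominal_rate: float = 500.0,
) -> AccelTrace:
    """Read a timestamped 3-axis trace from CSV.

    Parameters
    ----------
    path : str or path-like
    time_unit : {"s", "ms"}
        Unit of the time column; ``ms`` values are divided by 1000.
    time_col : str
        Name of the time column (default ``t``).

    Raises
    ------
    FormatError
        If the time column or any of ``x, y, z`` is missing.
    DataError
        If timestamps are not strictly increasing (the first offending row
        is named in the message).
    """
    if time_unit not in ("s", "ms"):
        raise ParameterError(f"time_unit must be 's' or 'ms', got {time_unit!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in (time_col, "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    t = df[time_col].to_numpy(dtype=float)
    if time_unit == "ms":
        t = t / 1000.0
    values = df[["x", "y", "z"]].to_numpy(dtype=float).T
    return AccelTrace(t, values, nominal_rate=nominal_rate)


def write_accel_csv(trace: AccelTrace, path, time_col: str = "t") -> None:
    """Write an :class:`AccelTrace` as a t,x,y,z CSV (time in seconds)."""
    df = pd.DataFrame(
        {
            time_col: trace.timestamps,
            "x": trace.values[0],
            "y": trace.values[1],
            "z": trace.values[2],
        }
    )
    df.to_csv(path, index=False)


def write_uniform_csv(signal: UniformSignal, path) -> None:
    """Write a :class:`UniformSignal` as CSV with a ``# sr=`` header line."""
    names = ["x", "y", "z"][: signal.n_channels] if signal.n_channels > 1 else ["value"]
    df = pd.DataFrame({n: signal.data[i] for i, n in enumerate(names)})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sr={signal.sr:g} start={signal.start_time:g}\n")
        df.to_csv(fh, index=False)


def read_uniform_csv(path) -> UniformSignal:
    """Read a :class:`UniformSignal` written by :func:`write_uniform_csv`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing '# sr=' header comment line")
    meta = dict(
        kv.split("=", 1) for kv in first.lstrip("#").split() if "=" in kv
    )
    if "sr" not in meta:
        raise FormatError(f"{path}: header comment does not declare sr")
    df = pd.read_csv(path, comment="#")
    return UniformSignal(
        df.to_numpy(dtype=float).T,
        sr=float(meta["sr"]),
        start_time=float(meta.get("start", 0.0)),
    )


def to_fixed_rate(
    trace: AccelTrace, up_hz: float = 1000.0, target_hz: float = 500.0
) -> UniformSignal:
    """Convert a nonuniform trace to a fixed rate by hold-then-decimate.

    A uniform grid at ``up_hz`` is anchored at the first timestamp and runs to
    the last; each grid point takes the value of the last raw sample at or
    before it (previous-value hold, so a grid point coinciding with a raw
    timestamp takes that raw value).  The dense grid is then decimated by the
    integer factor ``up_hz / target_hz``, keeping indices 0, k, 2k, ...

    No anti-alias filter is applied here: the respiration low-pass that
    follows in the pipeline removes everything above a fraction of a hertz.

    Raises
    ------
    ParameterError
        If ``up_hz`` is not a positive integer multiple of ``target_hz``.
    DataError
        If the trace has fewer than two samples.
    """
    if up_hz <= 0 or target_hz <= 0:
        raise ParameterError("rates must be positive")
    k = up_hz / target_hz
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ParameterError(
            f"up_hz ({up_hz}) must be an integer multiple of target_hz ({target_hz})"
        )
    k = int(round(k))
    if trace.n_samples < 2:
        raise DataError("resampling requires at least 2 samples")

    tau = trace.timestamps - trace.timestamps[0]
    # Guard against last grid point being lost to floating-point round-down.
    n_up = int(np.floor(tau[-1] * up_hz + 1e-9)) + 1
    grid = np.arange(n_up) / up_hz
    # Small forward tolerance so grid points that mathematically coincide
    # with a raw timestamp pick it up despite rounding (at-or-before hold).
    eps = 1e-4 / up_hz
    idx = np.searchsorted(tau, grid + eps, side="right") - 1
    held = trace.values[:, idx]
    out = held[:, ::k]
    return UniformSignal(out, sr=float(target_hz), start_time=float(trace.timestamps[0]))
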