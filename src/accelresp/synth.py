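"""Ground-truthed synthetic recordings for end-to-end validation.

The generator emulates the statistical structure the estimator assumes: a
quasi-periodic respiration source — concatenated breath cycles of a raised
cosine with decaying harmonics, each cycle's period perturbed by independent
Gaussian jitter — is linearly mixed with independent noise sources (one slow
in-band drift, the rest white) into three accelerometer axes, offset by
per-axis gravity constants, and observed at jittered timestamps around a
nominal 500 Hz grid.  A matched chest-belt signal shares the same breath
cycle times.

Harmonics are deliberate: they create cepstral rahmonics so the
second-harmonic logic of the quefrency selector is exercised.  Two RNG
streams (``mixing_seed`` vs ``noise_seed``) let the mixing geometry be held
fixed while the noise realisation varies.

What this synthetic world does *not* model: posture changes, motion-artifact
bursts, biomechanical chest-wall dynamics, or sensor quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, ParameterError
from .io_acc import AccelTrace, UniformSignal

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "CohortResult",
    "gen_respiration_source",
    "gen_trace",
    "gen_belt",
    "gen_cohort",
]


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    ``rr_bpm`` is the true mean breathing rate; ``rr_drift`` the fractional
    SD of independent cycle-to-cycle period jitter; ``harmonic_weights`` the
    amplitudes of the 2nd and 3rd waveform harmonics relative to the
    fundamental; ``snr_db`` the power of the respiration source relative to
    each unit-variance noise source; ``timestamp_jitter`` the uniform
    timestamp perturbation as a fraction of the nominal sample interval.
    """

    rr_bpm: float = 16.0
    rr_drift: float = 0.03
    harmonic_weights: tuple = (0.4, 0.15)
    n_noise: int = 2
    snr_db: float = 10.0
    mixing_seed: int = 0
    noise_seed: int = 1
    duration_s: float = 300.0
    mean_rate_hz: float = 500.0
    timestamp_jitter: float = 0.2
    gravity_offset: tuple = (0.12, 0.35, 9.81)
    internal_rate_hz: float = 2000.0
    epoch_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.rr_bpm < 60:
            raise ParameterError(
                f"rr_bpm must be in (0, 60) breaths/min, got {self.rr_bpm}"
            )
        if self.duration_s < 60:
            raise ParameterError("duration_s must be at least 60 s (one epoch)")
        if not math.isfinite(self.snr_db):
            raise ParameterError("snr_db must be finite")
        if self.n_noise < 2:
            raise ParameterError("need at least 2 independent noise sources")
        if not 0 <= self.timestamp_jitter < 0.5:
            raise ParameterError(
                "timestamp_jitter must be in [0, 0.5) of the sample interval"
            )
        ratio = self.internal_rate_hz / self.mean_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                "internal_rate_hz must be an integer multiple of mean_rate_hz"
            )


@dataclass
class GroundTruth:
    """True breathing structure of a synthetic recording."""

    rr_bpm: float
    onsets: np.ndarray  # breath-cycle onset times, seconds
    periods: np.ndarray  # per-cycle periods, seconds
    epoch_counts: np.ndarray  # breath onsets per full epoch
    epoch_rates: np.ndarray  # time-averaged instantaneous rate per epoch
    mixing: np.ndarray | None = None


def _cycles(cfg: SynthConfig, rng: np.random.Generator):
    """Draw breath-cycle onsets and periods covering the recording."""
    T0 = 60.0 / cfg.rr_bpm
    onsets = [0.0]
    periods = []
    while onsets[-1] < cfg.duration_s:
        jit = rng.normal(0.0, cfg.rr_drift)
        period = T0 * float(np.clip(1.0 + jit, 0.5, 1.5))
        periods.append(period)
        onsets.append(onsets[-1] + period)
    return np.asarray(onsets[:-1]), np.asarray(periods)


def _truth_from_cycles(cfg: SynthConfig, onsets, periods) -> GroundTruth:
    n_epochs = int(cfg.duration_s // cfg.epoch_s)
    edges = np.arange(n_epochs + 1) * cfg.epoch_s
    # Count onsets in [t0, t1); an onset within float tolerance of the upper
    # edge belongs to the next epoch (nominal onsets can land exactly on an
    # edge whenever the rate divides 60 evenly).
    tol = 1e-9 * max(cfg.duration_s, 1.0)
    marks = np.searchsorted(onsets, edges - tol, side="left")
    counts = np.diff(marks)
    # Time-weighted mean instantaneous rate 60/period(t) over each epoch.
    rates = np.empty(n_epochs)
    for e in range(n_epochs):
        t0, t1 = edges[e], edges[e + 1]
        overlap_lo = np.maximum(onsets, t0)
        overlap_hi = np.minimum(onsets + periods, t1)
        w = np.clip(overlap_hi - overlap_lo, 0.0, None)
        rates[e] = float(np.sum(w * 60.0 / periods) / np.sum(w))
    return GroundTruth(
        rr_bpm=cfg.rr_bpm,
        onsets=onsets,
        periods=periods,
        epoch_counts=counts,
        epoch_rates=rates,
    )


def _waveform(cfg: SynthConfig, onsets, periods, t: np.ndarray) -> np.ndarray:
    """Breath waveform at times t: raised cosine plus harmonics, continuous
    across cycle boundaries, one maximum per cycle (mid-cycle)."""
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, onsets.size - 1)
    phase = (t - onsets[idx]) / periods[idx]
    theta = 2.0 * np.pi * (phase - 0.5)
    w = np.cos(theta)
    for k, a in enumerate(cfg.harmonic_weights, start=2):
        w = w + a * np.cos(k * theta)
    return w


def gen_respiration_source(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[UniformSignal, GroundTruth]:
    """Generate the quasi-periodic respiration source at the internal rate.

    Returns the 1-channel source (internal high rate) together with the
    ground truth: cycle onsets/periods and per-epoch true counts and rates.
    """
    if seed is None:
        seed = cfg.noise_seed
    rng = np.random.default_rng([seed, 0])
    onsets, periods = _cycles(cfg, rng)
    truth = _truth_from_cycles(cfg, onsets, periods)
    fs = cfg.internal_rate_hz
    # Cover the closed interval [0, duration] so downstream hold-then-decimate
    # resampling retains the final epoch in full.
    n = int(round(cfg.duration_s * fs)) + 1
    t = np.arange(n) / fs
    x = _waveform(cfg, onsets, periods, t)
    return UniformSignal(x, sr=fs), truth


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _noise_sources(cfg: SynthConfig, n: int) -> np.ndarray:
    """Independent unit-variance noise sources (n_noise, n): one slow
    in-band drift (low-passed white noise) plus white Gaussian sources."""
    out = np.empty((cfg.n_noise, n))
    rng = np.random.default_rng([cfg.noise_seed, 10])
    sos = sps.butter(2, 0.3, btype="low", fs=cfg.internal_rate_hz, output="sos")
    drift = sps.sosfilt(sos, rng.standard_normal(n))
    out[0] = _standardise(drift)
    for k in range(1, cfg.n_noise):
        rng_k = np.random.default_rng([cfg.noise_seed, 10 + k])
        out[k] = _standardise(rng_k.standard_normal(n))
    return out


def _mixing_matrix(cfg: SynthConfig) -> np.ndarray:
    rng = np.random.default_rng([cfg.mixing_seed, 0])
    n_src = 1 + cfg.n_noise
    for _ in range(200):
        M = rng.standard_normal((3, n_src))
        if n_src != 3 or np.linalg.cond(M) < 20:
            return M
    raise ParameterError("could not draw a well-conditioned mixing matrix")


def gen_trace(cfg: SynthConfig) -> tuple[AccelTrace, GroundTruth]:
    """Synthesize a nonuniformly timestamped 3-axis recording.

    Respiration (scaled to ``snr_db`` relative to each unit-variance noise
    source) and the noise sources are mixed through a well-conditioned random
    3xN matrix, gravity offsets are added, and the result is read out at
    jittered timestamps around the nominal 500 Hz grid.
    """
    resp, truth = gen_respiration_source(cfg, seed=cfg.noise_seed)
    n = resp.n_samples
    gain = 10.0 ** (cfg.snr_db / 20.0)
    S = np.vstack([_standardise(resp.data[0]) * gain, _noise_sources(cfg, n)])
    M = _mixing_matrix(cfg)
    A = M @ S + np.asarray(cfg.gravity_offset, dtype=float)[:, None]

    nominal = np.arange(int(cfg.duration_s * cfg.mean_rate_hz) + 1) / cfg.mean_rate_hz
    rng_ts = np.random.default_rng([cfg.noise_seed, 999])
    jitter = rng_ts.uniform(-cfg.timestamp_jitter, cfg.timestamp_jitter, nominal.size)
    ts = nominal + jitter / cfg.mean_rate_hz
    ts[0] = max(ts[0], 0.0)
    ts = np.clip(ts, 0.0, (n - 1) / cfg.internal_rate_hz)
    t_int = np.arange(n) / cfg.internal_rate_hz
    values = np.vstack([np.interp(ts, t_int, A[i]) for i in range(3)])
    truth.mixing = M
    return AccelTrace(ts, values, nominal_rate=cfg.mean_rate_hz), truth


def gen_belt(cfg: SynthConfig) -> UniformSignal:
    """Chest-belt reference: the same breath cycles, nearly clean, at 500 Hz.

    Regenerates the respiration source from the same seed stream as
    :func:`gen_trace` (identical cycle times), decimates to the nominal
    rate and adds white noise at 30 dB SNR.
    """
    resp, _ = gen_respiration_source(cfg, seed=cfg.noise_seed)
    step = int(round(cfg.internal_rate_hz / cfg.mean_rate_hz))
    x = _standardise(resp.data[0][::step])
    rng = np.random.default_rng([cfg.noise_seed, 7777])
    noise = rng.standard_normal(x.size) * 10.0 ** (-30.0 / 20.0)
    return UniformSignal(x + noise, sr=cfg.mean_rate_hz)


@dataclass
class CohortResult:
    """Per-subject summaries and per-epoch detail for a synthetic cohort."""

    summaries: pd.DataFrame
    epoch_rates: list  # true per-epoch rates, one array per subject
    epoch_counts: list  # true per-epoch breath counts
    epoch_estimates: dict  # method -> list of per-epoch estimate arrays

    def comparison(self, method: str = "ica"):
        """Belt counts vs a method's rounded means as an RRComparison."""
        from .evalstats import RRComparison

        return RRComparison(
            labels=self.summaries["subject"].tolist(),
            rr_a=self.summaries["rr_belt"].to_numpy(dtype=float),
            rr_b=self.summaries[f"rr_{method}"].to_numpy(dtype=float),
        )

    def mae(self, method: str) -> float:
        """Mean absolute per-epoch error of a method against the true rate."""
        errs = []
        for est, truth in zip(self.epoch_estimates[method], self.epoch_rates):
            n = min(est.size, truth.size)
            errs.append(np.abs(est[:n] - truth[:n]))
        return float(np.concatenate(errs).mean())


def gen_cohort(
    n_subjects: int = 30,
    rr_range: tuple[int, int] = (15, 18),
    seed: int = 0,
    duration_s: float = 300.0,
    snr_db: float = 10.0,
    methods: tuple = ("ica",),
    estimator: str = "cepstrum",
) -> CohortResult:
    """Simulate a cohort and run belt counting plus the pipeline on each.

    Each subject gets an integer true rate drawn uniformly from ``rr_range``
    and an independent recording; the chest belt is peak-counted and the
    accelerometer trace is run through the full pipeline once per calibration
    method in ``methods``.

    Raises
    ------
    DataError
        If fewer than 2 subjects are requested.
    """
    from .baseline_rr import count_belt_peaks
    from .cepstrum_rr import PipelineConfig, estimate_rr

    if n_subjects < 2:
        raise DataError("a cohort needs at least 2 subjects")
    states = np.random.SeedSequence(seed).generate_state(2 * n_subjects + 1)
    rr_rng = np.random.default_rng([seed, 424242])
    rrs = rr_rng.integers(rr_range[0], rr_range[1] + 1, n_subjects)

    rows = []
    epoch_rates, epoch_counts = [], []
    epoch_estimates = {m: [] for m in methods}
    for i in range(n_subjects):
        cfg = SynthConfig(
            rr_bpm=float(rrs[i]),
            duration_s=duration_s,
            snr_db=snr_db,
            mixing_seed=int(states[2 * i] % 2**31),
            noise_seed=int(states[2 * i + 1] % 2**31),
        )
        trace, truth = gen_trace(cfg)
        belt = gen_belt(cfg)
        _, belt_rr = count_belt_peaks(belt)
        row = {"subject": i + 1, "rr_true": int(rrs[i]), "rr_belt": belt_rr}
        for m in methods:
            est = estimate_rr(
                trace,
                PipelineConfig(
                    calibration=m,
                    estimator=estimator,
                    seed=int(states[-1] % 2**31),
                ),
            )
            row[f"rr_{m}"] = est.mean_rounded
            epoch_estimates[m].append(est.per_epoch)
        rows.append(row)
        epoch_rates.append(truth.epoch_rates)
        epoch_counts.append(truth.epoch_counts)
    return CohortResult(
        summaries=pd.DataFrame(rows),
        epoch_rates=epoch_rates,
        epoch_counts=epoch_counts,
        epoch_estimates=epoch_estimates,
    )
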