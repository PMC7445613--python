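import numpy as np
import pytest

from accelresp import UniformSignal, gen_cohort


@pytest.fixture(scope="session")
def cohort30():
    """30 synthetic subjects at 15-18 breaths/min, 5 min each, run through
    belt counting and the pipeline under every calibration method.

    Session-scoped: this is the expensive fixture (ICA on 30 recordings);
    the acceptance tests and the synthetic-recovery tests share it.
    """
    return gen_cohort(
        n_subjects=30,
        rr_range=(15, 18),
        seed=1,
        duration_s=300.0,
        snr_db=10.0,
        methods=("ica", "rss", "x", "y", "z"),
    )


@pytest.fixture
def sine_epoch():
    """One 60 s epoch of a 0.25 Hz (15 breaths/min) unit sinusoid at 500 Hz."""
    t = np.arange(30000) / 500.0
    return UniformSignal(np.sin(2 * np.pi * 0.25 * t), sr=500.0)


def epoch_errors(cohort, method):
    """|estimate - true rate| per epoch, pooled over subjects."""
    errs = []
    for est, truth in zip(cohort.epoch_estimates[method], cohort.epoch_rates):
        n = min(est.size, truth.size)
        errs.append(np.abs(est[:n] - truth[:n]))
    return np.concatenate(errs)
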