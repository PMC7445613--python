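"""Compare axis-calibration methods on the same synthetic recording.

The same 3-axis trace is collapsed to a single channel five ways — ICA
component selection, per-sample root sum square (RSS), first principal
component, and each raw axis — and the cepstral estimator is run on each.
Across cohorts ICA is the most reliable calibration (see
synthetic_cohort_validation.py); on any single recording a fortunate axis or
the RSS can do just as well, while an unlucky axis — one the random mixing
loaded with noise — fails badly.
"""

import numpy as np

from accelresp import SynthConfig, estimate_rr, gen_trace

cfg = SynthConfig(rr_bpm=16, duration_s=300, snr_db=10, mixing_seed=4, noise_seed=9)
trace, truth = gen_trace(cfg)

print(f"true per-epoch rates: {np.round(truth.epoch_rates, 2)}")
for method in ("ica", "rss", "pca", "x", "y", "z"):
    est = estimate_rr(trace, calibration=method)
    n = min(est.per_epoch.size, truth.epoch_rates.size)
    mae = np.abs(est.per_epoch[:n] - truth.epoch_rates[:n]).mean()
    print(
        f"{method:>3}: per-epoch {np.round(est.per_epoch, 1)}  "
        f"mean {est.mean_rounded:2d}  MAE {mae:.2f} breaths/min"
    )
# Lower MAE = the calibrated channel carried the breathing signal more
# cleanly into the quefrency selection stage.  Axes differ because the
# mixing matrix loads respiration and noise unevenly onto them.
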