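# Methods

## Signal model

A smartphone lying near a reclining person observes, on its three
accelerometer axes, a linear instantaneous mixture of a quasi-periodic
respiration source and environmental noise sources, plus per-axis constants
(gravity projection):

    A(t) = U S(t) + g

with *A* the 3-axis measurement, *S* the statistically independent sources,
*U* the unknown mixing matrix and *g* the gravity offset. The model's
assumptions: mixing is instantaneous and stationary over a recording (no
convolutive echoes, no posture changes), at most one source is Gaussian, and
respiration is the only strongly periodic source in the 0.07–0.4 Hz band.

Respiration at rest is quasi-periodic with harmonic structure — each breath
repeats a similar non-sinusoidal waveform with a slowly wandering period.
That harmonic structure is what the estimator exploits, and it matters: a
perfectly sinusoidal "breath" puts a single line in the spectrum, which the
cepstral stage cannot localise reliably (see *Limitations*).

## Pipeline

**Fixed-rate resampling.** Mobile OS sensor stacks timestamp samples
individually around a nominal rate (~500 Hz). The trace is regularised by a
previous-value (zero-order) hold onto a 1000 Hz grid anchored at the first
timestamp — a grid point coinciding with a raw timestamp takes that raw
value, so an already-uniform trace passes through unchanged — followed by
plain decimation (every 2nd sample) to 500 Hz. No anti-alias filter is
applied at this stage; the 0.4 Hz low-pass that follows immediately removes
everything a hold step could alias into the band of interest.

**Band limiting.** A 4th-order Butterworth low-pass at 0.4 Hz, applied
forward-backward (zero phase, so breath peak timing is preserved), with
reflect padding of three cutoff time constants to suppress edge transients.
The filter family and order are this package's choice; only the cutoff is
externally prescribed.

**ICA calibration.** FastICA (tanh/log-cosh contrast, symmetric
decorrelation, eigendecomposition whitening, max 500 iterations, tolerance
1e-5, seeded) on the three filtered axes. Components are standardised to
zero mean, unit variance; mixing/unmixing are rescaled to preserve
`mixing @ unmixing = I` and exact reconstruction of the mean-removed input.
ICA runs once per recording and the selected component is epoched
(`ica_per_epoch=True` switches to per-epoch separation). The
respiration-bearing component is the one whose real cepstrum has the largest
max-to-median-absolute ratio inside the quefrency search range — a direct
proxy for the quantity the next stage maximises. Ties break to the lower
index. Sign/scale indeterminacy of ICA is harmless downstream: the cepstral
estimate is invariant to flipping or rescaling a component.

**Cepstral quefrency selection.** Per 60 s epoch the real cepstrum
c = Re(IFFT(log(|FFT(x)| + 1e-12))) is evaluated; index *q* corresponds to a
period of *q*/sr seconds. The search range SP for a band of
[rr_lo, rr_hi] breaths/min is

    sp_hi = round(60 * sr / rr_lo)        # slowest breath, longest period
    sp_lo = floor(60 * sr / rr_hi) + 1    # fastest breath, shortest period

i.e. (1251, 6000) samples at 500 Hz for the default 5–24 breaths/min band.
Let q_max be the in-range argmax (plateau ties to the lower quefrency). A
strongly periodic breath also produces rahmonics at multiples of the true
period, and noise can push one of them above the fundamental, so sub-peaks
at q_max/2 and q_max/3 are tested in order: if the cepstrum within
±5% of the sub-quefrency reaches at least 0.7 of c[q_max], the selection
moves there and the harmonic flag is set. Otherwise q* = q_max and the flag
reports whether a confirming rahmonic — a strict positive local cepstral
peak — exists within ±5% of 2·q_max. The rate is RR = 60·sr/q*, and the
per-recording summary is the mean epoch rate rounded half-up to an integer,
the granularity of per-minute respiration counting.

Design notes on this stage:

* The confirmation flag deliberately requires only the *presence* of a
  clear rahmonic, not the 0.7 threshold: second-rahmonic amplitudes decay
  with order for physiological waveforms, so a strength test of the
  confirming peak would rarely pass and the flag would be uninformative.
  The strong threshold applies only where it guards a decision (moving the
  selection to a sub-peak).
* Testing q_max/3 as well as q_max/2 is this package's extension: on
  harmonic-rich breaths the in-range argmax occasionally lands on the third
  rahmonic (observed on synthetic cohorts as isolated 5 breaths/min
  outliers), which a half-only rule cannot reach. Both the threshold (0.7)
  and window width (5%) are free parameters exposed in the configuration,
  as is an optional opposite-direction correction (`correct_double`).
* An optional relative spectral floor (`rel_floor`) can clamp the magnitude
  spectrum before the log. It is **off** by default: for signals with a
  physical noise floor, the floor's fine structure is what makes rahmonics
  decay with order, and clamping it measurably degrades cohort recovery.

**Baseline estimators.** Peak counting (minimum peak distance
sr·60/rr_hi — no two breaths closer than the fastest admissible breath),
the largest magnitude-spectrum bin in the band, and the best biased
autocorrelation lag over the band's lag range. The chest-belt reference is
scored by the same minimum-distance peak count per 1-minute epoch after the
same 0.4 Hz low-pass.

## Agreement statistics

* **Pearson r** on paired per-subject rates.
* **Wilcoxon rank-sum**: W = sum of pooled midranks of group A; tie-corrected
  variance n_a·n_b/12·(N+1 − Σ(t³−t)/(N(N−1))); 0.5 continuity correction
  toward the null mean; two-sided normal p. For small untied samples
  (N ≤ 12) the p-value comes from exact enumeration instead, as is
  conventional — at those sizes the normal tail approximation can be off by
  several hundredths (worst case 0.088 at 2+2, measured exhaustively).
* **Wilcoxon signed-rank** on paired differences: zeros dropped, midranks of
  |d|, exact enumeration of sign patterns for n ≤ 12, tie-corrected normal
  approximation with continuity correction above.
* **Bland–Altman**: bias = mean(b − a), limits of agreement ±1.96 sample SD
  (n−1 denominator).
* **Five-number summary** with interpolated quartiles and 1.5·IQR whisker
  fences (the numbers behind skeletal box plots; no drawing here).

Reported values round to two decimals, matching how such studies present
them. Three reference cohorts of per-subject rates ship with the package
(30 subjects belt-vs-accelerometer; 10 subjects by sensor placement; 10 by
phone model) and anchor the golden tests: W = 842, z = −1.11, p = .27,
r = 0.70, bias 0.43 breaths/min, LoA −1.47/+2.34 on the main cohort.

## Synthetic data

The generator emulates exactly the structure the method assumes, so every
stage is testable without recordings:

* **Breath source**: concatenated cycles of a raised cosine with 2nd/3rd
  harmonics (amplitudes 0.4 / 0.15 of the fundamental — strong enough to
  exercise the rahmonic logic), each cycle's period jittered by independent
  Gaussian noise (fractional SD `rr_drift`, default 3%). Continuity across
  cycle boundaries is guaranteed by construction (all terms are cosines of
  the cycle phase), and each cycle has a single maximum, so peak counting is
  well defined.
* **Noise sources** (≥2, unit variance): one slow in-band drift (white noise
  low-passed at 0.3 Hz) — the adversary that makes calibration matter — and
  white Gaussian sources. `snr_db` (default 10) scales the breath source
  against each unit-variance noise source.
* **Mixing**: a random 3×N matrix, redrawn until its condition number is
  below 20, plus gravity offsets (0.12, 0.35, 9.81) m/s².
* **Observation**: linear interpolation of the internally 2000 Hz mixture at
  timestamps jittered uniformly by ±20% of the nominal 500 Hz interval.
* **Belt**: the same breath cycles, decimated to 500 Hz, with 30 dB SNR
  additive noise.
* **Ground truth** carries per-epoch cycle *counts* (for comparison with
  peak counting) and the time-weighted true per-epoch *rate* (60/period
  averaged over the epoch). Recovery accuracy is judged against the rate:
  for breathing rates that divide 60 evenly, a nominal cycle onset falls
  exactly on every epoch boundary, so counts flip ±1 under any jitter — a
  windowing artifact, not estimator error.
* **Seeding**: two streams (`mixing_seed`, `noise_seed`) so the mixing
  geometry can be held fixed while noise varies; everything is deterministic
  given the seeds.

Default problem sizes used by the validation suite: 30-subject cohorts of
5-minute recordings (150 epochs), rates drawn uniformly from 15–18
breaths/min, SNR 10 dB. Under those conditions the pipeline's per-epoch
estimate lands within ±1 breath/min of the true rate in ≥ 90% of epochs,
and ICA calibration has lower mean absolute error than RSS and than the
worst single axis.

What the synthetic world does **not** model: posture changes, motion
artifact bursts, biomechanically realistic chest-wall dynamics, sensor
quantisation, or dropped-sample gaps. Passing these tests shows the
pipeline recovers rates under the stated statistical structure; it does not
certify performance on recordings that violate it.

## Numerical choices and degenerate inputs

* ε = 1e-12 inside the cepstral log avoids −∞ on exactly-zero bins;
  all-zero epochs raise a degeneracy error instead of returning noise.
* The hold grid uses a forward tolerance of 1e-4 of the grid period so a
  grid point that mathematically coincides with a raw timestamp takes that
  sample despite floating-point rounding.
* Rank-deficient axis covariance (eigenvalue ratio < 1e-10) aborts ICA with
  a degeneracy error; constant inputs to Pearson r and all-zero difference
  vectors to the signed-rank test do likewise.
* Rounding of per-recording summaries is half-up (`floor(x + 0.5)`).
* Epochs must hold at least 2·sp_hi samples so the search range is
  resolvable; shorter epochs are rejected up front.

## Limitations

* **Pure sinusoidal sources.** A breath with no harmonic content puts a
  single line in the spectrum; its cepstral signature is a broad cosine
  ridge of amplitude ~2·log(dynamic range)/n, which is smaller than the
  scale-free fluctuation of the log spectrum's remaining bins (~1.28/√n).
  Per-epoch cepstral estimates of a pure tone therefore scatter by several
  breaths/min irrespective of SNR. Harmonic structure is a premise of the
  method, not an optimisation.
* **Exactly periodic signals.** If the breath is perfectly periodic within
  an epoch, the log spectrum is itself periodic and all in-range rahmonics
  are exactly equal — the argmax is then decided by rounding noise, and only
  the subharmonic correction makes the selection deterministic. Any
  physiological period jitter (even 1%) smears the lines into smooth,
  well-ordered rahmonic peaks and removes the issue; drift-free synthetic
  input is a degenerate corner, not a realistic case.
* **Windowing bias.** For a noiseless periodic signal whose period does not
  divide the epoch, the raw cepstral argmax is biased by up to ~3–4% of the
  period; at 60 s epochs this is well inside the ±1 breath/min budget.
* The pipeline assumes the mixing is stationary per recording; position
  changes mid-recording break the single-ICA assumption (per-epoch ICA is
  available but slower and less stable on 60 s windows).
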