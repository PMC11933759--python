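# Methods

## Scope and model

`sleepalpha` analyzes two-channel prefrontal (FP1/FP2) resting-state EEG
recorded under eyes-open and eyes-closed conditions in a three-wave
longitudinal design, and relates sub-alpha-band activity to
self-reported sleep quality (PSQI). The analysis chain is:

1. **Preprocessing** — zero-phase 4th-order Butterworth bandpass
   (0.5–30 Hz, matching the acquisition passband), segmentation into
   non-overlapping 4 s epochs, and rejection of epochs with absolute
   amplitude > 150 µV or peak-to-peak z-score > 5 across epochs.
2. **Spectral estimation** — multitaper PSD per epoch (DPSS tapers,
   time-bandwidth product NW = 3, K = 5 tapers, plain eigenspectrum
   average), averaged over kept epochs, then averaged pointwise across
   the two prefrontal channels ("FP-mean"). One-sided density in
   µV²/Hz; 4 s epochs give a 0.25 Hz grid on which the band edges
   (7, 8.5, 9, 10.5, 11, 13 Hz) are exactly representable.
3. **Relative power** — band power divided by total power over
   0.5–30 Hz (configurable). Band integrals use the trapezoidal rule on
   the closed-interval grid slice, so a band's value reflects its true
   bandwidth and contiguous 0.5 Hz bins are exactly additive.
4. **Aperiodic/periodic decomposition** — the background is modeled as
   `psd(f) = offset + scale / (knee + f^exponent)`, fit by
   Levenberg–Marquardt on log10 power with all parameters
   log-transformed (positive by construction), three deterministic
   initializations (shallow/medium/steep), and two robust iterations
   that mask grid points lying more than 2.5 residual-MADs *above* the
   curve (oscillatory peaks). The periodic component is the signed
   linear-power residual, so `raw = aperiodic + periodic` holds
   identically. Component band powers share the raw total-power
   denominator, preserving that additivity at the band level.
5. **Statistics** — Pearson correlations (two-sided p, Fisher-z 95%
   CI) between band or per-bin relative power and the PSQI total, per
   month, pooled over months, per condition, for all participants and
   for the 22-member complete subgroup; paired t tests for the
   eyes-closed vs eyes-open (Berger) contrast per month and component;
   Bonferroni-corrected (m = 3) paired tests for cross-month stability;
   and a matched-pairs sample-size search on the noncentral t
   distribution.

## Aperiodic fit range

The background is fit over **3–24 Hz**, not the full analysis band.
Both edges of the 0.5–30 Hz range are shaped by the acquisition filter
and the offline zero-phase refilter (the combined PSD gain is ≈ 0.26 at
28 Hz); the knee model cannot follow that roll-off, and fitting through
it biases the curve upward through the alpha band by tens of percent —
enough to turn the aperiodic open/closed comparison into a spurious
positive. Inside 3–24 Hz the passband is flat and the fit is unbiased.
The range is a configuration parameter; the fitted curve is evaluated
on the full grid for the decomposition.

## The synthetic cohort generator

No recorded data ship with the package, so the generator is the ground
truth against which every stage is verified. It emulates:

* **Design** — the study's participation pattern: months 1/2/3 have
  27/25/40 participants, pairwise overlaps 24/25/23, 22 participants in
  all three months, 42 unique. Inclusion–exclusion over those counts
  forces a unique partition into membership cells (14 participants are
  month-3-only; none are month-1- or month-2-only).
* **Sleep trait and PSQI** — each participant has a standardized
  poor-sleep propensity z; the month-level state adds jitter
  (sd 0.3 before restandardization), so sleep quality is stable but not
  frozen across months. Each of the 7 PSQI components discretizes
  `0.75·state + noise` at fixed thresholds with marginal level
  probabilities (0.35, 0.40, 0.18, 0.07), giving a total with mean ≈ 6.5,
  SD ≈ 4.5 and full 0–21 support. The questionnaire total is the
  component sum.
* **EEG** — stationary Gaussian signals whose one-sided PSD is the
  1/f-like background (offset 0.05 µV²/Hz, scale 400, knee 20,
  exponent 2 at baseline; ≈ 120 µV² total power in 0.5–30 Hz) plus two
  Gaussian bumps: a main alpha bump (center 9.8 ± 0.15 Hz, sd 0.7 Hz)
  and a low-alpha bump (center 7.75 ± 0.15 Hz, sd 0.5 Hz). Time series
  are realized by frequency-domain amplitude shaping of seeded white
  noise, including the device's causal bandpass response; the two
  channels are independent realizations of the same target spectrum.
* **Condition contrast** — the main alpha bump amplitude is 5.5× larger
  with eyes closed (mean open amplitude 0.5 µV²/Hz); the background
  parameters have no systematic condition difference. Their
  recording-to-recording jitter (exponent sd 0.15, log-scale sd 0.10)
  is drawn independently per condition, representing minute-scale
  arousal drift between the two 3-minute recordings.
* **Trait coupling** — the low-alpha bump amplitude is
  `base·exp(0.7·v)` with `v = ρ·state + √(1−ρ²)·w`; w is a
  person-month disturbance shared by the two conditions. ρ is the only
  dial linking EEG to sleep quality.
* **Variance placement** — individual-stable spectral traits
  (participant-level exponent sd 0.10, alpha-amplitude log-sd 0.18,
  center sd 0.15) are deliberately smaller than recording-level
  variability (0.15 / 0.30). Because the pooled correlation treats 92
  participant-months as independent observations while participants
  recur across months, participant-stable spectral variance combined
  with the stable sleep trait inflates the sampling variance of pooled
  correlations in bands that should be null; the chosen split keeps the
  medium/high-alpha false-positive rate near nominal.

### Coupling calibration

The observable pooled correlation is attenuated relative to ρ by PSQI
discretization, the lognormal amplitude map, background variability and
spectral estimation noise. `calibrate_coupling` finds ρ by bisection
with common-random-number Monte-Carlo evaluation (spectrum-level
generation, 40 seeds, tolerance 0.005). The shipped defaults were
produced by that routine against the study-scale targets r = 0.45
(closed) and r = 0.26 (open): **ρ_closed = 0.731, ρ_open = 0.684**. On
50 held-out validation seeds the realized pooled correlations are 0.462
and 0.258.

### Spectrum-level fast mode

Calibration and replicate loops use a fast mode that skips time series:
the target PSD (with the full filter response) is smoothed over the
taper bandwidth (±NW/T = ±0.75 Hz boxcar, emulating the multitaper
expectation) and multiplied by independent Gamma noise with shape equal
to the estimator's averaging count (2 channels × 5 tapers × 45 epochs).
This neglects the correlation of neighboring frequency bins under the
shared tapers, slightly understating band-power variance; a cross-mode
test verifies that band powers from the two modes agree closely on the
same cohort. Full time-series generation is the default everywhere else.

### What the generator does not emulate

Blink/EMG artifact morphology (only optional large transients for
testing the rejection stage), non-stationarity within a recording
(bursty alpha), channel covariance between FP1 and FP2, sleep-stage
dynamics, and month-level systematic drift. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure the
generator encodes — not that real prefrontal EEG has that structure.

## Numerical choices

* Band edges snap to the nearest grid frequency within half a grid
  step; bands narrower than two grid points are rejected.
* The multitaper estimator de-means each epoch; DC and Nyquist bins are
  not doubled in the one-sided density.
* The sample-size search iterates n upward from 2; power is
  `P(T' > t_crit)` with T' noncentral t (df = n−1, ncp = dz·√n), both
  rejection regions for two tails. Note that at n = 2 (df = 1) the
  noncentral t is so heavy-tailed that 95% power is unattainable at any
  effect size; the two-tailed floor is n = 3.
* Pearson confidence intervals use the Fisher z transform (via
  scipy); paired tests with exactly zero differences return t = 0,
  p = 1 rather than an error.
* Fit non-convergence (all starts fail) yields a flagged fit; the
  pipeline logs and skips the recording's decomposition rather than
  aborting the run.
* Master seed → substreams via `numpy.random.SeedSequence` spawn keys
  derived from (participant index, month, condition index), so any
  recording can be regenerated in isolation and cohorts are
  bit-reproducible.

## Problem sizes

Replicate summaries and the acceptance script use 50 seeded replicates
of the full 92-participant-month cohort (184 recordings per replicate)
in spectrum-level fast mode; unit and property tests use cohorts or
epochs sized for the property under test (e.g. 100 spectra for exponent
recovery, 10⁴ null replicates for the paired-t type-I rate, 200
averaged epochs for PSD fidelity).

## Known limitations

* The open/closed specificity of the aperiodic component depends on the
  fit range avoiding the filter roll-off; analyzing data from a device
  with a different acquisition filter requires adjusting
  `fit.f_lo/f_hi` accordingly.
* Pooled correlations ignore the repeated-measures dependence of
  participant-months (as in the study design they mirror); the
  complete-subgroup and per-month analyses are the dependence-free
  views.
* EDF serialization is 16-bit; round-trips are exact only to the
  physical-range quantization step. Byte-exact reproducibility applies
  to the result tables, not to EDF sample values.
* The EDF writer emits a minimal single-patient, 1 s-record EDF; it is
  not a general-purpose EDF library.
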