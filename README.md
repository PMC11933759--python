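# sleepalpha

Analysis pipeline for a question in wearable-EEG sleep research: does
resting-state prefrontal EEG carry a *stable* spectral marker of
subjective sleep quality? `sleepalpha` implements the complete analysis
for a three-wave longitudinal design — two-channel (FP1/FP2) recordings
at 512 Hz under eyes-open and eyes-closed conditions, paired each month
with a Pittsburgh Sleep Quality Index (PSQI) questionnaire — and a
synthetic-cohort generator with the same statistical structure, so the
entire pipeline is testable end to end without any recorded data.

It is aimed at researchers working with portable frontal EEG who need a
reproducible reference implementation of:

* **multitaper spectral estimation** (DPSS tapers, NW = 3, K = 5) and
  **relative power**, `RP(band) = ∫_band S(f) df / ∫_{0.5}^{30} S(f) df`;
* **aperiodic/periodic decomposition**: the 1/f-like background
  `S_ap(f) = a + b / (c + f^d)` is fit on log-power with iterative
  peak masking, and the periodic component is the signed residual
  `S_per = S − S_ap`, so raw = aperiodic + periodic exactly;
* sub-alpha band quantification — low alpha (LA, 7–8.5 Hz), medium
  alpha (MA, 9–10.5 Hz), high alpha (HA, 11–13 Hz) — and Pearson
  correlation of each against the PSQI total (0–21, higher = worse
  sleep), per month, pooled, per condition, for the full sample and for
  the complete (all-three-months) subgroup;
* the eyes-closed alpha enhancement (Berger effect) tested as paired
  open/closed contrasts per month on raw, aperiodic and periodic
  relative alpha power, plus Bonferroni-corrected cross-month
  stability tests;
* a matched-pairs **sample-size search** on the noncentral t
  distribution.

## Worked example

Simulate the default synthetic cohort (42 participants, months with
27/25/40 participants, 22 complete) at the spectrum level and correlate
low-alpha relative power with the PSQI:

```python
from sleepalpha.pipeline import RunConfig, run

bundle = run(RunConfig(mode="simulate", generation="spectrum", seed=3))
bc = bundle.band_correlations
pooled = bc[(bc.subset == "all") & (bc.grouping == "pooled")
            & (bc.component == "raw") & (bc.condition == "closed")]
print(pooled[["band", "r", "p", "n"]].to_string(index=False))
```

```
 band         r        p  n
   HA -0.019389 0.854444 92
   LA  0.467255 0.000003 92
   MA -0.167440 0.110632 92
alpha -0.061468 0.560518 92
```

At this seed the pooled eyes-closed low-alpha correlation is r = 0.47
(p = 3·10⁻⁶, n = 92 participant-months) while MA/HA show no
significant association — the band-specific pattern the generator
encodes (calibrated so the closed-eye LA correlation averages ≈ 0.45
across seeds, against ≈ 0.26 for eyes open). The same bundle carries
the paired open/closed alpha-band tests (`bundle.paired_tests`):

```
 month component  n         t            p
     1 aperiodic 27  0.460767 6.487968e-01
     1  periodic 27  8.911222 2.208160e-09
     1       raw 27  7.873524 2.381801e-08
     2 aperiodic 25 -0.639581 5.285032e-01
     2  periodic 25  8.425804 1.245183e-08
     2       raw 25  5.357709 1.684654e-05
     3 aperiodic 40  0.762433 4.503883e-01
     3  periodic 40  7.286542 8.689981e-09
     3       raw 40  5.709801 1.310116e-06
```

Raw and periodic alpha power are higher with eyes closed at p < .001
in every month; the aperiodic background shows no condition effect —
the decomposition localizes the Berger effect in the periodic
component.

The sample-size computation for a matched-pairs design:

```python
from sleepalpha import sample_size_matched_pairs
sample_size_matched_pairs(0.65, alpha=0.05, power=0.95, tails=1)  # -> 28
```

A command-line interface wraps the same machinery:

```bash
sleepalpha simulate --seed 7 --out out/            # tables + manifest
sleepalpha simulate --seed 7 --out out/ --write-recordings   # + EDF files
sleepalpha analyze --recordings out/recordings --psqi out/recordings/psqi.tsv --out out2/
sleepalpha replicate --n 50 --seed 1 --out reps/   # multi-seed summary
```

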