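# asemlab

Analysis pipeline for experiments on **anticipatory smooth eye movements
(ASEMs) and manual interception**. Before a moving target appears, the eyes
often begin drifting slowly in the expected direction of motion; this
package quantifies that anticipatory response and relates it, trial by
trial, to how quickly a hand (cursor) movement is launched to intercept the
target. It is written for sensorimotor researchers who record 2-D eye
position (≈1 kHz) and cursor/hand position (≈60 Hz) in cue–target
interception paradigms with graded motion-coherence cues.

The package covers the full chain:

1. **Preprocessing** — zero-phase second-order Butterworth filtering
   (15 Hz eye position, 30 Hz eye velocity/acceleration, 20 Hz cursor),
   central-difference differentiation, saccade detection (velocity >
   30 deg/s AND |acceleration| > 1000 deg/s²), desaccading by linear
   interpolation, blink detection.
2. **Features & exclusion** — ASEM velocity (mean horizontal eye velocity
   over target-onset ± 50 ms), interception onset (first cursor sample with
   2-D speed > 1.0 deg/s) and latency, hand kinematics (initial direction,
   endpoint error, initial accelerations, peak velocities, movement time);
   trials excluded for motion-period blinks, ASEM-epoch saccades, pre-onset
   movement, or latency > 500 ms.
3. **Psychometrics** — per participant × condition fits of
   `v(x) = a/2·(1 + erf((x−μ)/(σ√2))) + b` (ASEM velocity vs signed
   coherence x) and `L(x) = c·exp(−(x−μ)²/(2σ²)) + d` (latency vs
   coherence), plus pooled within-participant z-normalized distributions.
4. **Inference** — paired t tests with Cohen's d, two-way repeated-measures
   ANOVA with Holm post hocs, a three-candidate mixed-model comparison of
   `latency ~ ASEM velocity` (correlated random intercept+slope / random
   intercept / fixed only) selected by BIC = −2 logLik + k ln(n), per-
   participant regressions with slope- and r²-vs-mean-latency correlations,
   and an upper-vs-lower-20% ASEM-stratum latency contrast.
5. **Synthetic cohorts** — a generator reproducing the study design (10
   participants × 2 conditions × 9 coherence levels × 20 trials, target at
   8.0 deg/s) with known ground truth, injected saccades/blinks, an
   explicit excludable-trial mode, and the three-set random-dot
   kinematogram — so every stage is testable without recorded data.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

Simulate a small cohort and run the full pipeline (library calls work the
same way; the CLI is a thin wrapper):

```sh
cat > demo.yaml <<EOF
simulation:
  n_participants: 4
  trials_per_cell: 8
  seed: 11
EOF
asemlab run-all --config demo.yaml --out demo --seed 11
cat demo/report.txt
```

which prints:

```
asemlab analysis report
=======================
config hash: e80161a81a9f184c
trials: 576  retained: 576 (100.0%)
ASEM velocity (control): 0.306 deg/s
ASEM velocity (gap): 0.560 deg/s
interception latency (control): 339.7 ms
interception latency (gap): 336.5 ms
sigmoid height control vs gap: t(3) = -4.50, p = 2.05e-02, d_z = -2.25
latency offset control vs gap: t(3) = 2.62, p = 7.87e-02, d_z = 1.31
LME selected: random_intercept (BICs: random_slope_intercept=-1544.1, random_intercept=-1553.2, fixed_only=-1509.9)
  fixed slope -0.0618 s/(deg/s) +- 0.0046, t(574) = -13.38, p = 9.65e-36
slope vs mean latency: r = -0.84, p = 0.161
r^2 vs mean latency: r = 0.99, p = 0.009
upper vs lower ASEM stratum latency: t(3) = -2.61, p = 0.079, mean diff = -39.4 ms
```

Reading this: the gap manipulation roughly doubles mean signed ASEM
velocity (0.31 → 0.56 deg/s), reflected in the sigmoid height contrast.
The mixed-model slope of latency on signed ASEM velocity is negative
(faster anticipatory eye movements go with earlier interception onsets) —
note that with the generator's default coherence-certainty component the
regression absorbs that pathway too, which is why the slope magnitude
exceeds the generative coupling of −0.03 s/(deg/s); `docs/methods.md`
discusses this identifiability point. The upper-20% ASEM trials start
their interception ~39 ms earlier than the lower-20% trials. At 4
participants the correlation p-values are illustrative only.

Intermediate products (`features.csv`, `fits.csv`, `report.json`, the
cohort directory with `metadata.csv` + `traces.h5`) are written alongside;
every table carries the analysis-configuration hash.

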