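# Methods

`asemlab` analyzes eye-hand coordination experiments in which a participant
intercepts a horizontally moving target while their gaze is tracked. The
quantity of interest is the anticipatory smooth eye movement (ASEM) — slow
pursuit-like eye drift that begins *before* target motion onset, in the
direction predicted by a preceding random-dot motion (RDM) cue — and its
trial-level relationship to the latency of the interception movement.

## Measurement model

Every trial provides a 2-D eye position trace at 1 kHz and a 2-D cursor
trace at 60 Hz, with metadata (condition, signed motion coherence
x ∈ {−0.64 … 0.64}, target direction ±1, target-onset time).

**Signal chain (module `preprocess`).** Eye position is low-passed with a
second-order Butterworth filter at 15 Hz; velocity and acceleration are
obtained by central differences (one-sided at the two boundary samples) and
low-passed at 30 Hz; the cursor uses the same contract with a 20 Hz cutoff.
All filtering is zero-phase (forward–backward), chosen so that event timing
(interception onset, the ASEM window) is not phase-shifted; the effective
magnitude response is the square of the second-order design, and
`butterworth_gain_squared` exposes it for verification. Saccades are
detected by the joint criterion velocity > 30 deg/s AND |acceleration| >
1000 deg/s² (horizontal axis by default — stimuli move horizontally; a 2-D
magnitude criterion is available via `saccade_axis="magnitude"`). A
detection seeds an interval that grows over the surrounding run of
super-threshold velocity, is padded by ±10 ms (configurable) and merged with
overlapping neighbours; the padded interval is excised from the filtered
position and bridged by linear interpolation, after which velocity and
acceleration are recomputed. Blinks are maximal runs of missing samples
padded by ±50 ms.

*Caveat on bridged gaps.* The slope of the interpolation bridge equals the
mean removed velocity over core + padding. For a saccade that barely
exceeds the velocity threshold, that mean is itself near the threshold, so
at the minimal ±10 ms padding the bridge can skim 30 deg/s; with ~20 ms
padding the bridged velocity stays well below threshold. The padding is a
configuration parameter for exactly this reason.

**Per-trial features (module `kinematics`).** ASEM velocity is the mean
desaccaded horizontal eye velocity over the closed window onset ± 50 ms;
`asem_velocity_signed` re-signs it so that the target direction is
positive. Interception onset is the first cursor sample whose 2-D speed
exceeds 1.0 deg/s; the search begins at the trial start (so pre-onset
movement is detectable) but skips a 50 ms warm-up guard where one-sided
differentiation at the trace edge is unreliable. Latency = interception
onset − target onset. Initial accelerations are means over the first 100 ms
after target onset; the initial direction is the angle from the +y midline
(rightward positive) of the vector from the start position to the cursor
position at peak 2-D acceleration; endpoint error is the absolute
horizontal distance to the target when the cursor first reaches the
target's vertical position, and movement time is that crossing minus
interception onset (the crossing-based definition is a package decision;
the underlying protocol lists movement time without defining it). Trials
are excluded for (i) blinks during target motion, (ii) saccades overlapping
the ASEM epoch, (iii) cursor movement before target onset (speed criterion
exceeded anywhere in [guard, onset), a package operationalization), or
(iv) latency > 500 ms (a missing onset counts as a latency violation). All
violated rules are reported; retention ⇔ empty reason set. No lower
latency bound is imposed: with a fully predictable onset time,
shorter-than-reaction-time latencies are legitimate anticipatory behavior.

## Response curves (module `psychometrics`)

Cell means per participant × condition × coherence are fitted with

* ASEM velocity: v(x) = a/2 (1 + erf((x − μ)/(σ√2))) + b — a cumulative
  Gaussian whose height *a* indexes the amplitude of the anticipatory
  response;
* latency: L(x) = c·exp(−(x − μ)²/(2σ²)) + d — a Gaussian peaking at low
  certainty whose offset *d* indexes overall interception latency.

Both are nonlinear least squares with five starts (μ ∈ {−0.2, 0, 0.2},
σ ∈ {0.1, 0.2, 0.3}) and bounds σ ∈ (1e-3, 2], |μ| ≤ 1; nine-point fits are
initialization-sensitive. r² = 1 − SS_res/SS_tot is reported as computed
(negative values possible for pathological fits; display clips at 0). Flat
data yield a = 0 with σ flagged unidentifiable and `converged=False`.
A known pathology of nine-point sigmoid designs: when the data do not
saturate within the tested coherence range, wide-σ solutions extrapolate
the height parameter far beyond the data; such fits are visible as σ near
its bound and inflate the between-condition height variance. Optional
inverse-variance weighting of cell means is off by default.

Distribution analysis: ASEM velocity is z-normalized per participant
across *all* that participant's retained trials, pooled, and cumulative
frequency curves are built per condition × coherence group. Unimodality is
checked with a dip-type statistic — the sup-norm distance from the
empirical CDF to the nearest unimodal CDF, computed by a greatest-convex-
minorant / least-concave-majorant scan over candidate modes — compared
against critical values simulated from matched Gaussian nulls (the null
distribution is size-dependent, so it is simulated, not tabulated).

## Statistics (module `inference`)

Paired condition contrasts use the paired t test; both Cohen's d
conventions are reported (d_z = mean(diff)/sd(diff), and d_av dividing by
the mean of the two level SDs), since they differ materially at n = 10.

The two-way repeated-measures ANOVA (condition × coherence) is computed
from balanced within-subject sums of squares, each effect tested against
its effect-by-subject interaction. This direct implementation keeps the
degenerate cases defined (zero effect SS → F = 0, p = 1; nonzero effect
with zero error → p = 0), which library routines reject; it reproduces
statsmodels `AnovaRM` to machine precision on non-degenerate data (tested).
Significant main effects get Holm-corrected pairwise paired t tests. A
Greenhouse–Geisser correction is available behind `greenhouse_geisser`
(sphericity handling in the underlying protocol is unstated, so the
uncorrected p is the default).

The trial-level coupling of latency with signed ASEM velocity is evaluated
with three nested candidates: (1) correlated random intercept + slope per
participant, (2) random intercept only, (3) fixed effects only. All are
fitted by maximum likelihood (not REML: the candidates differ in
random-effects structure and the fixed-only model has no REML analogue) and
compared by BIC = −2 logLik + k ln(n_obs), with k counting fixed effects,
unique random-covariance entries, and the residual variance (k = 6, 4, 3).
The fixed-slope test uses the residual-df convention df = n_obs − 2.
Boundary fits (zero random-slope variance) are flagged `singular`; the
optimizer cascade rejects non-finite likelihoods. Marginal and conditional
r² are both reported because a single mixed-model "r²" is ambiguous.
Per-participant simple regressions (slope, intercept, r², mean latency)
feed Pearson correlations of slope-vs-mean-latency and r²-vs-mean-latency,
the individual-differences analysis separating predictive from reactive
interceptors. The extreme-stratum control analysis ranks control-condition
trials within each participant × coherence cell by signed ASEM velocity
(stable sort; ties broken by trial order), selects the top and bottom
floor(0.2·n) (minimum 1; cells under 5 usable trials are skipped and
counted), and contrasts the per-participant stratum latency means with a
paired t test.

## Synthetic cohorts (module `synth`)

The generator emulates the study design — 10 participants × 2 conditions ×
9 signed coherence levels × 20 trials, target at 8.0 deg/s, eye 1 kHz,
cursor 60 Hz — with known ground truth. Per participant i, sigmoid
parameters (a_control, a_gap, μ, σ, b), latency-curve parameters
(c, μ, σ, d) and coupling parameters (β0, β1) are drawn from configurable
normal populations. Per trial:

* true ASEM velocity = sigmoid of signed coherence (height a_gap or
  a_control by condition) + N(0, 0.3) trial noise;
* true latency = d_i + c_i·exp(−(x−μ)²/2σ²) + β0_i + β1_i·(signed ASEM) +
  N(0, 0.05 s), clipped to [0.05, 0.45] s for non-violation trials.

Default population means put the direction-signed ASEM velocity near
0.28 deg/s (control) and 0.52 deg/s (gap) averaged over the nine coherence
levels, latency near 300–360 ms, and the coupling at β1 = −0.03 s/(deg/s)
with participant slope SD 0.01 — the scale of the phenomena the analysis
is built for.

**Trace shape.** Eye velocity is fixational noise (white velocity noise,
SD 0.2 deg/s, integrated to position) until 0.3 s before onset, then a
smoothstep ramp to the trial's true ASEM velocity *ending 80 ms before
onset*, a plateau through the measurement window, and a first-order
approach (τ = 120 ms) to 8.0 deg/s pursuit starting 100 ms after onset.
The plateau is deliberate: it makes the windowed mean identify the
generative value exactly, so noise-free recovery is an identity rather than
an approximation (a ramp reaching its target exactly at onset would bias
the windowed mean to 0.958× the generative value). The cursor is
stationary until onset + true latency, then follows a minimum-jerk
(bell-velocity) reach of 0.4 s toward the analytic interception point
(horizontal aim scatter SD 0.5 deg). Spontaneous saccades
(Poisson, 0.4 /s; amplitudes 0.4–1.0 deg, minimum-jerk displacement) and
pre-onset blinks (150 ms missing runs, p = 0.1/trial) are injected only
*outside* the exclusion-triggering windows; the explicit violation mode
plants excludable trials (motion-period blinks, ASEM-epoch saccades,
pre-onset movement, latencies > 500 ms) at a stated rate, so the planted
fraction is the expected exclusion rate by construction.

**What the generator does not emulate.** (i) Latency measurement carries a
systematic +10–25 ms offset (speed-threshold crossing of the bell profile
plus 60 Hz frame quantization) — absorbed into intercepts, irrelevant to
slopes. (ii) The condition effect on latency arises only through the ASEM
coupling (~7 ms), smaller than typically observed; the latency offset d is
condition-independent by design. (iii) The certainty component
c·exp(−x²/2σ²) is negatively correlated with signed ASEM velocity (both are
driven by |coherence|), so latency~ASEM regressions estimate β1 *plus* that
pathway (≈ −0.05 s/(deg/s) at the default c = 0.12). Coupling-recovery and
type-I simulations therefore set c = 0, the configuration in which β1 is
identified; with c > 0 the regression measures the combined quantity, just
as it does in real data. (iv) Small sub-threshold saccades survive
desaccading (as in real recordings); they are planted away from the ASEM
window. (v) Clipping non-violation latencies at 0.45 s truncates the upper
tail slightly; without it, chance latencies beyond 500 ms would contaminate
the exclusion bookkeeping.

Passing recovery tests on these cohorts therefore demonstrates that the
pipeline measures what the generative model encodes; they do not certify
behavior on pathologies the generator omits (drift, calibration error,
asymmetric saccade shapes, non-Gaussian latency tails).

**RDM stimulus.** `generate_rdm_frames` reproduces the three-interleaved-
set kinematogram: each set is redrawn three frames after it was shown,
each dot displaced by speed·3/refresh deg in the coherent direction with
probability |coherence| (signal flag), otherwise re-placed uniformly in the
circular aperture. The density convention 16.7 dots/deg²/s is interpreted
as dots drawn per deg² per second aggregated over frames (≈ 49 dots per
frame for a 15-deg aperture at 60 Hz; configurable). Signal displacements
that would exit the aperture wrap across the horizontal chord and carry a
`wrapped` flag so displacement checks can distinguish them.

## Problem sizes and determinism

Everything is driven by `numpy.random.default_rng` seeds; identical
configuration + seed gives bit-identical cohorts. Validation runs use:
noise-free identity at 10 participants × 2 trials/cell (cell means are
independent of trial count when noise is zero); coupling recovery and
exclusion bookkeeping at the full 10 × 360 design; detector/oracle
agreement over 200 seeded 3-s traces; type-I calibration over 500
replicates of a reduced 10 × 90 design using the trial-scalar generator
directly (the claim under test concerns the statistical layer, and the
trial table is the same statistical model the trace renderer consumes).

## Known limitations

* The BIC comparison's ability to detect random-slope variance at
  SD 0.01 s/(deg/s), residual 0.05 s and 360 trials/participant sits near
  the decision boundary (expected likelihood gain ≈ penalty); across seeds
  the selected model can flip. The fixed-slope estimate is insensitive to
  this choice.
* Nine-point sigmoid fits can enter the wide-σ regime (above); downstream
  height contrasts inherit that variance.
* The external-data adapter is a documented import contract (write the
  cohort directory layout described in `asemlab.io`), not a reader for any
  specific acquisition system's native files.
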