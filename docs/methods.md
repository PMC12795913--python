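# Methods

This note documents the models, conventions, parameter choices and
known limitations behind `vptsim`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Units and the device model

Stimulus intensity exists in three coordinate systems: the actuator
command (percent of full power), rms acceleration (g), and level in dB
re 10⁻⁶ m/s² rms per ISO 13091-1:

    amp [m/s²] = g · one_g,     dB = 20·log₁₀(amp / 10⁻⁶)

`one_g` defaults to standard gravity, 9.80665 m/s², and is
configurable. Because the conversion is a pure offset on the dB scale,
replacing 9.80665 by 9.90665 (a value that appears in some published
materials, almost certainly a misprint) shifts every level by exactly
20·log₁₀(9.90665/9.80665) ≈ 0.088 dB — far below any behaviorally
relevant difference, but worth documenting.

A command of 0% means "stimulus off" and is a distinct sentinel level
with no dB value; it is never represented as −∞ and the conversion
functions refuse non-positive accelerations.

Hardware controls amplitude as a command percentage, and the mapping
from percent to physical amplitude is actuator-specific. Two device
models are provided:

* `linear_acceleration` — output g rms scales linearly with the
  command up to a per-frequency ceiling, like a piezo actuator driven
  below resonance;
* `linear_db` — the command maps affinely onto the dB axis
  (`db = db_min + (percent−1)/99 · (db_max−db_min)`), so every 1% step
  is the same decibel increment. Up-down convergence theory assumes
  equal steps on the decision axis, so this mode is used for all
  convergence benchmarks. The benchmark device spans 60–159 dB (1 dB
  per percent), covering the plausible range of finger VPTs at
  250–500 Hz, and makes the procedures' 5%/2% steps exactly 5/2 dB.

Actuator ramp-up/ramp-down transients and resonance are not modeled.

## Observers

An observer is a map from (frequency, location) to psychometric
parameters, a reaction-latency model, and a private RNG stream.
Detection is Bernoulli with

    Ψ(x) = guess + (1 − guess − lapse) · Φ((x − μ)/σ)

on the dB axis; at stimulus-off the detection probability is the guess
rate (it doubles as the false-alarm rate, which matters because both
procedures begin at 0%). A `deterministic_step` form (detect iff
x ≥ μ, guess = lapse = 0, no RNG consumption) exists so that whole
tracks are hand-traceable; the guess rate is allowed up to 1 so that
degenerate "always detecting" observers can exercise the floor
termination rule, which real participants do occasionally trigger.

Latencies are zero or lognormal, parameterized by target mean and SD in
seconds via moment matching (no latency distribution is available from
human data; 0.4 ± 0.15 s is a plausible simple-reaction default). The
`detection_only` flag applies latency only to "detected" presses —
a mechanism by which slow reactions inflate continuous-tracking
thresholds specifically on the rising flank (tested property: enabling
it raises mean tracked estimates).

A population model draws participants by adding a shared offset
u_i ~ N(0, τ²) to every condition midpoint. Defaults: per-condition
means calibrated to observed continuous-tracking means at
250/375/500 Hz × index/ring (≈ 108–124 dB), τ = 10 dB (consistent with
observed between-participant SDs of ~9–16 dB), σ_psych = 4 dB (a free
simulation choice — participant-level psychometric slopes are not
identifiable from published summaries), guess 0.02, lapse 0.01.

Observers own their RNG streams (hierarchically spawned from the master
seed), so engines take no separate RNG argument and any single
participant-condition cell replays in isolation.

## Continuous (von Békésy) tracking

Time is discretized to the hardware tick (1.25 s); sub-tick dynamics
are unobservable to the procedure, so latencies round to the nearest
tick. Each epoch: move the command by the active rate in the current
direction (clamped to [0, 100]); sample a detection at the new level;
if the sampled state differs from the reported state and no press is
pending, schedule a press after the sampled latency (a single toggle
key cannot race itself, so at most one press is pending); a due press
toggles the reported state, flips the direction, and records a
reversal at the current level. The rate drops from 5%/tick to 2%/tick
the moment the second reversal registers. The re-press allowance real
participants get when unsure is not modeled (observers are never
unsure).

Termination: *completed* at ≥ 30 s and ≥ 8 reversals; *ceiling* after
15 s pinned at 100% with "not detected" reported; *floor* after 15 s
pinned at 0% with "detected" reported. The initial (pre-press) state
counts as "not detected" for the ceiling rule, otherwise a
never-detecting observer could not terminate. A 600-s hard cap raises
a runaway error.

## Staircase

Discrete trials: 2 s stimulus, answer prompt 1 s later, next trial 1 s
after the answer, so the answer-to-answer interval is 4 s plus
latency. Amplitude starts at 0% (trial 1 is effectively a catch
trial), rises after each miss, and falls after `n_down` consecutive
detections (3 in the standard rule; 1 gives the 50%-point variant).
Consecutive-answer counters reset on every amplitude change — the
standard transformed up-down bookkeeping, equivalent under 3D/1U to
requiring the three detections at a single level. A reversal is
recorded at the level of the trial whose answer completed the rule
that flipped the direction; steps are 5% until the second reversal is
recorded and 2% thereafter.

Termination: *completed* at 8 reversals; *ceiling*/*floor* after 3
consecutive misses at 100% / detections at 0%. Bound counts are
required to be consecutive (a reading choice; the rule is stated
ambiguously in the methods literature), and bound abandonment
pre-empts any reversal the same answer would imply, so a floored track
reports zero reversals.

## Threshold estimation

Both estimators work on the dB scale (thresholds are conventionally
reported in dB) and discard the first two reversals, which belong to
the coarse-step approach phase:

* staircase: mean of reversal levels 3–8, defined only for tracks with
  exactly 8 reversals;
* tracking: mean of reversal levels 3..R with an odd tail reversal
  dropped so only complete high/low pairs enter (R = 13 averages
  reversals 3–12). Completed tracks have R ≥ 8; R = 8 is accepted so
  every completed track yields an estimate.

Incomplete tracks yield missing estimates (the "NA" exclusions that
propagate into the statistics stage). Time-to-complete (TTC) is the
interval between the first and last answers — trial answer times for
the staircase, press times for tracking — and is missing whenever the
threshold is.

### Small-sample bias of the reversal average

The reversal-average estimator is asymptotically unbiased for its
target point but carries an **entry transient** under the
coarse-to-fine schedule: the 5%-step descent after the first reversal
overshoots low, and the first fine-step reversals are first-passage
events from below. With the standard termination rules only ~6–7 fine
reversals are averaged, and simulations in this package (σ = 4 dB,
steps 5/2 dB) show the mean estimate landing ≈ 0.4–0.6 dB below the
stationary point — ≈ 5 percentage points on the probability scale — for
both the 1D/1U staircase and zero-latency continuous tracking, while
the same procedures run to 40 reversals or 120 s recover their target
points to within 0.1 dB. The 3D/1U rule is much less affected because
its descent requires three consecutive detections per step and so
barely overshoots. This is a property of the procedures as actually
terminated, not of the implementation: a minimal independently coded
1D/1U simulation reproduces the same value. Consequently the package's
convergence benchmarks report ≈ 77–78% for 3D/1U (nominal 79.4%) and
≈ 44–46% for the 50%-point procedures; `scripts/acceptance.py` and the
test suite compute these numbers rather than asserting the nominal
ones away.

## Synthetic study generation

Two deliberately separate routes:

* **Mechanistic** (`run_study`): 30 observers drawn from the
  population (18 male / 12 female by default, gender effect zero —
  none is established in human data), 6 conditions shuffled
  independently per method, method order counterbalanced (even-indexed
  participants track first), every condition run through the actual
  engines. Missingness arises structurally from ceiling/floor
  terminations. With zero-latency observers the mechanistic method
  effect is *positive* (staircase ≈ +0.8 σ above tracking ≈ +3.3 dB at
  σ = 4), because 3D/1U targets a higher psychometric point; human
  studies report the opposite sign, which requires additional
  mechanisms (reaction latency on detections, adaptation) that the
  latency model can switch on.
* **Direct generative** (`generate_tidy_direct`): rows drawn straight
  from y_ij = X_ij β + u_i + ε_ij, for testing the statistics stage
  against known truth. The default preset uses the reported fixed
  effects (intercept 112.17; +7.78 at 375 Hz; +13.80 at 500 Hz; −4.91
  staircase; −1.47 ring; 0 gender), τ = 10 dB and σ_resid = 6 dB as
  plausible variance components (none are published), and a 10/360
  missing-completely-at-random rate mirroring the observed exclusion
  count. This preset encodes the method effect as a mean shift and
  makes no mechanistic claim.

## Statistics

Mixed models are fitted with `statsmodels`' `MixedLM` (falling back
through lbfgs → bfgs → cg → powell if an optimizer's Hessian is
singular); the package owns everything reported on top of the
optimizer:

* Wald-t inference with DF = n_obs − n_groups − (p − 1), where p
  counts fixed coefficients including the intercept (350 observations,
  30 participants and 5 coefficients give DF = 316). Satterthwaite or
  Kenward–Roger corrections are deliberately not used.
* CI = b ± t₀.₉₇₅,DF · SE; effect size r = √(t²/(t² + DF)) (this
  arithmetic reproduces published r values from their printed t and
  DF, e.g. t = −7.42, DF = 316 → r = 0.39).
* Likelihood-ratio ladder: intercept-only OLS baseline → participant
  random intercept → +Frequency → +Method → +Hand location → +Gender,
  all by ML on identical rows; χ² = 2·Δloglik with df = parameter-count
  difference (the τ² = 0 boundary is ignored, as is conventional in
  applied ladders). Factors significant at α = 0.05 are retained and
  the selected model is refitted by REML for variance-unbiased
  estimates.
* Descriptive per-condition tables report mean, SD, min, max and a
  normal-approximation 95% CI (mean ± 1.96·SD/√n), with missing values
  excluded per cell; single-observation cells report no SD/CI.

Frequency reference levels are configurable so the model can be
re-expressed with 500 Hz as the intercept; the re-referenced 375 Hz
coefficient equals b₃₇₅ − b₅₀₀ of the original fit to numerical
tolerance (a tested identity).

## What the simulations do and do not show

The synthetic observers are stationary: no temporary threshold shift,
adaptation, learning of the staircase rule, anticipation, inter-finger
mechanical crosstalk, or skin-temperature / contact-pressure effects.
Passing tests therefore validate the *procedures, estimators and
statistical machinery* under a known psychophysical model — they do not
certify that human thresholds behave this way, and in particular the
sign of the method effect in mechanistic simulations (staircase above
tracking) is expected to differ from human data unless latency or
adaptation mechanisms are enabled.

Problem sizes used by the benchmarks: 500 replicate tracks per
convergence point, 10⁴ presentation blocks for the re-presentation
check, 200 replicate datasets (× 2 fits) for parameter recovery, and
500 replicates for CI-coverage — sizes at which the Monte-Carlo error
of each reported mean is an order of magnitude below its comparison
tolerance, while a full run stays under a minute on one CPU.
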