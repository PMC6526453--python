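# Methods

## Model

The decision process is a Wiener diffusion between two absorbing
boundaries: evidence `X(t)` starts at `z = z_r · a`, drifts with rate `v`
and within-trial standard deviation `s = 1` (the scaling convention; some
software uses `s = 0.1`), and a response is produced when `X` reaches `a`
("word", upper) or `0` ("nonword", lower). Observed RT is the first-passage
time plus nondecision time `t0`. Across trials `v ~ Normal(v_c, s_v)`,
`z_r ~ Uniform(z_r,c ± s_zr/2)` and `t0 ~ Uniform(t0 ± s_t0/2)`; these
variabilities let the model produce both fast errors (start-point
variation) and slow errors (drift variation). Drift and relative starting
point are condition-specific (word vs. nonword stimuli); `a`, `t0`, `s_v`,
`s_zr`, `s_t0` are shared. `s_zr` is a *relative* start range (fraction of
`a`), and the starting-point interval must stay inside (0, 1), the
nondecision interval above 0.

Parameter roles: larger `|v|` = more efficient evidence accumulation;
larger `a` = more conservative responding (slower, more accurate);
`z_r ≠ 0.5` = a priori response bias; `t0` = encoding + motor time. In the
paper-based task, participants can preview the next item while still
marking the previous one, which motivates condition-specific starting
points biased toward the correct response.

## First-passage mathematics

Two exact series representations of the defective lower-boundary density
and CDF are implemented and selected per evaluation:

* **large-time** trigonometric series
  `g(t) = (π/a²) e^{−vz} Σ k sin(kπ z_r) e^{−λ_k t}`,
  `λ_k = (v² + k²π²/a²)/2`, integrated term-by-term for the CDF, with the
  truncation order chosen from an error bound (target ~1e−10) including the
  `e^{−vz}` prefactor;
* **small-time** method-of-images series; the CDF terms are combinations of
  single-boundary inverse-Gaussian CDFs and are evaluated in log space
  (`log Φ`) so that extreme drift–boundary products cannot overflow or
  cancel catastrophically.

The switch point is `t = 0.04 a²`, moved upward where the large-time
prefactor would exceed ~e²⁵ (strong drift away from the boundary), where
the alternating large-time sum loses precision. The upper boundary is
evaluated by the reflection `(v, z_r) → (−v, 1 − z_r)`. Choice
probabilities use the closed form `P_lower = (e^{−2va} − e^{−2vz}) /
(e^{−2va} − 1)` computed through `expm1` on the reflection branch where all
exponents are non-positive.

Across-trial variabilities are marginalized by deterministic quadrature:
Gauss–Hermite in drift (20 nodes) and Gauss–Legendre in starting point and
nondecision time (10 nodes each); zero variability collapses to a single
node, making the degenerate case exact. Deterministic quadrature keeps the
fit objective smooth for the SIMPLEX search.

Two evaluation paths exist: an exact path (`predicted_signed_cdf`) that
evaluates the series at the requested points, and a fast path
(`SignedCDFGrid`) used inside the fit objective, which computes the
decision-time CDFs once per parameter vector on a fixed 265-point grid
(geometric below 0.12 s, linear up to 3.8 s), factorizes the large-time
series over the starting-point nodes, and evaluates samples by linear
interpolation with the nondecision mixture applied as a shift. The grid
path agrees with the exact path to better than ~3e−4, an order of magnitude
below the sampling noise of the empirical CDFs it is compared against.

## Simulator

Trials are simulated by Euler–Maruyama steps (`dt = 5e−5 s` default) with
two standard discretization corrections: the boundaries are pulled inward
by `0.5826·√dt` (the Riemann-zeta continuity correction for discretely
monitored barrier crossing) and half a step is subtracted from the crossing
time. With these corrections the simulated signed-RT distribution agrees
with the analytic CDF to sup-distance < 0.01 at 10⁵ trials (the remaining
gap is mostly Monte-Carlo noise). The step size matters more than it first
appears: in parameter-recovery experiments the simulator *generates the
data*, and at `dt = 2e−4` its residual ~3e−3 distribution distortion is
resolvable at ~1000 trials per condition and displaced estimates along the
shallow valley of the KS objective (boundary separation biased low by
several percent). `dt = 5e−5` makes the discretization error negligible
relative to estimator precision while simulation remains a small fraction
of total cost.

## Estimation

Per participant, each condition's trimmed trials form a sorted signed
sample; the objective is the sum over conditions of the log KS p-value
(`λ = D(√n + 0.12 + 0.11/√n)` with the Kolmogorov tail series, evaluated in
log space so poor fits retain gradient). Optimizing p rather than D weighs
conditions with unequal trial counts comparably. Because the trials were
trimmed to an RT window, the model CDF entering the KS comparison is
*conditioned on that window* (restricted and renormalized); this removes
the truncation bias that fitting the unconditioned CDF to trimmed data
would introduce. If a sample contains RTs outside the configured window,
conditioning is skipped.

Search: Nelder–Mead with box constraints by penalty
(`a ∈ (0.1, 10)`, `|v| < 10`, `z_r ∈ (0.02, 0.98)` with the start interval
inside (0,1), `t0 − s_t0/2` between 0.03 s and the fastest observed RT,
`s_v ≤ 2.5`). Starting values are moment-based (EZ-style): per-condition
drift and boundary from edge-corrected accuracy and correct-RT variance,
`t0 = 0.9 ×` minimum RT, starting points from the response-proportion
asymmetry, small fixed variabilities. The KS surface has distinct local
basins for different response-bias structures, and multiplicative jitter
around one start cannot cross between them; the restarts therefore combine
the moment-based start with two bias-structured starts (starting points
0.66/0.36 and 0.36/0.66, larger initial variabilities) plus jittered copies
(±20%, seeded). Restarts run on a coarser quadrature (factor 0.4); the best
restart is polished at full resolution with 1.5× the per-restart evaluation
budget (default 500). Reported KS statistics are recomputed at the estimate
with the exact path. Degenerate data (e.g. all responses at one boundary)
return `converged=False` rather than raising.

At the study's trial counts (~1000 per condition), drift rates, boundary
separation, starting points and nondecision time recover to within ~10%
(across-participant means of a homogeneous cohort considerably better);
the across-trial variabilities are weakly identified — `s_zr` in
particular is biased low by up to ~25% — which is the known cost of
KS-based fitting of the full variability model. At near-ceiling accuracy
the error-side starting point inherits this weakness: with ~99% correct
nonword responses only a handful of error trials constrain
`z_r`(nonword), and its estimate compresses toward 0.5 by up to ~+0.06
(the KS objective is nearly flat in it; restarting the search at the
generating values lands at the same compressed optimum). Boundary
separation shows a residual low bias of several percent of the same
origin.

## Fit assessment

A participant's model p-value is the minimum of the two condition p-values
(conservative and monotone; the pooling rule is a package choice). Because
KS power grows with n, the nominal cutoff over-flags large datasets; the
calibrated criterion simulates `n_sims = 1000` datasets from a multivariate
normal over the cohort's fitted parameter vectors (mean and covariance
across participants; diagonal fallback if singular; redraws until parameter
invariants hold), with per-condition trial counts resampled from the
empirical counts, refits each with the same configuration, and takes the
empirical `alpha = 0.01` quantile of the simulated model p-values as the
critical value. Flags are `model_p < critical_p`. Sensitivity analyses
rerun the group statistics excluding flagged participants.

## Group statistics

Balanced 2×2 mixed-design ANOVA by sums-of-squares decomposition
(between error: subjects within groups; within error: condition ×
subjects within groups), partial `η² = SS_eff/(SS_eff + SS_err)`. With
unequal group sizes the weighted (sample-size) decomposition is used.
Follow-ups to a significant interaction are the four simple effects (two
between-group t-tests within condition, two paired t-tests within group),
Bonferroni-adjusted over the family of four. Shared parameters (`a`, `t0`,
variabilities) are compared by pooled-variance t-tests
(`df = n₁ + n₂ − 2`); `η² = t²/(t² + df)`. Nonword drifts are multiplied by
−1 before the drift ANOVA so that "better performance" has one sign in
both conditions. Vocabulary–drift association uses Pearson r and the
first-order partial correlation controlling the binary group indicator.

## Synthetic cohorts

Group profiles default to the empirical group-level parameter means and
SDs of the modeled aging study (younger adults: word drift 1.472, boundary
2.106, t0 0.345 s, word/nonword starts 0.724/0.359; older adults: 2.033,
2.679, 0.399 s, 0.771/0.305; with the corresponding variability means) and
vocabulary scores 72.06 ± 12.23 (younger) vs. 85.37 ± 13.41 (older).
Parameters are drawn independently normal per participant (no covariance
information is available) and redrawn until jointly valid; the only induced
coupling is vocabulary ↔ word drift at correlation 0.5, implemented through
a shared standard-normal component. Trials come from the simulator over a
full randomized schedule; 2% of trials (default) are contaminants with
uniform RT *inside* the trimming window and coin-flip responses, so
trimming alone cannot remove them — they exercise the fit diagnostics
rather than the trimming. Stroke logs are synthesized so that pen-down
minus previous pen-up reproduces each trial's RT to representation
precision; recovery experiments set contamination and between-person SDs
to zero.

What the generator does *not* emulate: item-level word-frequency effects on
drift, sequential (trial-to-trial) dependencies, missing responses, real
German lexical material, and any demographic structure beyond the group
label and vocabulary mean/SD. Passing recovery and calibration tests
therefore validates the estimation machinery under the model's own
assumptions, not the model's adequacy for any particular real dataset.

## Numerical and design choices

* Time unit is seconds internally; milliseconds appear only in report
  formatting.
* Trimming keeps RTs in the closed window [0.250 s, 3.500 s]; references
  pass through untouched and are excluded from elimination fractions.
* RT definition from strokes: `rt(i) = pen_down(i) − pen_up(i−1)`; a
  missing stroke invalidates the following item's RT (no chaining across
  gaps). Pen-up before pen-down is a data error naming the slot.
* Practice sessions are flagged but *included* by default: the schedule
  arithmetic of the modeled design (2010 analyzable items across all 67
  sessions, matching the observed per-condition trial counts) is only
  consistent with their inclusion; a configuration switch excludes them.
* The experiment's stimulus pool uses placeholder pronounceable
  consonant–vowel strings; frequency classes ("low" 46.7%, "very low") are
  labels only.
* Per-stage pipeline seeds derive from the master seed via
  `SeedSequence(master, spawn_key=(stage_index,))`; a fixed seed reproduces
  every artifact byte for byte.
* Scaled problem sizes in the test suite (e.g. 8-participant bootstrap
  self-consistency at 300 trials/condition without variabilities, 3-seed
  qualitative cohort checks at 800 trials/condition) are the package's
  chosen validation sizes; the acceptance script runs the full recovery
  protocol (10 participants × 2010 trials, both groups).

## Known limitations

* KS-based estimation identifies across-trial variabilities weakly;
  their estimates should be interpreted as regularizers for the main
  parameters rather than as substantive quantities.
* The mixed ANOVA is exact for the balanced two-condition design it
  targets; it is not a general repeated-measures engine (no sphericity
  machinery is needed with two within levels).
* The bootstrap calibration inherits the cost of refitting (`n_sims`
  full fits); published-scale runs (1000 simulations) are hours of CPU,
  which is why the configuration exposes `n_sims`.
* The calibrated critical value depends on how converged the refits are:
  a thoroughly converged KS-p-maximizing search absorbs ~0.01–0.02 of KS
  distance into the nine free parameters at ~1000 trials per condition,
  concentrating the self-simulated model p-values high (bulk > 0.7) and
  placing the calibrated alpha-quantile far above where a lightly
  converged optimizer would put it. Critical values are therefore only
  comparable within one optimizer configuration; the flag *rate* at the
  nominal level is the invariant quantity.
* Euler simulation error is O(dt) after the boundary corrections but not
  zero; applications needing exact samples should lower `dt` (cost scales
  as 1/dt).
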