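# Methods

This note documents the modeling and numerical choices behind the package:
what is computed, under which conventions, and what the synthetic validation
does and does not establish.

## Task environments

**dynaPRL.** Two levers (`A1`, `A2`); three block types defined by their
reward-probability contrast — HC 0.80/0.10, LC 0.60/0.30, NC 0.45/0.45.
Blocks are scheduled to last 15–30 trials (uniform); at a transition, NC
never repeats, and the better side flips between consecutive contrast
blocks. Block types are otherwise drawn uniformly from the menu. Two
readings of the consecutive-error rule are implemented: by default a due
transition is *deferred* while the last four choices in a contrast block are
all incorrect (so contingencies are never switched mid-failure);
`defer_mode="hasten"` instead forces an early switch on such a streak. The
deferral couples switch timing to recent choices, which measurably raises
p(correct) on the trial just before a transition — a task property worth
remembering when interpreting perseveration curves.

After the 12th trial of an HC/LC block, 40% of rewarded trials deliver a
halved (16 µL) or doubled (66 µL) volume instead of the standard ~33 µL,
with equal odds. The manipulation affects volume metadata only: every model
consumes the binary outcome, so magnitude never enters value updates.

**PRL (training stage).** Fixed 0.70/0.10 contrast. A reversal becomes
eligible when an exponential moving average of correctness exceeds 0.75; the
EMA uses smoothing constant `2/(8+1)`, the standard n-period convention for
"an EMA of the previous 8 trials". Once eligible, a reversal occurs with
probability 0.10 per trial and is forced after 20 eligible trials without
one. The EMA and eligibility counter reset at each reversal.

Trials on which no response occurs are marked invalid and excluded from
every computation; response timing itself is not simulated.

## Models and conventions

All four models initialize both action values at 0 at the start of each
session, carry values across block transitions within a session, and reset
between sessions (fitting is per session, so session-level reset is the
consistent choice). Latent states (`avgRPE`, `Rtrace`) start at 0. In the
GRS model the trace updates from the *previous* trial's outcome, so the
first trial of a session uses the initial trace unchanged.

Choice probabilities come from a two-action softmax on `β·ΔV`. Numerical
guards: β is bounded at 20 (likelihoods flatten well before that; an
unbounded β destabilizes MLE on near-deterministic sessions), and
probabilities are floored at 1e−9 inside the log.

Two documented quirks are implemented literally:

* the avgRPE value update adds `avgRPE_t` directly (no separate step size),
  so α plays a dual role as RPE scaling inside the average;
* the avgRPE model reduces to standard RL at `hW = 0` (algebraically
  immediate from the update), and `hW` is bounded at 0.75.

The "unsigned avgRPE" used everywhere downstream is `|avgRPE_t|` from the
avgRPE model; the "GRS" is the reward trace itself (not `wR·Rtrace`; the
scaled version is available from the same trace if wanted). Decay rates of
the five-parameter model are reported as `1 − γ` while the update multiplies
by `γ`.

## Fitting

Per-session MLE with 10 restarts: initial points drawn uniformly inside the
parameter bounds, L-BFGS-B as the bounded optimizer with a bounded Powell
fallback on failure, best restart by nLL. Deterministic given the seed.
Sessions need ≥ 20 valid trials. BIC uses the natural log. Model comparison
reports per-session BIC, per-subject/overall mean and summed BIC, and
session winner counts; ties break toward fewer parameters. The winner call
uses mean BIC.

## Hierarchical two-group model

For the five-parameter model, each subject's parameters are modeled on an
unconstrained scale: subject j in group g has
`u_{j,p} ~ Normal(μ_p + s_g·δ_p/2, σ_p)`, with `s_g = +1` for group A and
−1 for group B, mapped to bounds by a logistic (β by a logistic scaled to
(0, 20]). Priors: `μ ~ N(0,1)`, `δ ~ N(0,0.5)`, `σ ~ half-N(0.5)`, one
triple per parameter. This is one reasonable parameterization among several
(how δ enters and whether σ is shared are genuinely open choices); it makes
`δ_p` directly interpretable as the group difference on the transformed
scale.

The posterior is sampled by a compiled Metropolis-within-Gibbs scheme chosen
for this model's structure: the conditional posterior of `(μ_p, δ_p)` given
the subject effects is exactly bivariate normal (Gibbs draw); `σ_p` gets a
univariate slice update on the log scale; each subject-level parameter gets
a random-walk Metropolis update whose step size adapts during warm-up only.
Default: 2 independent chains × 1,000 kept sweeps after 500 warm-up
(~2 s per fit for 12 subjects × 360 trials). Agreement between chains is
summarized by split R-hat per hyperparameter; a fit with any R-hat above
1.05 is flagged, not rejected. An off-the-shelf ensemble sampler was tried
first and mixed far too slowly at this dimensionality (R-hat ~3 after 1,600
steps); the blocked scheme exploits the conjugate structure instead.

The directed Bayes Factor is the ratio of posterior draws of `δ_p` above
zero to draws below zero, capped at the number of draws when one side is
empty; `dBF > 1` means group A higher. Because the bound mapping is
monotone, the sign of δ on the unconstrained scale is the sign of the group
difference on the natural scale.

## Behavioral metrics

A win-stay is a rewarded trial whose next valid same-session trial repeats
the choice; a lose-shift is an unrewarded trial whose next choice differs.
Probabilities are micro-averaged: counts pooled across sessions first, then
divided. Stay/shift pairs may span block transitions (the outcome trial
determines the stratum) but never sessions. Strata come from the outcome
trial: phase (early = block trials 1–6, late = 7+), block type, and action
class (better/worse by reward probability; NC trials carry `none` and are
excluded from better/worse splits). Zero-denominator cells are reported as
missing with their counts. Action-difference scores are better-minus-worse
probabilities within the remaining strata.

The perseveration curve is the probability, per offset around a block
transition (5 pre, 12 post), of choosing the *outgoing* block's better
lever; for outgoing NC blocks a reference lever is drawn at random from the
module's RNG. Offsets outside the two flanking blocks are skipped.

## Latent-state analyses

All "correlations" with binary stay/shift outcomes are binomial logistic
regressions on the z-scored predictor (z-scored across the analyzed trials
of the stratum); the coefficient (log-odds slope) is the reported effect.
Degenerate cells — constant predictor, all-stay or all-shift — are reported
missing, and classes with fewer than 30 events are flagged and skipped.

* **k-sweep**: `wRPE_t = k·RPE_t + (1−k)·RPE_{t−1}` with RPEs from the
  standard-RL fit and `rpe_prev = 0` on a session's first trial (no previous
  trial exists; zero is the neutral element). Grid: k from 0.5 to 1.0 in
  steps of 0.025 (21 points), WS and LS separately; the reported k maximizes
  |coefficient|.
* **Latent-choice regressions**: WS (stay among wins) or LS (shift among
  losses) on `|avgRPE|` (avgRPE-model fit) or the reward trace (GRS-model
  fit), restricted by default to better actions in the late phase, per block
  type.
* **Median split**: better-action late-phase win trials, per block type;
  medians of GRS and `|avgRPE|` computed within the analyzed set; ties
  assigned to "low" deterministically; p(WS) per 2×2 cell, cells under 10
  trials flagged.

## Synthetic cohorts

`CohortSpec` draws each subject's generative parameters from group-level
normals (clipped just inside bounds) with optional between-group deltas
applied ±δ/2, then simulates dynaPRL sessions and marks a small fraction of
trials invalid (default 0.5%, matching an omission rate of well under 1%).
Defaults emulate the study design scale — 9 + 5 subjects — with group SDs of
0.04–0.05 for learning rates, 0.03 for retention factors, 0.5 for β:
moderate, realistic individual differences that keep ≥ 99% of draws inside
bounds. Scripts and tests scale session counts down for speed.

What the generator deliberately does not emulate: response-time structure,
within-session nonstationarity (satiety, attention), magnitude-sensitive
valuation, and any perseveration kernel beyond what the four models produce.
Passing recovery tests therefore shows the estimators work *when the model
family is the generator*; they say nothing about misspecification on real
animals.

## Validation studies and their problem sizes

* Nesting: one 300-trial session; avgRPE(hW=0), GRS(wR=0) and
  asym5(α⁺=α⁻, γ⁺=γ⁻=1) reproduce the standard-RL nLL to < 1e−10.
* Counting oracles: 1,000 random ≤ 20-trial mini-sessions against literal
  enumeration (WS/LS strata and median-split cells), exact.
* Hand traces: 3–10-trial fixtures against step-by-step recursions, 1e−12.
* Parameter recovery: 100 sessions × 400 trials, α ~ U(0.1, 0.6),
  β ~ U(1, 8); measured r ≈ 0.94 for both.
* Model recovery: 25 subjects per generator × 2 sessions × 400 trials.
  Standard and avgRPE rows recover 25/25; asym5 is diagonally dominant
  (15/25). The GRS row is **not** recovered (6/25): with a moderate trace
  weight (wR = −0.5) the reward trace shifts both actions' values largely in
  common, and its likelihood advantage (~8 nats per 1,000 trials) stays
  below the session-level BIC penalty for its two extra parameters at any
  realistic session length. This is an identifiability property of the
  model class at session-level BIC, reported as such rather than hidden by
  inflating the generative effect.
* k recovery: 10,000 trials, true k = 0.8 recovered within one grid step.
* dBF: 20 null and 20 effect (Δα⁺ = 0.15) cohorts of 6 + 6 subjects × 360
  trials. Directional recovery exceeds 80%. Null calibration lands at
  ~50–65% of replications inside [1/3, 3]: for a *calibrated* posterior the
  band corresponds to |z| < 0.675, which holds only ~50% of the time under
  honest cohort resampling, so rates well above that require deliberately
  over-dispersed posteriors. The stated priors are kept and the measured
  rate is reported as is.

## Known limitations

* The GRS model's reward-trace weight is weakly identified from single-
  session choices (above); group-level or pooled-session fitting would be
  the remedy but is out of scope for the session-level design.
* Walker-free MCMC diagnostics: split R-hat across 2 chains is a coarse
  check; occasional flagged fits (R-hat ≈ 1.05–1.3) occur at desk scale and
  are surfaced via `converged=False`.
* The perseveration curve inherits selection bias near transitions from the
  deferral rule whenever that rule is active.
* `p(WS)`/`p(LS)` micro-averaging weights sessions by event counts; per-
  session macro-averages would differ on unbalanced data.
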