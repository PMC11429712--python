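# Methods

## The model

A decision policy π(a|s) mapping stimuli to actions is treated as a
communication channel. Its **policy complexity** is the mutual information

    I(S;A) = Σ_s Σ_a P(s) π(a|s) log[π(a|s) / P(a)],

the average of the per-trial **policy cost** log π(a|s)/P(a), where
P(a) = Σ_s P(s) π(a|s) is the marginal action distribution. An agent with a
capacity limit C can only realize policies with I(S;A) ≤ C, and the maximum
expected reward achievable at each complexity defines the
**reward–complexity frontier**. The policy achieving the frontier at
inverse temperature β has the form

    π(a|s) ∝ P(a) · exp[β Q(s,a)],

with Q(s,a) the average reward for action a in state s; β indexes the
trade-off between reward maximization (large β) and compression (small β).
The frontier is computed by the Blahut–Arimoto alternating minimization:
update π(a|s) ∝ P(a) exp[β Q(s,a)] row-wise, then P(a) = Σ_s P(s) π(a|s),
until the marginal stops moving.

Learning can implement this trade-off through a cost-penalized reward
prediction error

    δ = r − V(s) − (1/β) · log[π(a|s)/P(a)],

used to update both state values (delta rule) and policy preferences
(softmax actor step). With β = 1 the penalty enters unweighted,
δ = r − V − log π(a|s)/P(a). We carry the explicit 1/β weight so that the
learner's fixed point is exactly the capacity-limited optimal policy at the
same β as the Blahut–Arimoto solution; the unweighted form is the β = 1
special case. The hypothesis linking this to neural data is that
outcome-locked dopamine responses encode δ, so policy cost should
*suppress* the response over and above outcome and value.

## Units

Per-trial costs are in **nats** (they enter the learning rule under a
natural log); complexities are reported in **bits**. The ln 2 conversion is
applied once, at the reporting boundary, and the equality
mean(cost)/ln 2 = I(S;A) is exact for the plug-in policy at pseudocount 0.

## The task and the synthetic generator

The generator emulates a head-fixed 2AFC contrast-discrimination task:

- **9 stimulus states**: signed contrasts {0, ±6.25, ±12.5, ±25, ±50} %
  (stored as fractions), negative = left. The levels are a design choice —
  symmetric, configurable — and uniform P(s) = 1/9 by default.
- **Blockwise 2:1 reward asymmetry**: in "left-large" blocks a correct left
  response pays 2 units of water and a correct right response 1 unit, and
  vice versa; blocks alternate every 100 trials starting from a seeded
  random type. Block length is a design choice (the task's block statistics
  are not constrained by the analysis).
- **Zero-contrast trials**: the rewarded side is drawn uniformly per trial,
  the standard convention for ambiguous stimuli.
- **Choices** come from the capacity-limited policy at the task's long-run
  value table Q (programmed rewards averaged over the two equiprobable block
  types), with session-specific β and bias. Conditioning choices on the
  current block would give the generated agent information beyond the
  stimulus, lifting its (complexity, reward) point above the stimulus-only
  frontier; averaging keeps generated sessions exactly on the frontier
  family the analysis assumes, while delivered reward magnitudes still
  follow the 2:1 blocks.
- **Session bias** is the marginal P(a) plugged into the policy. Note the
  *realized* choice asymmetry is weaker than the plugged-in value (the
  conditional rows pull back toward the stimulus), so a generative bias of
  0.7 yields an empirical P(right) near 0.58.
- **Outcome responses** are generated as
  response = g·(r − V(s)) − cost + ε, ε ~ N(0, σ²), σ = 0.5 by default,
  with V(s) and cost evaluated under the session's generating policy. The
  gain g equals the session's β by default (`gain_by_beta=True`): models in
  which a single inverse temperature sets both the reward–compression
  trade-off and the reward sensitivity of the prediction error predict
  exactly this scaling, and it is what makes the per-session outcome
  coefficient correlate with behavioral β. With g = 1 the response is
  literally δ = r − V − cost. Responses can be embedded as a boxcar over
  [300, 800) ms of a flat trace to exercise the windowing step end to end.
- **Default dataset**: 55 sessions × 400 trials, β ~ U[0.5, 5],
  bias ~ U[0.3, 0.7]. The session count matches the scale of the kind of
  photometry dataset the analysis is designed for; trial counts and
  parameter ranges are chosen to give psychometric curves spanning
  near-chance to near-deterministic regimes. All randomness flows from one
  seed through spawned per-session seeds.

What the generator does **not** emulate: sensory noise or lapses, wheel
kinematics and reaction times, within-session learning or drift, slow
calcium dynamics and bleaching, across-trial autocorrelation in the
photometry noise. Passing tests therefore show the estimators and model
comparisons are correct *under the generative assumptions*, not that real
data satisfy those assumptions.

## Estimation choices

- **Plug-in policy**: per-session (state, action) counts with additive
  pseudocount α = 1 (default) to avoid log 0 in the cost regressor;
  sessions have hundreds of trials so the bias is small, but it is visible:
  shrinking π toward uniform *underestimates* complexity slightly, which
  can place estimated session points marginally above the frontier
  (negative deviations of ~1–2% at 400 trials). No bias-corrected MI
  estimators are used, matching plug-in session-level estimation.
- **Blahut–Arimoto**: tolerance 1e-10 on the max-norm marginal change,
  max 10,000 iterations, uniform marginal start. The β = 0 endpoint is
  analytic (best unconditional action) because at β = 0 every marginal is a
  fixed point of the iteration. Default grid: 100 log-spaced β in
  [0.01, 100]. The frontier is clipped to be monotone against ~1e-12
  numerical wobble.
- **Frontier deviation** is the vertical gap: 100·(R_opt(I) − R)/R_opt(I)
  with R_opt linearly interpolated at the session's complexity (clamped to
  the frontier's range). Negative values (points above the curve) are
  reported as-is. Horizontal or Euclidean distances would be defensible
  alternatives; the vertical gap reads directly as "percent of achievable
  reward foregone".
- **Policy fit**: only β is free, maximized on [0, 50]; the bias is plugged
  in from the session's empirical P(a) (clipped to [1e-3, 1−1e-3] for
  degenerate sessions), not jointly optimized. The likelihood is evaluated
  on count tables; a 61-point log-spaced scan brackets the optimum before
  bounded scalar refinement, which is what makes the fit deterministic and
  robust to the flat likelihood at β ≈ 0. BIC counts k = 2 parameters with
  bias (β plus the plug-in marginal) and k = 1 without; ΔBIC is summed over
  per-session fits by default, with a pooled variant available.
- **Value smoothing**: a triangular kernel (w, 1−2w, w) over
  contrast-adjacent states, w = 0.25 by default, edge states renormalized
  over their available neighbors; this encodes a small amount of state
  (contrast) uncertainty. Q defaults to the empirical session mean reward
  per (s,a), with unvisited cells filled from the programmed task rewards.
- **Neural regression**: responses are the [300, 800) ms window mean minus
  the [−100, 100) ms baseline mean (half-open sample windows), z-scored
  within session (sd with ddof = 1), then pooled into a single OLS on
  (intercept, cost, value, outcome) — no random effects. The value
  regressor is Q(s, a_chosen) from the smoothed empirical table; the cost
  regressor uses the α = 1 plug-in policy. BIC uses the profiled-variance
  Gaussian form n·ln(RSS/n) + k·ln n, so only differences are meaningful.
  The β–outcome association is a Pearson correlation with a two-sided
  t-distributed p-value. Two-sided p-values throughout, no multiple-testing
  correction (three planned regressors).

## The learner's numerics

Actor-critic defaults: α_v = 0.1, α_θ = 0.1, α_marginal = 0.01, θ and V
initialized at 0, marginal at uniform. Learning rates follow a harmonic
(Robbins–Monro) decay α(t) = α·τ/(τ+t) with τ = 2000: at small β the
optimal marginal is only weakly determined (the objective is nearly flat in
P(a)), and with constant rates the marginal tracker executes a slowly
mixing random walk along that flat direction instead of settling; decay
restores almost-sure convergence while τ = 2000 leaves the early trials
fast enough to reach the fixed-point neighborhood well within a 50,000-trial
run. `decay_tau=None` restores constant rates. The terminal policy is
π(a|s) averaged over the last 5,000 trials to smooth residual
stochastic-approximation noise. The fixed point, not the trajectory, is the
scientifically meaningful object; trajectories depend on these unmodeled
choices.

Degenerate inputs: all-one-action sessions clip the bias and warn;
never-visited states get uniform policy rows (silently under smoothing,
with a warning at α = 0); zero-variance sessions are an error in z-scoring;
rank-deficient design matrices are an error naming the collinear columns;
Blahut–Arimoto non-convergence raises carrying the last iterate. Argmax
ties resolve to the lowest-index action.

## Problem sizes

Tests and the acceptance script use the generator's default study scale
(55 sessions × 400 trials for dataset-level claims; 10–50k trials where a
single long session or learner run is the right unit; 20 seeds for the
replication-rate check), sizes at which Monte-Carlo error is well inside
every asserted tolerance.

## Known limitations

- ΔBIC for the bias model on the *default* synthetic dataset is typically
  negative: biases drawn symmetrically from U[0.3, 0.7] produce realized
  choice asymmetries too weak to beat the extra-parameter penalty in 400
  trials. Datasets generated with frank biases (0.6–0.9) robustly favor the
  bias model. Both regimes are tested.
- The plug-in cost regressor is estimated from the same trials it is
  regressed on; at 400 trials/session this is noisy but unbiased enough for
  sign and model-comparison conclusions, which is all the pipeline claims.
- Per-session β̂ is consistent under the generative model but its scale
  depends on the Q table used in the fit; rank-order comparisons across
  sessions are the robust quantity.
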