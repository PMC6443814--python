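# Methods

This note documents the models implemented in `dynforage`, the synthetic
data they are exercised on, the numerical choices that matter, and the
limits of what the test suite shows.

## The baiting environment

`schedule` simulates the concurrent variable-interval task.  Each trial,
every *empty* target is independently baited with its programmed
probability (drawn at the start of the trial, before the choice, so
reward probability grows with time since the target was last chosen); a
bait persists until the target is chosen.  Per-block rates sum to
`total_bait_rate = 0.35` rewards/trial and the rich:lean ratio is drawn
uniformly from {8:1, 6:1, 3:1, 1:1}, with the rich side assigned to green
or red by a fair coin.  Block lengths are uniform on 100–200 trials (a
distribution is not dictated by the task description; uniform is the
simplest choice).

**Changeover delay (COD).**  A reward is never delivered on the first
choice of a switch; the bait persists and pays on the second consecutive
choice of the new color.  Trained subjects comply with the COD almost
always, so the simulator's agents repeat the new color once after every
switch (`repeat_switch`, on by default when the COD is enabled), and the
switch pair is collapsed into a single *free choice* — imposed second
choices are excluded from every likelihood and statistic.  Without the
repeat, single-trial excursions are never rewarded and the unchosen
income cannot recover, which distorts the closed-loop dynamics.

**Harvesting efficiency.**  Defined as rewards obtained divided by the
maximum number collectable.  The maximum is computed from the same
per-trial uniforms as the session itself, as the bait count of an oracle
whose targets are always empty (every `u < p` event is a bait it would
have collected).  Actual assignments are a subset of the oracle's — an
occupied target cannot be re-baited — so efficiency is bounded by 1.
Note that the naive alternative (baits actually assigned) is degenerate:
baits persist until collected, so every agent's rewards/assigned ratio is
~1 regardless of policy.  Even an omniscient harvester reaches only ~0.9
of the oracle, because simultaneous baits can be cleared only one per
trial.  For ingested external data without bait bookkeeping the
denominator falls back to `total_bait_rate × n_trials`, the oracle
count's expectation.

## The multi-timescale choice model

Incomes are leaky integrators of the per-target reward stream,
`I ← (1 − 1/τ) I + (1/τ) r`, applied to **both** targets every trial
(`r = 1` only for a rewarded choice of that target).  The per-target
incomes are combined with simplex weights and choices follow the
fractional-income (local matching) rule `P_G = I_G / (I_G + I_R)`, with
`P = 0.5` declared when both incomes are zero.

**Exploration floor (`lapse`, default 0.01).**  The pure fractional rule
has absorbing boundaries: if one target's income decays to ~0 while the
other keeps being rewarded, the losing target is never sampled again and
its income can never recover; in closed loop a purely fast agent fixates
on one color within ~10² trials.  Real subjects have an irreducible lapse
rate, and the simulated choice probability is therefore clipped to
`[lapse, 1 − lapse]`.  With the floor a `w_slow = 0` agent's block-wise
matching slope is 0.95–0.98 (the ~0.03 shortfall from 1 is the lapse's
own compression plus regression attenuation from noisy block reward
fractions); the slow-limit behavior is untouched.  The lapse plays no
role in likelihood computations, which clip probabilities at 1e−6 purely
to avoid infinite log-likelihoods.

Initial incomes default to `total_bait_rate / 2 = 0.175` per target and
timescale: an unbiased start at the schedule's mean payoff.

The **random-bias** alternative model replaces slow integration by
additive per-session color biases, `P_G = (I_G + B_G)/(I_G + I_R + B_G +
B_R)` with fast-only incomes.  It exists to demonstrate a
non-identifiability: any slowly drifting bias, reward-driven or not,
reproduces the session-level correlation between fitted slow weight and
undermatching (verified in the confound study: biases drawn uniformly on
[0, 0.15] per session yield r ≈ 0.5–0.7 with block-permutation p < 10⁻³).

## Behavioral statistics

* **Matching regression** — OLS of block-wise green choice fraction
  (free choices) on green reward fraction; slope S, undermatching 1 − S,
  color choice bias = fitted value at reward fraction 0.5, minus 0.5.
  Blocks with fewer than 5 rewards are excluded by default (they put
  extreme, noisy fractions at high leverage); block fractions can be
  restricted to the last 50 trials of each block to skip transients.
  With ≲10 blocks per session the reward-fraction measurement error
  attenuates per-session slopes by roughly 0.1–0.25; session-wise
  undermatching estimates are therefore biased upward by a roughly
  constant amount, which cancels in the correlation analyses.
* **Variance of choice** — the free-choice series (green = 1) is smoothed
  by two causal half-Gaussian kernels (σ = 8 and σ = 50 trials, truncated
  at a 200-trial span and renormalized; the truncation and normalization
  are implementation choices) and the variance is the mean squared
  fast–slow difference over trials with a full span of history.
* **Color reward imbalance** — (R_G − R_R)/N over a session or pooled
  window, N counting all trials.

## Bias–variance decomposition

The estimation task is a single-target "coin": a Bernoulli reward
probability, constant within blocks of L trials, cycling
deterministically through the task's per-trial baiting levels (both rich
and lean values of each ratio, so the long-run mean is 0.175).  For the
mixed estimator `(1 − w) I_fast + w I_slow` the first and second moments
of both filters and their cross-covariance obey exact linear recursions
(variance: `v ← (1−a)² v + a² p(1−p)`; cross-covariance with rates a_f,
a_s: `c ← (1−a_f)(1−a_s) c + a_f a_s p(1−p)`), so squared bias, variance
and MSE are computed deterministically, time-averaged over one full cycle
after a 10-block burn-in.  The filter moments are weight-independent and
are combined bilinearly across the weight grid (default 51 points).  A
vectorized Monte Carlo estimator over replicate reward streams is the
independent cross-check (agreement within 3 SE over randomized tasks is a
property test).

At w ≈ 0 the curve's squared bias is not exactly monotone: the fast
filter's own post-change transient bias interacts with the slow bias and
produces a dip of order 1e−7, five orders below the curve scale.
Monotonicity assertions therefore use a 1e−6 numerical tolerance.

On the full behavioral task (simulated sweep, matched randomness across
weights) the same tradeoff appears as declining matching slope, declining
choice variance, and an inverted-U of harvesting efficiency in
`w_slow`.  The efficiency–undermatching *correlation* across sessions has
no fixed sign: it is positive only for agents left of the inverted-U
optimum (fast, high-variance learners).  In this simulator the optimum
sits at small `w_slow` (~0.1), so session-wise drift datasets show the
negative (right-of-optimum) sign; subjects showing the positive sign are
operating below their optimal slow weight.

## Model fitting

`MultiTimescaleModel` fixes the time constants (default 2, 20, 1000
trials) and estimates the simplex weights by maximum likelihood on the
free choices.  The per-timescale income trajectories depend only on the
data, so they are precomputed once; each likelihood evaluation is a
weighted combination.  The 3-simplex is parametrized by a 2-dimensional
softmax chart and optimized by Nelder–Mead from 5 starting points
(uniform weights plus random draws, tolerance 1e−8); solutions with a
weight above 1 − 1e−4 are flagged as boundary fits.  Standard errors come
from the numerical Hessian in the chart, delta-transformed through the
softmax Jacobian (NaN at boundary solutions).  Sessions are fitted
independently except that the slow integrator's final incomes seed the
next session's initial slow incomes; fast integrators restart at 0.175.

Parameter recovery on the reference conditions (20 independent
~5000-trial sessions, `w_slow = 0.4`): median absolute error of the
recovered slow weight ≈ 0.01–0.04, comfortably inside the 0.15 band the
acceptance suite asserts; recovery degrades gracefully at 500-trial
sessions.

## LMIT

Per-session color choice bias and color reward imbalance series are
correlated at session lags 0…−5 within a sliding 25-session window; a
weighted least-squares line with weights γ^lag (γ = 0.5 — small lags are
the more reliable) is fitted to the lagged correlations and its zero
crossing, times the window's mean session length (all trials), is the
LMIT in trials.  Negative crossings clamp to 0; a non-negative fitted
slope has no finite crossing and is capped at the maximum lag and flagged
(with a non-positive intercept the line never exceeds zero and the LMIT
is 0).  Sliding windows advance one session; the first 25 sessions of a
dataset are excluded by default (training transients in chronic data; the
synthetic calibration uses a 5-session burn-in instead, which is all a
stationary simulated agent needs).

Single-window LMIT estimates are noisy (six correlations, each from 25
points), so the weight calibration averages lagged-correlation profiles
over sliding windows and over 50 replicate datasets per weight before
fitting the line, and summarizes per-dataset estimates by a rank
correlation with the generating weight.  Calibration conditions: 60
sessions of ~500 trials (5 blocks of 90–110), τ_fast = 5,
τ_slow = 400 trials (≈0.8 sessions — about the τ/session-length ratio of
the chronic experiments, scaled down), slow income carried across
sessions.  Under these conditions the LMIT rises from ≈1500 to ≈1900
trials as `w_slow` goes 0.1 → 0.7.  The LMIT is a lower bound on the
slowest integration timescale, not an estimate of τ itself.

**Block permutation test.**  Correlations between session-level series
are tested by shuffling blocks of five consecutive sessions while
preserving within-block order, two-sided, with the add-one p-value
estimator.  The test is exact when dependence is confined to the blocks
(exchangeable blocks; type-I error 0.05 within Monte-Carlo error over
1000 replicates) and approximate — mildly anti-conservative, ~0.07 at
ρ = 0.6 — for dependence that crosses block boundaries.

## Cascade network

Two plastic pathways carry populations of bounded binary-strength
synapses with m = 8 ordered plasticity levels.  Rates fall geometrically
with depth: plasticity α_i = x^i with x = 0.35, and consolidation
q_i = 0.15·x^(i−1).  On the chosen pathway, reward potentiates depressed
synapses into the most plastic potentiated state (probability α_i) and
deepens potentiated ones (q_i); no reward is the mirror image.  Choice is
a logistic readout of the difference in potentiated fraction between
pathways with temperature 0.02.  Breaks between days apply
strength-flipping transitions to the most plastic level at rate
`forgetting_rate × α_i` per break unit.  The default engine propagates
occupancy fractions, which is the exact expectation of the per-synapse
chain; a stochastic engine is provided for cross-checking.

The defaults were set so the mechanism is expressed at desk scale:
day 1 starts from occupancies uniform over all 2m states, and because the
consolidation flux (q_scale = 0.15 > x^i ladder) makes the learning
equilibrium deeper than uniform, practice slowly consolidates the
network — the effective learning rate falls from ≈0.034 to ≈0.006 per
outcome over 40 days, undermatching grows from ≈0.26 to ≈0.46 (the
empirically observed 0.1–0.4 range), and undermatching and the variance
of choice are negatively correlated across sessions.  With a shallow
ladder (m = 3) or with q_i = x^i the uniform state is already at
equilibrium and no consolidation trend exists.  Forgetting restores
plasticity after breaks, which is the mechanism behind the
schedule-covariate predictions (longer recent days → longer LMIT; longer
breaks → shorter LMIT).

## Study conditions and what the tests show

All data are synthetic; every protocol in `dynforage.experiments` is
seeded and regenerates its data at run time.  Reference problem sizes:
10⁵-trial runs (6 replicates) for the slow limit; 500 blocks × 150 trials
for the fast limit; 15-point weight grids on ~45k-trial schedules for the
efficiency sweep; 20 × 5000-trial sessions for recovery; 60 sessions for
the confound; 4 weights × 50 replicate 60-session datasets for the LMIT
calibration; 1000 replicates for the permutation calibration; 40
simulated days for the cascade.  These sizes were chosen to make each
qualitative claim resolvable against Monte-Carlo noise.

The generators emulate the structure of chronic primate datasets —
block/session/day hierarchy, COD bookkeeping, session-to-session drift or
consolidation — but not eye movements, satiety, motivational drift,
reaction times, or inhomogeneous ratio usage across experiments.  Passing
tests therefore demonstrate internal consistency of the models and
estimators under the stated conditions, not biological validity of any
parameter value.
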