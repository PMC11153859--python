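# Methods

This note documents the models, the synthetic-data generator, the sampler,
and the numerical and design choices behind `valsearch`, in enough detail
to judge what the package's passing tests do and do not establish.

## Task designs

Two seedable schedule generators encode the study structure exactly:

* **Learning task** — 3 face pairs, one per value condition (reward /
  punishment / zero outcome), 10 presentations per pair per block, 10
  blocks, 300 main trials.  The pair's two faces sit above/below fixation;
  only a binary arrangement flag matters computationally, balanced 5/5 per
  pair and block.  Orderings are drawn by rejection resampling until no
  two adjacent trials show the same pair in the same arrangement
  (including across block boundaries), capped at 10,000 attempts per block
  before erroring — in practice a handful of shuffles suffice.
* **Search task** — 4 blocks of 24 target-present (8 per condition; each
  target twice at each of 4 display positions per block, hence 8 per
  position and 32 in total over the experiment) plus 24 target-absent
  trials, ordered so the same target never occupies the same position on
  two adjacent trials.

Stimulus counterbalancing across participants is exposed as a relabelling
handle (`condition_allocation`); the printed count of 24 presentation
combinations does not factorise uniquely (6 condition allocations × 8
independent target-status flips would give 48), so both readings are
recorded as constants and a single default allocation is used — the
allocation never changes the schedule's combinatorial structure.
Optional practice blocks (30 learning / 24 search trials, `block = 0`)
are generated only on request and carry a `practice` flag that analysis
code excludes.

## Learning model

Four expected values, one per (face role × {reward, punishment}); the
chosen option's value moves toward the monetary outcome (coded −1/0/+1)
by the condition's learning rate, `EV ← EV + η(outcome − EV)`.  The
prediction error is `outcome − EV` — the standard delta rule; the
alternative sign convention (value minus outcome) makes learning diverge
and is not implemented.  Choice follows a softmax over the pair's two
values with condition-specific inverse temperature, computed through the
logistic of the signed value gap so that arbitrarily large τ cannot
overflow.  Values start at 0, the midpoint of the outcome scale.  Only the
chosen option updates; the zero condition gives no feedback, so its trials
are excluded from the likelihood (their parameters are unidentified) and
simulated choices there are uniform.

## Diffusion model

Target-present search trials are modelled as a unit-diffusion Wiener
process between absorbing boundaries 0 and α, starting at z·α with
z = 0.5 fixed (the "dissimilar"/present response maps to the upper
boundary; on target-present trials response and accuracy coding coincide).
Drift ν and boundary α are condition-specific per participant; the
non-decision time t0 is a single population-level parameter per fitted
group.  Inter-trial variability parameters (sv, st0, sz) are deliberately
omitted — α, ν, t0 are the model.  The first-passage density uses the
two classical series expansions with per-point selection by the
Navarro–Fuss term-count bounds at truncation error 1e-7; a compiled
scalar kernel evaluates the log-density directly, switching to the
leading-term asymptote when the standardised series underflows so extreme
proposals can never produce spurious +∞ log-likelihoods.  Target-absent
trials are generated (the design requires them) with a separate
absent-condition parameter pair, drift negative toward the "absent"
boundary, but are not fitted.  The likelihood offers an optional slow-RT
trim and a uniform-contaminant mixture weight; both default to off, since
the task had no response deadline and no trials were excluded.

## Synthetic cohorts

The generator mirrors the fitted hierarchy: participant parameters are
drawn on transformed scales (logit η, log τ, log α and t0, raw ν) around
group locations, with a within-condition correlation (default 0.3)
between log α and ν.  Group locations default to the published group
posterior means — young: η_r 0.05, η_p 0.12, τ_r 7.98, τ_p 4.50,
t0 0.36 s; older: 0.01, 0.02, 11.70, 3.95, 0.50 s — with diffusion
locations chosen to reproduce the reported young-minus-old contrasts
(older: larger α, lower ν).  Between-participant scales (η logit-sd 1.2,
τ log-sd 0.5, α log-sd 0.15, ν sd 0.40, t0 log-sd 0.08) are set so
individual differences are resolvable from one participant's data —
learning rates span roughly an order of magnitude — which is the regime
the cross-participant rank-correlation analysis presupposes; far tighter
scales would make individual parameters statistically indistinguishable
and the linking table meaningless.

Outcomes realise the 80/20 contingency Bernoulli per trial by default;
`exact_block_balance` instead pre-randomises an event sequence with
exactly 8 events per 10 presentations of a pair (the target pays on event
trials, the nontarget on the rest) — the original realisation scheme is
not documented, so both are provided.  RTs are simulated by
Euler–Maruyama at dt = 1e-4 s with a Brownian-bridge crossing test per
step; without the bridge correction first-passage times carry an
O(√dt) upward bias that is visible as a Kolmogorov–Smirnov distance of
~0.01 against the analytic density at 200,000 trials (with it, ~0.002).

What the generator does **not** emulate: practice-block learning,
fatigue or attentional lapses, RT contaminants, post-error slowing, and
any departure from the fitted model family.  Passing recovery tests
therefore show that the estimation machinery inverts the generative
model at realistic sample sizes — not that the model is true of real
participants.  Each participant also receives an individual t0 (8%
log-scale jitter) while the fitted model assumes a shared population t0;
this mild, realistic misspecification is kept deliberately.

## Hierarchical estimation

Priors (the original's are not published): Normal(0,1) on group
locations of all transformed scales; HalfNormal(1) on group scales;
an LKJ(2)-type density ∝ (1−ρ²) on the within-condition (log α, ν)
correlation; t0 uniform on (0, min observed RT) via a scaled logit, which
also guarantees every trial's RT exceeds t0 during sampling.  The start
point is fixed and never sampled.

The sampler is Metropolis-within-Gibbs, vectorised so all chains and all
participants advance simultaneously:

* **Participant blocks.**  The RL likelihood factorises into a reward
  part (η_r, τ_r) and a punishment part (η_p, τ_p); each is a 2-D block,
  as is each condition's (log α, ν).  Proposals use per-block covariances
  adapted from the chain history (Haario-style), a log-normal step-size
  jitter for heavy-tailed exploration, and 20% prior-independence
  proposals — participants whose likelihood is nearly flat (e.g. τ
  unidentified when η ≈ 0) accept those at rate ≈ 1, where a random walk
  would crawl.  Accept/reject is per participant, exploiting conditional
  independence given the group level.
* **Group level.**  Locations update by conjugate Gibbs; scales by a
  Metropolised independence draw from the inverse-gamma conditional
  implied by the Normal likelihood (the HalfNormal prior enters through a
  near-1 acceptance ratio); the diffusion model's (scales, correlation)
  triple by a small joint Metropolis step.
* **Interweaving.**  Centred hierarchies mix scales poorly (the funnel);
  alternating sweeps therefore add non-centred moves that hold the
  standardised individual effects fixed while rescaling (or shifting)
  the group parameters, with the likelihood re-evaluated.

Adaptation (Robbins–Monro on log step sizes, running proposal
covariances) runs during burn-in only, so the kept chain is Markovian.
`MCMCConfig.thin` (default 5) advances that many full sweeps per kept
iteration; the desk-scale default is 1,000 kept iterations after 1,000
burn-in across 4 chains, with `MCMCConfig.full_scale()` providing the
original 5,000/5,000/4 setting.  Every stored parameter gets a split
R-hat; any value above 1.05 raises a warning and flags the summary row
rather than failing silently.  Group-level values are reported on the
natural scale by transforming location draws (a population-median
interpretation, since exp/expit of the mean location is not the mean of
the transformed distribution).

## Posterior summaries and linking

Summaries report mean, KDE-argmax mode, central 95% credible interval and
R-hat per parameter.  Group contrasts difference two posteriors' draws
elementwise (truncating to the common length with a warning if they
differ).  Individual posterior modes use a Gaussian KDE with Silverman's
bandwidth on a 512-point grid spanning the draw range — deterministic and
standard; constant draws return the constant.  Spearman correlations use
average ranks for ties with the large-sample t approximation for two-sided
p-values; zero-variance inputs raise rather than returning NaN.  The 6 × 4
table flags |r| > 0.30 as a conservative effect-size criterion; p-values
are per-cell and uncorrected, so with 24 cells some flags are expected
under the null — the table is descriptive.  Learning curves support both
5-trial bins (20-point descriptive curves) and 20-trial bins (five coarse
bins), computed over each condition's own 100-trial sequence.

## Validation studies (test suite)

* Design exactness: exact schedule counts and adjacency constraints,
  scanned over 100 seeds.
* Kernel correctness: density normalisation to 1e-3 by quadrature,
  drift-free symmetry, closed-form absorption probabilities, and a
  200,000-trial simulation cross-check (KS < 0.01).
* Parameter recovery: correlations between true and posterior-mean
  individual parameters, reported as medians over replicate cohorts
  (3 cohorts of n=30 for the learning model, 5 of n=20 for the diffusion
  model) because a single cohort's recovery correlation carries sampling
  noise of order ±0.1 at these sizes.
* Linking recovery: cohorts generated with a Gaussian-copula rank-0.6
  coupling between η_r and ν(reward); after the full pipeline the coupled
  cell is checked against the 0.30 flag over 20 replicates while
  uncoupled cells must stay below it.  These replicates use a reduced
  configuration (500/500 iterations, 2 chains, thin 3) as the package's
  desk-scale default for that study — verified to give the same linking
  cells as full-scale fits, because the limiting factor is the data, not
  the sampler (see limitations).
* Calibration: small-scale simulation-based calibration (truths drawn
  from the model's own prior) checks 95% CI coverage of the group
  location and non-extreme posterior ranks; split R-hat is verified
  against an independent textbook implementation and against `arviz`.

## Known limitations

* The random-walk sampler needs thousands of sweeps where a
  gradient-based sampler would need hundreds; the `thin` default trades
  wall-time for effective sample size, and occasional cohorts with many
  near-non-learners can still show R-hat up to ~1.1 at desk scale.
* Recovery of η in the older-group regime (η ≈ 0.01) is intrinsically
  poor — near-zero learning rates are indistinguishable from zero at 100
  trials per condition; the recovery studies therefore use the
  young-group regime.
* Mode-based Spearman linking attenuates true couplings substantially:
  with individual-parameter recovery around 0.75 per model (the
  information ceiling at 100 reward learning trials and 32 target-present
  trials per condition), a true rank coupling of 0.6 reaches the
  correlation table at roughly 0.35.  A coupling that size therefore
  clears the conservative |r| > 0.30 flag only ~60–75% of the time at
  these cohort sizes — the flag is a conservative detector, not a
  calibrated estimator, and observed cross-model correlations should be
  read as lower bounds on the underlying coupling.
* Target-absent trials and contaminant processes are generated but never
  fitted; model comparison (WAIC/LOO) and alternative learning-model
  variants are out of scope.
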