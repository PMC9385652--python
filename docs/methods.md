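# Methods

This note documents the modelling choices, numerical conventions, generator
design, and known limitations of `navrl`. It states no empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Task model

The environment is a grid of rooms (default 6×6 = 36 states) with a door in
each shared wall; boundary rooms lack the corresponding doors, so rooms have
2 (corner), 3 (edge) or 4 (interior) available actions — 120 directed doors
in total on the default grid. Transitions are deterministic. Distance is
counted in room transitions and computed by BFS on the door graph (equal to
Manhattan distance on the open grid, but kept graph-based so the definition
survives any future wall structure).

Coordinates are (row, col), 0-based, row 0 at the top; "up" decreases the
row. Orientation within a room is not part of the state: the analyses
operate on room-level choices only.

The default task places three goals at rooms (1,4), (4,1), (4,4) with the
fixed start at (0,0). The literature source for the protocol does not
publish its goal coordinates; every analysis here depends only on path
lengths, so the defaults merely keep the goals off the start and apart from
one another, and all geometry is configurable. Only the current trial's
goal carries reward; the other goal rooms are ordinary rooms during that
trial. Reward magnitude defaults to 1 — any positive constant rescales Q
and trades off against θ, so 1 is canonical.

## Learning and choice

All model-free learners maintain per-goal tables Q(s, a), zero-initialized
at the start of the experiment and carried across trials and phases; the
three goal tables are independent. Choices are softmax with inverse
temperature θ, computed with a max shift so probabilities are invariant to
adding a constant to all values and numerically safe for any θ·Q.

Update conventions:

* The TD target is undiscounted and on-policy (SARSA): the bootstrap term
  is the value of the action actually taken next; it is defined as 0 when
  the next room is the goal, so goal-entering values converge to the
  reward.
* **Ordering.** The next action is drawn *before* the current step's update
  is applied (the update needs that action for its bootstrap); the
  likelihood replay therefore evaluates each choice's probability under
  exactly the Q-state at which the generative agent sampled it. Generator
  and fitter share one compiled per-step implementation, so the fitted
  model class contains the generating process exactly. The alternative
  "update-then-choose" ordering differs only when a room is revisited
  within a trial under a trace-based learner.
* Eligibility traces reset at the start of every trial. TD(λ) uses the
  accumulating rule (decay all entries by λ, add 1 to the visited pair);
  entries are bounded by 1/(1−λ). TD(1) is implemented as a non-decaying
  *replacing* trace — set to 1 on visit and held for the trial — matching
  its defining property that every visited pair receives the same update
  regardless of visitation frequency. The literal λ = 1 accumulating
  variant (which can diverge) is available behind `td1_accumulating`.
* Model-based values come from a value-iteration sweep with γ = 0.8,
  iterated until the largest absolute change is below 1e-4, with the goal
  terminal. On the deterministic grid the converged action value is
  reward·γ^d(s′); the sweep is cross-checked against this closed form over
  every (goal, room, action) in the tests. The table is precomputed once
  and frozen — it represents an already-perfect cognitive map.
* The hybrid mixes at choice time, Q = (1−ω)·Q_MF + ω·Q_MB, with TD(λ) as
  the MF component; learning updates touch Q_MF only. No rescaling is
  applied before mixing: both tables lie in [0, reward] by construction.

A note on value ranges: Q_MF provably stays within [0, reward] for TD(0)
(each update is a convex move toward a target in that range), and the tests
assert this. Under trace-based learners a traced pair can transiently
overshoot the reward bound when α is large and the trace exceeds 1 (or when
a high-valued pair receives another pair's error), so no such bound is
asserted for TD(λ)/TD(1); the optimizer's likelihood surface is kept finite
by capping non-finite replay values.

## Likelihood, fitting, comparison

`trajectory_nll` is a deterministic replay: identical inputs give
bit-identical NLL. Two engines exist — a compiled (numba) kernel used
everywhere, and a pure-Python reference built from the public `learners`
operations — and the tests assert exact agreement across all five models
and all phases.

Phase handling: Fixed-phase fits score Fixed choices only. Random-phase
fits warm-start by replaying the Fixed phase under the candidate parameter
vector without scoring it, reconciling per-phase fitting with value
carryover; `cold_start=True` instead zeroes Q at the phase boundary.
Truncated trials (a simulation step cap, never produced by the protocols at
sensible parameters) are excluded from the scored likelihood by default but
still drive updates; a flag includes their partial sequences.

Estimation is bounded L-BFGS-B from 10 uniform-random restarts within the
parameter bounds (α ∈ [0,1], θ ∈ [1,15], λ ∈ [0,1], ω ∈ [0,1]), seeded;
the best restart wins and is recorded. BIC uses the natural logarithm with
n = number of scored trials in the phase (9 or 72); `bic_n_mode="choices"`
switches n to the number of scored step choices. Winner selection breaks
BIC ties (1e-9) toward fewer parameters, then lexicographic model name.

## Synthetic cohorts

The generator runs seeded softmax agents through the exact protocols: Fixed
phase from the fixed start with the goal cycle G1-G2-G3 repeated; Random
phase from uniform non-goal starts with an independent seeded permutation
of the goals in each block of three. θ and ω may switch at the phase
boundary; α and λ are shared across phases. Trials are capped at 2000 steps
and flagged truncated if the cap is hit.

Per-agent parameters are drawn from configurable marginals (uniform or
truncated normal). The within-phase dependence between ω and θ is induced
by a Gaussian copula: a latent bivariate normal with correlation
2·sin(π·ρ_s/6) mapped through the marginal quantile functions hits a target
Spearman ρ_s; other parameters are independent.

Default cohort (50 agents, hybrid generative model): α ~ U(0.2, 0.8),
λ ~ U(0, 1), θ_fixed ~ TN(10, 2), θ_random ~ TN(8, 1) on [1, 15],
ω_fixed ~ TN(0.35, 0.25), ω_random ~ TN(0.6, 0.3) on [0, 1], target
Spearman ω–θ correlations +0.25 (Fixed) and −0.35 (Random). The regime is
chosen so the cohort emulates the qualitative structure reported for human
navigators: more map reliance and less choice consistency under random
starts, a positive ω–θ coupling when the start repeats and a negative one
when it does not, and a negative ω–ED correlation in both phases. The θ
band deliberately excludes near-random walkers: human participants found
every goal with bounded detours, whereas a softmax agent near θ = 1 walks
almost randomly (mean excessive distance around 9 on this grid), and such
agents would let θ dominate path efficiency entirely and mask the
strategy–efficiency relation the cohort is meant to exhibit.

Recovery cohort (for parameter/model recovery): θ ~ U(3, 10) and
ω ~ U(0, 1) held constant across phases, zero planted coupling,
α ~ U(0.2, 0.8). α extremes are excluded because at α ≈ 0 the model-free
table stays flat and ω is structurally unidentifiable.

What the generator does not emulate: reaction times, within-room movement,
head direction, perceptual noise beyond softmax stochasticity, fatigue or
learning-to-learn across phases. Passing tests therefore show that the
pipeline is correct and identifiable *for softmax RL navigators under the
stated protocols* — not that human data would yield any particular values.

## What the validation experiments show

Problem sizes were picked to give stable signs and correlations at
desk scale: 50 agents × 81 trials for parameter recovery, 30 agents per
generating model for model recovery (θ pinned at 8), 50 agents for the
default-cohort pattern, 100 agents per cohort for correlation propagation.

* Parameter recovery: the correlation between generative and fitted ω in
  the Random phase is required to reach 0.7, and fitted θ must preserve the
  ordering of the true θ tertiles.
* Model recovery: BIC selects the generating model for the majority of
  agents in TD(0)- and MB-generated cohorts.
* Study-level pattern: on the default cohort the hybrid model attains the
  lowest mean BIC in both phases, and generative ω_random correlates
  negatively with mean Random-phase excessive distance.
* Correlation propagation: a planted Spearman ω–θ coupling of −0.5
  (Random phase) survives fitting in sign, and the fitted correlation is
  monotone in the planted one. A *positive* planted coupling of the same
  size is attenuated to about zero: ω̂ scales the spread of the effective
  values, so θ̂ trades off against it and fitted ω̂–θ̂ correlations carry a
  negative offset of roughly 0.3 at these trial counts. The effect is far
  stronger in the 9-trial Fixed phase, where the estimation-error
  correlation (about −0.4) dominates any plausible planted value. Users
  interpreting fitted ω–θ correlations on few trials should expect this
  negative bias; it is a property of the likelihood geometry, not of the
  optimizer (recovery correlations and the dual python/numba replay rule
  out implementation error).

## Numerical and degenerate-input conventions

* Softmax: max-shifted; empty action sets are an error (every room has ≥ 2
  doors, so an empty set signals corrupted state).
* Replay NLL is finite for all in-bounds parameters except divergent
  accumulating-trace corners, which the optimizer objective maps to 1e12.
* Excessive distance requires a non-truncated, goal-terminated trial with
  optimal distance ≥ 1; truncated trials are excluded from ED tables by
  default (or kept as NaN).
* The RM-ANOVA reports the classical η² = SS_condition / SS_total for the
  one-way within-subject design alongside partial η²; F = t² holds exactly
  at two conditions. Cohen's d for paired contrasts is mean(diff)/sd(diff).
* The dependent-correlation test (two correlations sharing no variable,
  same sample) is the Fisher-z stabilized Pearson–Filon statistic;
  `method="pf"` gives the unstabilized variant. The 4×4 input matrix must
  be positive semidefinite.
* Hypothesis tests are two-sided; no multiple-comparison correction is
  applied by default.
* Every stochastic entry point takes an explicit integer seed; derived
  seeds stay below 2³¹. CLI runs log a configuration hash and all seeds to
  stderr; logging never affects numerical outputs.

## Known limitations

* The likelihood is evaluated under one fixed choice-timing convention
  (sample-then-update); data generated under the alternative convention
  would be mildly misfit by trace-based models on within-trial revisits.
* ω and θ are weakly identified from 9 Fixed-phase trials (see above);
  hierarchical pooling would help but is out of scope (per-participant MLE
  only, as in the modelled analysis).
* The model-based table assumes a perfect map from the first trial;
  map *learning* is not modelled.
* BIC's n is trials by default; rankings within a phase are unaffected by
  switching to choices except through the scale of the k·ln(n) penalty.
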