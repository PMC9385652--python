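# navrl

Reinforcement-learning models of human-style spatial navigation in room-grid
environments: task simulation, maximum-likelihood model fitting, BIC model
comparison, and individual-differences statistics.

## The scientific problem

People differ enormously in how they find their way. One framing casts a
navigator's strategy as a balance between two learning systems:

* **model-free (route following)** — repeat actions that previously led to
  the goal, valuing each room-direction pair from direct reward-prediction
  errors;
* **model-based (cognitive mapping)** — plan over an internal map of the
  environment.

`navrl` implements this framing for a wayfinding task on a 6×6 grid of
rooms. A session has a **Fixed phase** (9 trials from one start room, three
hidden goals sought in a fixed cyclic order) followed by a **Random phase**
(72 trials from uniformly random non-goal start rooms, goal order
block-randomized so each goal occurs once per block of three). State = room,
actions = {up, down, left, right} through the available doors, transitions
deterministic, reward 1 on entering the current goal's room.

## The models

Five valuation models are fitted per navigator and phase to the step-by-step
room choices. All maintain a per-goal table Q(s, a) (zero-initialized,
carried across trials and phases) and choose by softmax with inverse
temperature θ ∈ [1, 15]:

p(a | s) = exp(θ·Q(s, a)) / Σ_{a'} exp(θ·Q(s, a'))

* **TD(0)** (k = 2: α, θ) — SARSA-style update Q(s_t, a_t) += α·δ with
  δ = r_{t+1} + Q(s_{t+1}, a_{t+1}) − Q(s_t, a_t) (bootstrap 0 at the goal).
* **TD(λ)** (k = 3: α, θ, λ) — an eligibility trace e(s, a) (decayed by λ
  each step, +1 on the visited pair, reset per trial) spreads δ backward:
  Q += α·δ·e for every pair.
* **TD(1)** (k = 2: α, θ) — no forgetting: the trace is set to 1 on visit
  and held for the rest of the trial, so every visited pair gets the same
  update regardless of visitation frequency.
* **Model-based** (k = 1: θ) — values from a value-iteration sweep over the
  room graph (γ = 0.8, tolerance 1e-4) terminating at the goal; converged
  values equal γ^d with d the shortest-path distance of the landing room
  from the goal. Precomputed, identical for everyone, never updated.
* **Hybrid** (k = 4: α, θ, λ, ω) — choices use
  Q_hybrid = (1 − ω)·Q_MF + ω·Q_MB, with the TD(λ) learner as the
  model-free component. ω is the weight on cognitive mapping — the model's
  continuous measure of navigation strategy; θ measures how consistently
  the strategy is applied.

Fitting minimizes the negative log-likelihood of the observed choices
(bounded L-BFGS-B, 10 seeded random restarts); models are compared with
BIC = k·ln(n) + 2·NLL, n = trials in the fitted phase. Random-phase fits
warm-start by replaying the Fixed phase under the candidate parameters.

Because human trajectory data for this task are not publicly deposited, the
package ships a first-class synthetic cohort generator: softmax RL agents
running the exact Fixed/Random protocols through the *same* per-step code
path as the likelihood replay, with per-agent parameters drawn from
configurable marginals and a Gaussian-copula-induced ω–θ rank correlation
per phase. Known ground truth makes parameter recovery, model recovery, and
the correlation analyses fully testable.

## Worked example

```python
from navrl import (default_task, default_cohort, simulate_cohort,
                   fit_cohort, fits_to_frame, compare_models)

task = default_task()
cohort, truth = simulate_cohort(default_cohort(seed=7, n_agents=12))
fits = fits_to_frame(fit_cohort(cohort, task, n_restarts=10, seed=7))
print(compare_models(fits, "random")["summary"].round(2))
```

Output:

```
          mean_bic  sd_bic  n_wins
model
hybrid      779.46  242.49       8
mb          864.73  235.18       2
td0         849.76  240.50       0
td1         857.64  258.56       0
tdlambda    816.96  255.24       2
```

The hybrid model attains the lowest mean BIC and wins for 8 of 12 agents —
the expected result, since the generating agents are themselves hybrids with
intermediate ω. Correlating each agent's generative ω against its mean
Random-phase excessive distance, ED = (actual − optimal)/optimal path
length in rooms, gives r = −0.26 at this small n: heavier reliance on the
cognitive map goes with more efficient wayfinding.

The same pipeline is scriptable from the shell:

```bash
navrl run-all --seed 7 --agents 50 --out-dir out/
navrl simulate --seed 3 --agents 20 --out-dir sim/
navrl fit --trajectories sim/trajectories.csv --model hybrid --phase random \
          --restarts 10 --seed 1 --out fits.csv
```

All commands require explicit seeds and produce byte-identical outputs on
repeated runs.

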