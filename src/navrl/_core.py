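"""Compiled kernels for likelihood replay and generative simulation.

Both the fitter's deterministic replay (`replay_nll`) and the generative
agent (`simulate_trials`) drive the same per-step learning rule
(`_apply_update`) and the same softmax choice rule, so the model class being
fitted contains the generating process exactly.

Conventions shared by replay and simulation (SARSA ordering): at each step
the *next* action is drawn (or, in replay, its probability evaluated) from
the current effective Q, and only then is the current step's TD update
applied using that action for the bootstrap term. The final step of a
truncated trial has no successor action and performs no update.

Model kinds are encoded as integers: 0 TD0, 1 TD1, 2 TD(lambda), 3 MB,
4 hybrid. Eligibility traces reset at the start of every trial; Q_MF carries
across trials and phases.
"""
from __future__ import annotations

import numpy as np
from numba import njit

KIND_TD0 = 0
KIND_TD1 = 1
KIND_TDLAMBDA = 2
KIND_MB = 3
KIND_HYBRID = 4

N_ACTIONS = 4


@njit(cache=True, inline="always")
def _effective_q(kind, omega, q, q_mb, g, s, a):
    if kind == KIND_MB:
        return q_mb[g, s, a]
    if kind == KIND_HYBRID:
        return (1.0 - omega) * q[g, s, a] + omega * q_mb[g, s, a]
    return q[g, s, a]


@njit(cache=True)
def _choice_logp(kind, theta, omega, q, q_mb, legal, g, s, a_chosen):
    """log p(a_chosen | s) under max-shifted softmax over legal actions."""
    m = -1.0e300
    for a in range(N_ACTIONS):
        if legal[s, a]:
            x = theta * _effective_q(kind, omega, q, q_mb, g, s, a)
            if x > m:
                m = x
    z = 0.0
    num = 0.0
    for a in range(N_ACTIONS):
        if legal[s, a]:
            e = np.exp(theta * _effective_q(kind, omega, q, q_mb, g, s, a) - m)
            z += e
            if a == a_chosen:
                num = e
    return np.log(num / z)


@njit(cache=True)
def _sample_action(kind, theta, omega, q, q_mb, legal, g, s, u):
    """Draw an action from the softmax over legal actions using uniform u."""
    m = -1.0e300
    for a in range(N_ACTIONS):
        if legal[s, a]:
            x = theta * _effective_q(kind, omega, q, q_mb, g, s, a)
            if x > m:
                m = x
    z = 0.0
    for a in range(N_ACTIONS):
        if legal[s, a]:
            z += np.exp(theta * _effective_q(kind, omega, q, q_mb, g, s, a) - m)
    acc = 0.0
    last = -1
    for a in range(N_ACTIONS):
        if legal[s, a]:
            last = a
            acc += np.exp(theta * _effective_q(kind, omega, q, q_mb, g, s, a) - m) / z
            if u < acc:
                return a
    return last  # guard against roundoff


@njit(cache=True)
def _apply_update(
    kind, alpha, lam, td1_accumulating, q, trace, g, s, a, reward, boot, n_states
):
    """One TD update of Q_MF (no-op for the model-based kind)."""
    if kind == KIND_MB:
        return
    delta = reward + boot - q[g, s, a]
    if kind == KIND_TD0:
        q[g, s, a] += alpha * delta
    elif kind == KIND_TD1:
        if td1_accumulating:
            trace[s, a] += 1.0
        else:
            trace[s, a] = 1.0
        for ss in range(n_states):
            for aa in range(N_ACTIONS):
                if trace[ss, aa] != 0.0:
                    q[g, ss, aa] += alpha * delta * trace[ss, aa]
    else:  # TD(lambda) / hybrid
        for ss in range(n_states):
            for aa in range(N_ACTIONS):
                trace[ss, aa] *= lam
        trace[s, a] += 1.0
        for ss in range(n_states):
            for aa in range(N_ACTIONS):
                if trace[ss, aa] != 0.0:
                    q[g, ss, aa] += alpha * delta * trace[ss, aa]


@njit(cache=True)
def replay_nll(
    kind,
    alpha,
    theta,
    lam,
    omega,
    td1_accumulating,
    q_mb,
    legal,
    s_arr,
    a_arr,
    ns_arr,
    r_arr,
    g_arr,
    trial_first,
    terminal,
    count,
    n_goals,
    n_states,
):
    """Deterministic replay of a choice sequence; returns summed NLL.

    Arrays are flat over all steps in chronological order (Fixed phase first).
    ``trial_first`` marks trace resets; ``terminal`` marks goal-entering
    steps; ``count`` selects which choices contribute to the NLL (phase
    selection and truncated-trial exclusion). Steps with count=0 still drive
    the learning updates, which is how Random-phase fits warm-start on the
    Fixed phase.
    """
    q = np.zeros((n_goals, n_states, N_ACTIONS))
    trace = np.zeros((n_states, N_ACTIONS))
    nll = 0.0
    T = s_arr.shape[0]
    for t in range(T):
        g = g_arr[t]
        s = s_arr[t]
        a = a_arr[t]
        if trial_first[t]:
            trace[:, :] = 0.0
            if count[t]:
                nll -= _choice_logp(kind, theta, omega, q, q_mb, legal, g, s, a)
        if terminal[t]:
            _apply_update(
                kind, alpha, lam, td1_accumulating, q, trace, g, s, a, r_arr[t], 0.0, n_states
            )
        elif t + 1 < T and not trial_first[t + 1]:
            a_next = a_arr[t + 1]
            s_next = ns_arr[t]
            # probability of the next choice is evaluated before this update
            if count[t + 1]:
                nll -= _choice_logp(kind, theta, omega, q, q_mb, legal, g, s_next, a_next)
            boot = q[g, s_next, a_next]
            _apply_update(
                kind, alpha, lam, td1_accumulating, q, trace, g, s, a, r_arr[t], boot, n_states
            )
        # else: last step of a truncated trial -> no successor, no update
    return nll


@njit(cache=True)
def simulate_trials(
    kind,
    alpha,
    theta_arr,
    lam,
    omega_arr,
    td1_accumulating,
    q_mb,
    legal,
    next_state,
    goal_arr,
    start_arr,
    goal_state_arr,
    reward_magnitude,
    max_steps,
    seed,
    out_s,
    out_a,
    out_ns,
    out_r,
    out_len,
    out_trunc,
):
    """Run a full session of trials with a softmax TD/MB/hybrid agent.

    Per-trial arrays: ``goal_arr`` goal indices, ``start_arr`` start rooms,
    ``goal_state_arr`` goal room per trial, ``theta_arr``/``omega_arr``
    per-trial parameters (phase-dependent). Output arrays are
    (n_trials, max_steps); ``out_len`` holds realized lengths and
    ``out_trunc`` flags trials that hit the step cap.
    """
    np.random.seed(seed)
    n_goals, n_states, _ = q_mb.shape
    q = np.zeros((n_goals, n_states, N_ACTIONS))
    trace = np.zeros((n_states, N_ACTIONS))
    n_trials = goal_arr.shape[0]
    for i in range(n_trials):
        g = goal_arr[i]
        goal_state = goal_state_arr[i]
        theta = theta_arr[i]
        omega = omega_arr[i]
        trace[:, :] = 0.0
        s = start_arr[i]
        a = _sample_action(kind, theta, omega, q, q_mb, legal, g, s, np.random.random())
        t = 0
        truncated = True
        while t < max_steps:
            s2 = next_state[s, a]
            r = reward_magnitude if s2 == goal_state else 0.0
            out_s[i, t] = s
            out_a[i, t] = a
            out_ns[i, t] = s2
            out_r[i, t] = r
            t += 1
            if s2 == goal_state:
                _apply_update(
                    kind, alpha, lam, td1_accumulating, q, trace, g, s, a, r, 0.0, n_states
                )
                truncated = False
                break
            if t >= max_steps:
                break  # cap reached: no successor action, no update (matches replay)
            a2 = _sample_action(
                kind, theta, omega, q, q_mb, legal, g, s2, np.random.random()
            )
            boot = q[g, s2, a2]
            _apply_update(
                kind, alpha, lam, td1_accumulating, q, trace, g, s, a, r, boot, n_states
            )
            s = s2
            a = a2
        out_len[i] = t
        out_trunc[i] = 1 if truncated else 0
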