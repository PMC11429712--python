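"""Cost-penalized actor-critic reinforcement learning.

The agent's prediction error carries a policy-complexity penalty,

    delta = r - V(s) - (1/beta) * log[pi(a|s) / P(a)],

so that learning is driven away from high-complexity policies.  With the
trade-off weight beta set to 1 the error is literally r - V - log P(a|s)/P(a).
The policy is parameterized as pi(a|s) ∝ exp[theta(s,a) + log P_hat(a)] with
a running estimate of the marginal action distribution; values are learned by
a delta rule and preferences by the standard softmax likelihood-gradient
(actor) step.  Its fixed point is the capacity-limited optimal policy
P(a|s) ∝ P(a) exp[beta Q(s,a)], i.e. the Blahut-Arimoto solution at the same
beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import TaskSpec, BLOCK_TYPES, _block_sequence, q_block

__all__ = ["AgentState", "AgentRun", "rpe", "act", "update", "run_agent"]


@dataclass
class AgentState:
    """Learner state: values, policy preferences, and marginal tracker."""

    beta: float
    n_states: int = 9
    n_actions: int = 2
    alpha_v: float = 0.1
    alpha_theta: float = 0.1
    alpha_marginal: float = 0.01
    v: np.ndarray = None
    theta: np.ndarray = None
    marginal_hat: np.ndarray = None

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        for a in (self.alpha_v, self.alpha_theta, self.alpha_marginal):
            if not 0.0 < a <= 1.0:
                raise ValueError("learning rates must lie in (0, 1]")
        if self.v is None:
            self.v = np.zeros(self.n_states)
        if self.theta is None:
            self.theta = np.zeros((self.n_states, self.n_actions))
        if self.marginal_hat is None:
            self.marginal_hat = np.full(self.n_actions, 1.0 / self.n_actions)

    def policy_row(self, s: int) -> np.ndarray:
        """pi(a|s) ∝ exp[theta(s,a) + log marginal_hat(a)]."""
        logits = self.theta[s] + np.log(self.marginal_hat)
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()

    def policy(self) -> np.ndarray:
        logits = self.theta + np.log(self.marginal_hat)[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class AgentRun:
    """A simulated session: trial log, final state, and late-trial policy."""

    trials: pd.DataFrame
    state: AgentState
    terminal_policy: np.ndarray   # pi(a|s) averaged over the tail trials


def rpe(r: float, v: float, cost: float, beta: float) -> float:
    """Cost-penalized reward prediction error delta = r - V - cost/beta.

    ``cost`` is the per-trial policy cost in nats; beta balances reward
    maximization against policy compression (beta = 1 gives the unweighted
    penalty).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return r - v - cost / beta


def act(state: AgentState, s: int, rng: np.random.Generator) -> int:
    """Sample an action from pi(a|s)."""
    return int(rng.choice(state.n_actions, p=state.policy_row(s)))


def update(state: AgentState, s: int, a: int, r: float) -> tuple[AgentState, float, float]:
    """One learning step from a (state, action, reward) transition.

    Computes the policy cost and cost-penalized RPE, then applies the critic
    delta rule, the actor likelihood-gradient step, and an exponential
    moving-average marginal update.  Mutates and returns ``state`` along with
    (delta, cost) for logging.
    """
    pi = state.policy_row(s)
    cost = float(np.log(pi[a] / state.marginal_hat[a]))
    delta = rpe(r, float(state.v[s]), cost, state.beta)
    state.v[s] += state.alpha_v * delta
    grad = -pi
    grad[a] += 1.0
    state.theta[s] += state.alpha_theta * delta * grad
    onehot = np.zeros(state.n_actions)
    onehot[a] = 1.0
    state.marginal_hat += state.alpha_marginal * (onehot - state.marginal_hat)
    np.clip(state.marginal_hat, 1e-8, None, out=state.marginal_hat)
    state.marginal_hat /= state.marginal_hat.sum()
    return state, delta, cost


def run_agent(task: TaskSpec, beta: float, n_trials: int, seed: int,
              alpha_v: float = 0.1, alpha_theta: float = 0.1,
              alpha_marginal: float = 0.01, decay_tau: float | None = 2000.0,
              tail: int = 5000) -> AgentRun:
    """Simulate a full session of cost-penalized learning on the task.

    States are i.i.d. from the task's state distribution within alternating
    reward blocks (same trial generator as the behavioral simulator).
    Learning rates follow a Robbins-Monro harmonic decay
    alpha(t) = alpha * tau / (tau + t) (``decay_tau=None`` keeps them
    constant): at low beta the optimal marginal is only weakly determined,
    so constant-rate updates leave the marginal tracker on a slowly mixing
    random walk instead of settling on the fixed point.

    Logs per-trial delta, cost, and V(s); the terminal policy is pi(a|s)
    averaged over the last ``tail`` trials, which smooths residual
    stochastic-approximation noise.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    state = AgentState(beta=beta, alpha_v=alpha_v, alpha_theta=alpha_theta,
                       alpha_marginal=alpha_marginal)

    block_idx = _block_sequence(n_trials, task.block_length, rng)
    states = rng.choice(9, size=n_trials, p=np.asarray(task.state_probs))
    contrasts = np.asarray(task.contrast_levels)[states]
    target = np.where(contrasts > 0, 1, 0)
    zero = contrasts == 0
    target[zero] = rng.integers(2, size=int(zero.sum()))
    pay = np.array([task.reward_asym[bt] for bt in BLOCK_TYPES])
    unif = rng.random(n_trials)

    tail = min(tail, n_trials)
    pol_sum = np.zeros((state.n_states, state.n_actions))
    log = {k: np.empty(n_trials) for k in ("delta", "cost", "v_s")}
    actions = np.empty(n_trials, dtype=int)
    rewards = np.empty(n_trials)

    for t in range(n_trials):
        if decay_tau is not None:
            d = decay_tau / (decay_tau + t)
            state.alpha_v = alpha_v * d
            state.alpha_theta = alpha_theta * d
            state.alpha_marginal = alpha_marginal * d
        s = states[t]
        pi_s = state.policy_row(s)
        a = int(unif[t] < pi_s[1])
        r = pay[block_idx[t], a] if a == target[t] else 0.0
        log["v_s"][t] = state.v[s]
        _, delta, cost = update(state, s, a, r)
        log["delta"][t] = delta
        log["cost"][t] = cost
        actions[t] = a
        rewards[t] = r
        if t >= n_trials - tail:
            pol_sum += state.policy()

    trials = pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "state_index": states,
        "contrast": contrasts,
        "block_type": np.asarray(BLOCK_TYPES)[block_idx],
        "action": np.where(actions == 1, "right", "left"),
        "correct": actions == target,
        "reward": rewards,
        "delta": log["delta"],
        "cost": log["cost"],
        "v_s": log["v_s"],
    })
    return AgentRun(trials=trials, state=state, terminal_policy=pol_sum / tail)
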