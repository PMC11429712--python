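"""Synthetic task, behavior, and outcome-response generator.

Emulates a head-fixed 2AFC contrast-discrimination task: 9 signed contrast
levels (negative = grating on the left), blockwise asymmetric water rewards
(in one block type the left-correct response pays twice the right-correct
response, and vice versa), choices drawn from the capacity-limited policy
P(a|s) ∝ P(a) exp[beta Q(s,a)] with session-specific inverse temperature and
bias, and outcome-locked responses generated as a cost-penalized reward
prediction error delta = r - V(s) - cost plus Gaussian noise, optionally
embedded as a boxcar in a flat calcium-like trace.

Action coding: 0 = left, 1 = right (CSV labels "left"/"right").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .info import Policy
from .policy import optimal_policy

__all__ = [
    "TaskSpec",
    "PhotometryTrace",
    "DEFAULT_CONTRASTS",
    "make_task",
    "q_block",
    "q_mean",
    "generating_policy",
    "generate_session",
    "generate_responses",
    "generate_dataset",
]

DEFAULT_CONTRASTS = (-0.5, -0.25, -0.125, -0.0625, 0.0, 0.0625, 0.125, 0.25, 0.5)
BLOCK_TYPES = ("left-large", "right-large")


@dataclass(frozen=True)
class TaskSpec:
    """Static task structure.

    contrast_levels : 9 signed contrasts, ascending (fraction; sign = side).
    state_probs     : stimulus distribution P(s), sums to 1.
    block_length    : trials per reward block.
    reward_asym     : mapping block type -> (left-correct, right-correct)
                      water magnitudes; the two block types mirror each other.
    go_cue          : placeholder for timing realism; unused by the analysis.
    """

    contrast_levels: tuple[float, ...]
    state_probs: tuple[float, ...]
    block_length: int
    reward_asym: dict = field(default_factory=dict)
    go_cue: float | None = None

    def __post_init__(self):
        if len(self.contrast_levels) != 9:
            raise ValueError("exactly 9 contrast levels are required")
        if any(b < a for a, b in zip(self.contrast_levels, self.contrast_levels[1:])):
            raise ValueError("contrast levels must be sorted ascending")
        p = np.asarray(self.state_probs, dtype=float)
        if len(p) != 9 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("state_probs must be 9 non-negative values summing to 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        for bt in BLOCK_TYPES:
            if bt not in self.reward_asym:
                raise ValueError(f"reward_asym missing block type {bt!r}")
            left, right = self.reward_asym[bt]
            if left <= 0 or right <= 0:
                raise ValueError("reward magnitudes must be positive")
        ll = self.reward_asym["left-large"]
        rl = self.reward_asym["right-large"]
        if ll != (rl[1], rl[0]):
            raise ValueError("block reward pairs must mirror each other")

    @property
    def n_states(self) -> int:
        return 9

    def state_index(self, contrast: float) -> int:
        return self.contrast_levels.index(contrast)


@dataclass
class PhotometryTrace:
    """Outcome-aligned traces: uniform time grid (ms) x trials."""

    time_ms: np.ndarray            # (n_samples,), relative to outcome delivery
    values: np.ndarray             # (n_samples, n_trials)
    sampling_rate: float           # Hz

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniformly sampled")
        if self.time_ms[0] > -200 or self.time_ms[-1] < 900:
            raise ValueError("time grid must cover at least [-200, 900] ms")
        if self.values.shape[0] != len(self.time_ms):
            raise ValueError("values must have one row per time sample")


def make_task(contrasts=None, state_probs=None, block_length: int = 100,
              reward_large: float = 2.0, reward_small: float = 1.0) -> TaskSpec:
    """Build a TaskSpec; defaults emulate the 9-contrast, 2:1-block task."""
    contrasts = tuple(DEFAULT_CONTRASTS if contrasts is None else contrasts)
    if state_probs is None:
        state_probs = tuple(1.0 / 9 for _ in range(9))
    reward_asym = {"left-large": (float(reward_large), float(reward_small)),
                   "right-large": (float(reward_small), float(reward_large))}
    return TaskSpec(contrast_levels=contrasts, state_probs=tuple(state_probs),
                    block_length=int(block_length), reward_asym=reward_asym)


def q_block(task: TaskSpec, block_type: str) -> np.ndarray:
    """Programmed Q(s,a) within one block: correct side pays, errors pay 0.

    Zero-contrast trials have a uniformly random target side, so each action
    is correct with probability 1/2 and Q is half that side's magnitude.
    """
    r_left, r_right = task.reward_asym[block_type]
    q = np.zeros((9, 2))
    for i, c in enumerate(task.contrast_levels):
        if c < 0:
            q[i, 0] = r_left
        elif c > 0:
            q[i, 1] = r_right
        else:
            q[i] = (0.5 * r_left, 0.5 * r_right)
    return q


def q_mean(task: TaskSpec) -> np.ndarray:
    """Programmed Q(s,a) averaged over the two (equiprobable) block types."""
    return 0.5 * (q_block(task, "left-large") + q_block(task, "right-large"))


def generating_policy(task: TaskSpec, beta: float, bias: float) -> Policy:
    """Generating policy P(a|s) ∝ P(a) exp[beta Q(s,a)] for a session.

    Q is the task's true long-run value table (programmed rewards averaged
    over the two equiprobable block types), so choices depend on the stimulus
    only -- the agent does not track block identity, and its
    (complexity, reward) point lies on the stimulus-only frontier.  The
    returned marginal is self-consistent (sum_s P(s) P(a|s)).
    """
    marg = np.array([1.0 - bias, bias])
    cond = optimal_policy(q_mean(task), marg, beta).cond
    p_s = np.asarray(task.state_probs)
    return Policy(state_probs=p_s, cond=cond, marginal=p_s @ cond)


def _block_sequence(n_trials: int, block_length: int, rng) -> np.ndarray:
    """Alternating block-type indices (0/1), first type seeded random."""
    first = int(rng.integers(2))
    n_blocks = -(-n_trials // block_length)
    types = (np.arange(n_blocks) + first) % 2
    return np.repeat(types, block_length)[:n_trials]


def generate_session(task: TaskSpec, beta: float, bias: float, n_trials: int,
                     seed: int, session_id: str = "s000") -> pd.DataFrame:
    """Simulate one session of choices from the capacity-limited policy.

    States are i.i.d. from the task's state distribution within alternating
    reward blocks; actions are sampled from
    P(a|s) ∝ P(a) exp[beta Q(s,a)] with P(a) = (1-bias, bias) and Q the
    task's long-run value table.  Delivered reward magnitudes follow the
    current block's 2:1 asymmetry.  Deterministic given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not 0.0 < bias < 1.0:
        raise ValueError("bias must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    marg = np.array([1.0 - bias, bias])

    block_idx = _block_sequence(n_trials, task.block_length, rng)
    states = rng.choice(9, size=n_trials, p=np.asarray(task.state_probs))
    contrasts = np.asarray(task.contrast_levels)[states]

    # generative target side; zero-contrast targets assigned at random
    target = np.where(contrasts > 0, 1, 0)
    zero = contrasts == 0
    target[zero] = rng.integers(2, size=int(zero.sum()))

    cond = optimal_policy(q_mean(task), marg, beta).cond
    p_right = cond[states, 1]
    actions = (rng.random(n_trials) < p_right).astype(int)

    correct = actions == target
    pay = np.array([task.reward_asym[bt] for bt in BLOCK_TYPES])  # (2, 2)
    reward = np.where(correct, pay[block_idx, actions], 0.0)

    return pd.DataFrame({
        "session_id": session_id,
        "trial_index": np.arange(n_trials),
        "contrast": contrasts,
        "state_index": states,
        "block_type": np.asarray(BLOCK_TYPES)[block_idx],
        "action": np.where(actions == 1, "right", "left"),
        "correct": correct,
        "reward": reward,
        "beta_true": float(beta),
        "bias_true": float(bias),
    })


def generate_responses(trials: pd.DataFrame, task: TaskSpec,
                       noise_sd: float = 0.5, seed: int = 0,
                       outcome_gain: float = 1.0,
                       traces: bool = False,
                       sampling_rate: float = 200.0
                       ) -> pd.DataFrame | tuple[pd.DataFrame, PhotometryTrace]:
    """Attach outcome-window responses generated by the cost-penalized RPE.

    response_i = gain * (r_i - V(s_i)) - cost_i + eps_i,  eps ~ N(0, sd^2),

    where V(s) is the expected reward and cost_i = log P(a|s)/P(a) under the
    session's block-averaged generating policy.  With ``outcome_gain == 1``
    this is exactly delta = r - V - cost.  A gain proportional to the
    session's inverse temperature models beta-scaled reward sensitivity of
    the prediction error.  The true regressors are recorded as ``value_true``
    and ``cost_true``.

    With ``traces=True`` also returns the responses embedded as a boxcar over
    [300, 800) ms of an otherwise flat trace, to exercise window averaging.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if "beta_true" not in trials or "bias_true" not in trials:
        raise ValueError("trials must carry beta_true/bias_true to recover "
                         "the generating policy")
    beta = float(trials["beta_true"].iloc[0])
    bias = float(trials["bias_true"].iloc[0])
    pol = generating_policy(task, beta, bias)

    # expected reward per state under the generating policy
    v = (pol.cond * q_mean(task)).sum(axis=1)

    s = trials["state_index"].to_numpy()
    a = (trials["action"] == "right").to_numpy().astype(int)
    r = trials["reward"].to_numpy(dtype=float)
    cost = np.log(pol.cond[s, a] / pol.marginal[a])

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=len(trials)) if noise_sd > 0 else 0.0
    response = outcome_gain * (r - v[s]) - cost + eps

    out = trials.copy()
    out["value_true"] = v[s]
    out["cost_true"] = cost
    out["response"] = response
    if not traces:
        return out

    dt_ms = 1000.0 / sampling_rate
    time_ms = np.arange(-200.0, 900.0 + dt_ms / 2, dt_ms)
    values = np.zeros((len(time_ms), len(trials)))
    window = (time_ms >= 300.0) & (time_ms < 800.0)
    values[window, :] = response[None, :]
    return out, PhotometryTrace(time_ms=time_ms, values=values,
                                sampling_rate=sampling_rate)


def generate_dataset(n_sessions: int = 55,
                     beta_range: tuple[float, float] = (0.5, 5.0),
                     bias_range: tuple[float, float] = (0.3, 0.7),
                     n_trials: int = 400, seed: int = 0,
                     task: TaskSpec | None = None,
                     noise_sd: float = 0.5,
                     gain_by_beta: bool = True,
                     with_responses: bool = True) -> list[pd.DataFrame]:
    """Generate a multi-session dataset (default 55 sessions).

    Per-session beta and bias are drawn uniformly from their ranges and
    recorded in the tables.  With ``gain_by_beta`` the outcome-response gain
    equals the session's beta (beta-scaled reward sensitivity); otherwise the
    gain is 1 for every session.  All randomness flows from ``seed``.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    for name, (lo, hi) in (("beta_range", beta_range), ("bias_range", bias_range)):
        if hi < lo:
            raise ValueError(f"{name} is empty")
    if task is None:
        task = make_task()
    rng = np.random.default_rng(seed)
    betas = rng.uniform(*beta_range, size=n_sessions)
    biases = rng.uniform(*bias_range, size=n_sessions)
    child_seeds = rng.integers(0, 2**31 - 1, size=(n_sessions, 2))

    sessions = []
    for i in range(n_sessions):
        tr = generate_session(task, float(betas[i]), float(biases[i]), n_trials,
                              seed=int(child_seeds[i, 0]),
                              session_id=f"s{i:03d}")
        if with_responses:
            gain = float(betas[i]) if gain_by_beta else 1.0
            tr = generate_responses(tr, task, noise_sd=noise_sd,
                                    seed=int(child_seeds[i, 1]),
                                    outcome_gain=gain)
        sessions.append(tr)
    return sessions
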