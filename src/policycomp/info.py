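"""Information-theoretic quantities for policy compression.

A policy pi(a|s) mapping task states (stimuli) to actions is treated as a
communication channel.  Its *complexity* is the mutual information I(S;A)
between states and actions, i.e. the average per-trial *policy cost*
log P(a|s)/P(a).  The maximum expected reward achievable at each complexity
level -- the reward-complexity frontier -- is computed with the
Blahut-Arimoto alternating-minimization algorithm.

Unit convention: per-trial policy costs are in nats (natural log), matching
the learning rule in which they enter; complexities are reported in bits.
The ln 2 conversion is applied explicitly at the reporting boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LN2 = np.log(2.0)

__all__ = [
    "Policy",
    "Frontier",
    "ConvergenceError",
    "estimate_policy",
    "mutual_information",
    "policy_cost",
    "trial_costs",
    "blahut_arimoto",
    "frontier",
    "frontier_deviation",
]


class ConvergenceError(RuntimeError):
    """Blahut-Arimoto failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_policy: "Policy | None" = None):
        super().__init__(message)
        self.last_policy = last_policy


@dataclass
class Policy:
    """A conditional action distribution P(a|s) with marginals.

    Parameters
    ----------
    state_probs : (n_states,) array
        State (stimulus) distribution P(s).
    cond : (n_states, n_actions) array
        Conditional action probabilities P(a|s); rows sum to 1.
    marginal : (n_actions,) array
        Marginal action probabilities P(a).  Need not equal
        ``state_probs @ cond`` (e.g. a session bias plugged into the
        capacity-limited policy); quantities that require self-consistency
        recompute the marginal internally.
    """

    state_probs: np.ndarray
    cond: np.ndarray
    marginal: np.ndarray

    def __post_init__(self):
        self.state_probs = np.asarray(self.state_probs, dtype=float)
        self.cond = np.asarray(self.cond, dtype=float)
        self.marginal = np.asarray(self.marginal, dtype=float)
        if self.cond.ndim != 2:
            raise ValueError("cond must be a 2-D (states x actions) array")
        n_s, n_a = self.cond.shape
        if self.state_probs.shape != (n_s,):
            raise ValueError("state_probs length must match cond rows")
        if self.marginal.shape != (n_a,):
            raise ValueError("marginal length must match cond columns")
        if np.any(self.cond < -1e-12) or np.any(self.state_probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of cond must sum to 1")
        if not np.isclose(self.marginal.sum(), 1.0, atol=1e-10):
            raise ValueError("marginal must sum to 1")
        if not np.isclose(self.state_probs.sum(), 1.0, atol=1e-10):
            raise ValueError("state_probs must sum to 1")

    @property
    def n_states(self) -> int:
        return self.cond.shape[0]

    @property
    def n_actions(self) -> int:
        return self.cond.shape[1]

    def implied_marginal(self) -> np.ndarray:
        """Marginal P(a) = sum_s P(s) P(a|s) implied by cond and state_probs."""
        return self.state_probs @ self.cond

    def is_self_consistent(self, atol: float = 1e-10) -> bool:
        return bool(np.allclose(self.marginal, self.implied_marginal(), atol=atol))


@dataclass
class Frontier:
    """Optimal reward-complexity frontier, indexed by inverse temperature.

    ``betas`` is ascending; ``complexity`` (bits) and ``reward`` are the
    coordinates of the optimal policy at each beta.  Both coordinates are
    non-decreasing in beta.
    """

    betas: np.ndarray
    complexity: np.ndarray
    reward: np.ndarray

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        self.complexity = np.asarray(self.complexity, dtype=float)
        self.reward = np.asarray(self.reward, dtype=float)
        if not (len(self.betas) == len(self.complexity) == len(self.reward)):
            raise ValueError("frontier arrays must have equal length")
        if np.any(np.diff(self.betas) < 0):
            raise ValueError("betas must be ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.betas, "complexity_bits": self.complexity, "reward": self.reward}
        )

    def interp_reward(self, complexity: float) -> float:
        """Optimal reward at a given complexity, linearly interpolated.

        Complexities outside the frontier's range are clamped to the nearest
        endpoint.
        """
        return float(np.interp(complexity, self.complexity, self.reward))


# ---------------------------------------------------------------------------
# Estimation from trial data
# ---------------------------------------------------------------------------

def estimate_policy(trials: pd.DataFrame, pseudocount: float = 1.0,
                    n_states: int = 9, n_actions: int = 2) -> Policy:
    """Plug-in policy estimate from a session's trial table.

    P(a|s) comes from per-state action counts with additive pseudocount
    ``pseudocount``; P(a) from overall action counts (same smoothing); P(s)
    from raw state counts.  Estimated separately per session by callers.

    With ``pseudocount == 0`` a never-visited state would yield an undefined
    row; it is set to uniform with a warning.
    """
    if len(trials) == 0:
        raise ValueError("cannot estimate a policy from an empty trial table")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    s = np.asarray(trials["state_index"], dtype=int)
    a = _action_codes(trials)
    if s.min() < 0 or s.max() >= n_states:
        raise ValueError(f"state_index out of range [0, {n_states})")

    counts = np.zeros((n_states, n_actions))
    np.add.at(counts, (s, a), 1.0)
    row_tot = counts.sum(axis=1)

    smoothed = counts + pseudocount
    with np.errstate(invalid="ignore"):
        cond = smoothed / smoothed.sum(axis=1, keepdims=True)
    if pseudocount == 0:
        unvisited = row_tot == 0
        if unvisited.any():
            warnings.warn(
                f"{int(unvisited.sum())} state(s) never visited with pseudocount=0; "
                "using uniform rows", RuntimeWarning)
            cond[unvisited] = 1.0 / n_actions

    a_counts = counts.sum(axis=0) + pseudocount * n_states
    marginal = a_counts / a_counts.sum()
    state_probs = row_tot / row_tot.sum()
    return Policy(state_probs=state_probs, cond=cond, marginal=marginal)


def _action_codes(trials: pd.DataFrame) -> np.ndarray:
    a = trials["action"]
    if a.dtype == object or str(a.dtype).startswith("str"):
        codes = a.map({"left": 0, "right": 1})
        if codes.isna().any():
            bad = a[codes.isna()].iloc[0]
            raise ValueError(f"unknown action label {bad!r}; expected 'left'/'right'")
        return codes.to_numpy(dtype=int)
    return np.asarray(a, dtype=int)


# ---------------------------------------------------------------------------
# Complexity and cost
# ---------------------------------------------------------------------------

def mutual_information(policy: Policy) -> float:
    """Policy complexity I(S;A) in bits.

    I(S;A) = sum_s sum_a P(s) P(a|s) log2[P(a|s)/P(a)], with 0 log 0 := 0.
    The marginal is recomputed from ``cond`` and ``state_probs`` before
    evaluation so the result is a true mutual information.
    """
    p_s = policy.state_probs
    cond = policy.cond
    marg = p_s @ cond
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(cond > 0, np.log2(np.where(cond > 0, cond, 1.0)) -
                            np.log2(np.where(marg > 0, marg, 1.0)), 0.0)
    return float(np.sum(p_s[:, None] * cond * logratio))


def policy_cost(policy: Policy, state_index, action):
    """Per-trial policy cost log[P(a|s)/P(a)] in nats.

    Vectorized over array-like ``state_index`` and ``action``.  Raises if any
    queried conditional probability is zero (cannot occur with pseudocount
    smoothing) or the marginal is zero.
    """
    s = np.asarray(state_index, dtype=int)
    a = np.asarray(action, dtype=int)
    p_as = policy.cond[s, a]
    p_a = policy.marginal[a]
    if np.any(p_a <= 0):
        raise ValueError("marginal probability of a queried action is zero")
    if np.any(p_as <= 0):
        raise ValueError("P(a|s)=0 for an observed (s,a); use pseudocount smoothing")
    out = np.log(p_as / p_a)
    return out if out.ndim else float(out)


def trial_costs(policy: Policy, trials: pd.DataFrame) -> np.ndarray:
    """Policy-cost regressor: cost (nats) for every trial in the table."""
    return policy_cost(policy, trials["state_index"].to_numpy(),
                       _action_codes(trials))


# ---------------------------------------------------------------------------
# Blahut-Arimoto and the frontier
# ---------------------------------------------------------------------------

def blahut_arimoto(q: np.ndarray, state_probs: np.ndarray, beta: float,
                   tol: float = 1e-10, max_iter: int = 10_000
                   ) -> tuple[Policy, float, float]:
    """Optimal capacity-limited policy at inverse temperature ``beta``.

    Alternates P(a|s) ∝ P(a) exp[beta Q(s,a)] (row-normalized) and
    P(a) = sum_s P(s) P(a|s) from a uniform-marginal start until the
    max-norm change of the marginal drops below ``tol``.

    Returns ``(policy, complexity_bits, expected_reward)``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    q = np.asarray(q, dtype=float)
    p_s = np.asarray(state_probs, dtype=float)
    n_s, n_a = q.shape
    marg = np.full(n_a, 1.0 / n_a)
    cond = np.tile(marg, (n_s, 1))
    for _ in range(max_iter):
        logits = beta * q + np.log(np.maximum(marg, 1e-300))
        logits -= logits.max(axis=1, keepdims=True)
        cond = np.exp(logits)
        cond /= cond.sum(axis=1, keepdims=True)
        new_marg = p_s @ cond
        delta = np.max(np.abs(new_marg - marg))
        marg = new_marg
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"Blahut-Arimoto did not converge in {max_iter} iterations "
            f"(last marginal change {delta:.3g})",
            last_policy=Policy(p_s, cond, marg / marg.sum()))
    pol = Policy(state_probs=p_s, cond=cond, marginal=marg / marg.sum())
    reward = float(np.sum(p_s[:, None] * cond * q))
    return pol, mutual_information(pol), reward


def frontier(q: np.ndarray, state_probs: np.ndarray,
             beta_grid: np.ndarray | None = None,
             tol: float = 1e-10, max_iter: int = 10_000) -> Frontier:
    """Reward-complexity frontier over a grid of inverse temperatures.

    The beta = 0 endpoint is evaluated analytically: zero complexity and
    reward max_a sum_s P(s) Q(s,a) (the best unconditional policy).  The
    default grid is 100 log-spaced betas in [0.01, 100] plus that endpoint.
    """
    if beta_grid is None:
        beta_grid = np.geomspace(0.01, 100.0, 100)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid < 0) or np.any(np.diff(beta_grid) < 0):
        raise ValueError("beta_grid must be ascending and non-negative")
    q = np.asarray(q, dtype=float)
    p_s = np.asarray(state_probs, dtype=float)

    betas = [0.0]
    complexity = [0.0]
    reward = [float(np.max(p_s @ q))]
    for b in beta_grid:
        if b == 0:
            continue
        _, c, r = blahut_arimoto(q, p_s, b, tol=tol, max_iter=max_iter)
        betas.append(b)
        # numerical guard: BA at tiny beta can land a hair below the analytic
        # zero-complexity optimum; the frontier is monotone by construction
        complexity.append(max(c, complexity[-1]))
        reward.append(max(r, reward[-1]))
    return Frontier(np.array(betas), np.array(complexity), np.array(reward))


def frontier_deviation(complexity: float, reward: float, front: Frontier) -> float:
    """Percent shortfall of a (complexity, reward) point below the frontier.

    100 * (R_opt(I) - R) / R_opt(I), with R_opt(I) the linearly interpolated
    optimal reward at the point's complexity (clamped to the frontier's
    range).  Negative values (points above the curve, from estimation noise)
    are returned as-is.
    """
    r_opt = front.interp_reward(complexity)
    if r_opt <= 0:
        raise ValueError("optimal reward at this complexity is non-positive")
    return 100.0 * (r_opt - reward) / r_opt
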