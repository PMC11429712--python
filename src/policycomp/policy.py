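"""Capacity-limited policy fitting.

The optimal capacity-limited policy for a 2AFC contrast-discrimination task
is P(a|s) ∝ exp[beta * Q(s,a) + log P(a)]: a softmax over action values
tilted toward the marginal action distribution (the session bias).  The
inverse temperature beta is the single free parameter, fit per session by
maximum likelihood; the bias is plugged in from the session's empirical
choice frequencies rather than jointly optimized.  A small amount of state
uncertainty is captured by smoothing Q across neighboring contrast levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .info import Policy, _action_codes

__all__ = [
    "PolicyFit",
    "smooth_values",
    "optimal_policy",
    "empirical_q",
    "fit_beta",
    "compare_bias_models",
    "psychometric_prediction",
]

BETA_MAX = 50.0
BIAS_EPS = 1e-3


@dataclass
class PolicyFit:
    """Maximum-likelihood fit of the capacity-limited policy to one session."""

    beta_hat: float
    bias: float                 # session marginal P(right)
    loglik: float
    bic: float
    n_trials: int
    q_used: np.ndarray          # value table after smoothing, (9, 2)
    include_bias: bool
    session_id: str | None = None

    @property
    def marginal(self) -> np.ndarray:
        return np.array([1.0 - self.bias, self.bias])


def smooth_values(q: np.ndarray, weight: float) -> np.ndarray:
    """Smooth Q across contrast-adjacent states with a triangular kernel.

    Interior states get weights (w, 1-2w, w) over (previous, self, next);
    edge states renormalize over their available neighbors.  States must be
    ordered by signed contrast.  ``weight == 0`` is the identity.
    """
    if not 0.0 <= weight < 0.5:
        raise ValueError("smoothing weight must be in [0, 0.5)")
    q = np.asarray(q, dtype=float)
    if weight == 0.0:
        return q.copy()
    out = np.empty_like(q)
    n = q.shape[0]
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        w = np.zeros(n)
        w[i] = 1.0 - 2.0 * weight
        if lo != i:
            w[lo] += weight
        if hi != i:
            w[hi] += weight
        out[i] = w[lo:hi + 1] @ q[lo:hi + 1] / w[lo:hi + 1].sum()
    return out


def optimal_policy(q: np.ndarray, marginal: np.ndarray, beta: float,
                   state_probs: np.ndarray | None = None) -> Policy:
    """Capacity-limited softmax policy P(a|s) ∝ P(a) exp[beta Q(s,a)].

    Numerically stabilized by max-subtraction in the exponent.  The returned
    Policy carries ``marginal`` as given (the plugged-in bias), which need
    not be self-consistent with the conditional.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q, dtype=float)
    marginal = np.asarray(marginal, dtype=float)
    if np.any(marginal <= 0):
        raise ValueError("marginal entries must be strictly positive")
    logits = beta * q + np.log(marginal)
    logits -= logits.max(axis=1, keepdims=True)
    cond = np.exp(logits)
    cond /= cond.sum(axis=1, keepdims=True)
    if state_probs is None:
        state_probs = np.full(q.shape[0], 1.0 / q.shape[0])
    return Policy(state_probs=np.asarray(state_probs, dtype=float),
                  cond=cond, marginal=marginal / marginal.sum())


def empirical_q(trials: pd.DataFrame, fill_q: np.ndarray | None = None,
                n_states: int = 9, n_actions: int = 2) -> np.ndarray:
    """Empirical mean reward per (state, action) cell.

    Unvisited cells are filled from ``fill_q`` (typically the programmed
    task rewards) or, if absent, the grand mean reward.
    """
    s = np.asarray(trials["state_index"], dtype=int)
    a = _action_codes(trials)
    r = np.asarray(trials["reward"], dtype=float)
    tot = np.zeros((n_states, n_actions))
    cnt = np.zeros((n_states, n_actions))
    np.add.at(tot, (s, a), r)
    np.add.at(cnt, (s, a), 1.0)
    with np.errstate(invalid="ignore"):
        q = tot / cnt
    missing = cnt == 0
    if missing.any():
        fill = np.asarray(fill_q, dtype=float) if fill_q is not None \
            else np.full((n_states, n_actions), r.mean())
        q[missing] = fill[missing]
    return q


def _session_marginal(trials: pd.DataFrame) -> np.ndarray:
    a = _action_codes(trials)
    p_right = a.mean()
    if p_right <= 0.0 or p_right >= 1.0:
        warnings.warn("all-one-action session; clipping bias away from 0/1",
                      RuntimeWarning)
        p_right = float(np.clip(p_right, BIAS_EPS, 1.0 - BIAS_EPS))
    return np.array([1.0 - p_right, p_right])


def fit_beta(trials: pd.DataFrame, q: np.ndarray | None = None,
             smoothing_w: float = 0.25, include_bias: bool = True,
             fill_q: np.ndarray | None = None,
             beta_max: float = BETA_MAX) -> PolicyFit:
    """Fit the inverse temperature to one session's choices by ML.

    The marginal is fixed at the session's empirical P(a) when
    ``include_bias``, else at (0.5, 0.5); only beta is optimized, over
    [0, beta_max].  The likelihood is evaluated on (state, action) counts; a
    coarse log-spaced scan brackets the optimum before a bounded scalar
    refinement, guarding against flat-likelihood traps.  BIC = k ln n - 2 LL
    with k = 2 (beta plus the plug-in bias) or 1 (bias-free).
    """
    if len(trials) == 0:
        raise ValueError("cannot fit an empty trial table")
    if q is None:
        q = empirical_q(trials, fill_q=fill_q)
    q_used = smooth_values(np.asarray(q, dtype=float), smoothing_w)
    marginal = _session_marginal(trials) if include_bias else np.array([0.5, 0.5])

    s = np.asarray(trials["state_index"], dtype=int)
    a = _action_codes(trials)
    counts = np.zeros_like(q_used)
    np.add.at(counts, (s, a), 1.0)

    log_marg = np.log(marginal)

    def loglik(beta: float) -> float:
        logits = beta * q_used + log_marg
        logits -= logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return float(np.sum(counts * (logits - logz)))

    # bracket on a dense log grid (plus 0), then refine
    grid = np.concatenate([[0.0], np.geomspace(1e-3, beta_max, 60)])
    lls = np.array([loglik(b) for b in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        beta_hat = float(lo)
    else:
        res = minimize_scalar(lambda b: -loglik(b), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-10})
        beta_hat = float(res.x)
        if loglik(beta_hat) < lls[i]:
            beta_hat = float(grid[i])

    ll = loglik(beta_hat)
    k = 2 if include_bias else 1
    n = len(trials)
    bic = k * np.log(n) - 2.0 * ll
    sid = trials["session_id"].iloc[0] if "session_id" in trials else None
    return PolicyFit(beta_hat=beta_hat, bias=float(marginal[1]), loglik=ll,
                     bic=float(bic), n_trials=n, q_used=q_used,
                     include_bias=include_bias, session_id=sid)


def compare_bias_models(sessions: list[pd.DataFrame],
                        q: np.ndarray | None = None,
                        smoothing_w: float = 0.25,
                        fill_q: np.ndarray | None = None,
                        pooled: bool = False) -> float:
    """ΔBIC = BIC(bias-free) - BIC(with-bias); positive favors the bias model.

    Summed over per-session fits by default; ``pooled=True`` instead
    concatenates all trials and fits a single model of each kind.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    if pooled:
        sessions = [pd.concat(sessions, ignore_index=True)]
    bic_bias = bic_free = 0.0
    for tr in sessions:
        bic_bias += fit_beta(tr, q=q, smoothing_w=smoothing_w, fill_q=fill_q,
                             include_bias=True).bic
        bic_free += fit_beta(tr, q=q, smoothing_w=smoothing_w, fill_q=fill_q,
                             include_bias=False).bic
    return float(bic_free - bic_bias)


def psychometric_prediction(fit: PolicyFit, contrasts: np.ndarray) -> pd.DataFrame:
    """Model psychometric curve: P(right | contrast) at the fitted beta/bias."""
    pol = optimal_policy(fit.q_used, fit.marginal, fit.beta_hat)
    return pd.DataFrame({"contrast": np.asarray(contrasts, dtype=float),
                         "p_right": pol.cond[:, 1]})
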