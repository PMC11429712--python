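"""Outcome-locked response analysis.

Turns outcome-aligned calcium traces into scalar responses (mean over
[300, 800) ms minus a baseline centered on outcome delivery), z-scores them
within session, and regresses them on four regressors -- intercept, policy
cost, action value, and outcome (water amount) -- by pooled ordinary least
squares.  Partial residuals visualize the cost effect after adjusting for
the other regressors; nested-model BIC comparison tests whether the cost
term earns its keep; and per-session outcome coefficients are correlated
with the behaviorally fitted inverse temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .info import Policy, trial_costs, _action_codes
from .synth import PhotometryTrace

__all__ = [
    "RegressionFit",
    "REGRESSOR_NAMES",
    "window_response",
    "zscore_within_session",
    "build_regressors",
    "fit_dopamine_regression",
    "compare_cost_models",
    "partial_residuals",
    "correlate_beta_outcome",
]

REGRESSOR_NAMES = ("intercept", "cost", "value", "outcome")

RESPONSE_WINDOW_MS = (300.0, 800.0)   # encompasses the calcium peak
BASELINE_WINDOW_MS = (-100.0, 100.0)  # 200 ms centered on outcome delivery


@dataclass
class RegressionFit:
    """OLS fit of responses on (intercept, cost, value, outcome)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    loglik: float
    bic: float
    n: int
    residuals: np.ndarray
    fitted: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "coef": self.coef,
                             "se": self.se, "t": self.tstats,
                             "p": self.pvalues})

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])


def window_response(trace: PhotometryTrace) -> np.ndarray:
    """Scalar outcome response per trial.

    Mean of the trace over [300, 800) ms after outcome delivery minus the
    mean over the [-100, 100) ms baseline window.
    """
    t = trace.time_ms
    resp = (t >= RESPONSE_WINDOW_MS[0]) & (t < RESPONSE_WINDOW_MS[1])
    base = (t >= BASELINE_WINDOW_MS[0]) & (t < BASELINE_WINDOW_MS[1])
    if not resp.any() or not base.any():
        raise ValueError("response or baseline window contains no samples")
    return trace.values[resp].mean(axis=0) - trace.values[base].mean(axis=0)


def zscore_within_session(responses: np.ndarray, sessions: np.ndarray) -> np.ndarray:
    """Z-score responses separately within each session (sd with ddof=1)."""
    responses = np.asarray(responses, dtype=float)
    sessions = np.asarray(sessions)
    out = np.empty_like(responses)
    for sid in pd.unique(sessions):
        m = sessions == sid
        x = responses[m]
        if m.sum() < 2:
            raise ValueError(f"session {sid!r} has fewer than 2 trials")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"session {sid!r} has zero response variance")
        out[m] = (x - x.mean()) / sd
    return out


def build_regressors(trials: pd.DataFrame, policy: Policy,
                     q: np.ndarray) -> pd.DataFrame:
    """Design matrix for the outcome-response regression.

    Per trial: cost = log P(a|s)/P(a) (nats) under the session's plug-in
    policy; value = Q(s, a_chosen), the average reward for the chosen action
    conditional on the stimulus; outcome = delivered water amount; plus an
    intercept.
    """
    s = trials["state_index"].to_numpy(dtype=int)
    a = _action_codes(trials)
    return pd.DataFrame({
        "intercept": np.ones(len(trials)),
        "cost": trial_costs(policy, trials),
        "value": np.asarray(q, dtype=float)[s, a],
        "outcome": trials["reward"].to_numpy(dtype=float),
    })


def _gaussian_bic(rss: float, n: int, k: int) -> tuple[float, float]:
    """Profiled-variance Gaussian log-likelihood and BIC = n ln(RSS/n) + k ln n."""
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return loglik, n * np.log(sigma2) + k * np.log(n)


def fit_dopamine_regression(y: np.ndarray, X: pd.DataFrame) -> RegressionFit:
    """Pooled OLS of normalized responses on the design matrix."""
    y = np.asarray(y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    n, k = Xm.shape
    if n <= k:
        raise ValueError("need more observations than regressors")
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(Xm, rowvar=False)
        pairs = [(X.columns[i], X.columns[j])
                 for i in range(k) for j in range(i + 1, k)
                 if abs(corr[i, j]) > 1 - 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {pairs}")
    res = sm.OLS(y, Xm).fit()
    rss = float(res.ssr)
    loglik, bic = _gaussian_bic(rss, n, k)
    return RegressionFit(names=tuple(X.columns), coef=res.params,
                         se=res.bse, tstats=res.tvalues, pvalues=res.pvalues,
                         loglik=loglik, bic=bic, n=n,
                         residuals=np.asarray(res.resid),
                         fitted=np.asarray(res.fittedvalues))


def compare_cost_models(y: np.ndarray, X: pd.DataFrame) -> float:
    """ΔBIC = BIC(model without cost) - BIC(full); positive favors cost."""
    full = fit_dopamine_regression(y, X)
    reduced = fit_dopamine_regression(y, X.drop(columns=["cost"]))
    return float(reduced.bic - full.bic)


def partial_residuals(fit: RegressionFit, X: pd.DataFrame,
                      regressor: str = "cost") -> np.ndarray:
    """Residuals plus the fitted contribution of one regressor.

    Regressing the output on that regressor alone recovers its
    multiple-regression coefficient (Frisch-Waugh).
    """
    if regressor not in fit.names:
        raise KeyError(f"unknown regressor {regressor!r}; have {fit.names}")
    return fit.residuals + fit[regressor] * np.asarray(X[regressor], dtype=float)


def correlate_beta_outcome(betas: np.ndarray,
                           outcome_coefs: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-session inverse
    temperatures and outcome regression coefficients."""
    betas = np.asarray(betas, dtype=float)
    outcome_coefs = np.asarray(outcome_coefs, dtype=float)
    if len(betas) != len(outcome_coefs) or len(betas) < 3:
        raise ValueError("need >= 3 paired sessions")
    if np.ptp(betas) == 0 or np.ptp(outcome_coefs) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(betas, outcome_coefs)
    return float(r), float(p)
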