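"""Configuration, delimited-text IO, and the end-to-end analysis pipeline.

The pipeline runs, in order: synthetic dataset generation (or CSV ingestion),
the Blahut-Arimoto reward-complexity frontier, per-session plug-in policy
complexity and frontier deviation, per-session capacity-limited policy fits
with a bias-model BIC comparison, the pooled outcome-response regression with
a cost-model BIC comparison, and the correlation of per-session outcome
coefficients with fitted inverse temperatures.  All outputs are delimited
text plus a JSON summary; a manifest records the config, seed, and library
versions so runs are pure functions of (data, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import info, neural, policy as policy_mod, synth

__all__ = ["RunConfig", "read_trials", "write_trials", "read_trace",
           "write_trace", "run_pipeline", "TRIAL_COLUMNS"]

# documented trial-table schema (columns written/required by read_trials)
TRIAL_COLUMNS = ("session_id", "trial_index", "contrast", "state_index",
                 "block_type", "action", "correct", "reward")
OPTIONAL_COLUMNS = ("beta_true", "bias_true", "value_true", "cost_true",
                    "response")


@dataclass
class RunConfig:
    """Full pipeline configuration with documented defaults.

    Task: ``contrasts`` (9 signed levels), ``block_length`` (trials per
    reward block), ``reward_large``/``reward_small`` (2:1 water asymmetry).
    Generation: session count/length, uniform beta and bias ranges, response
    noise sd, beta-scaled outcome gain.  Estimation: plug-in pseudocount,
    value-smoothing weight.  Frontier: log-spaced beta grid.  ``seed`` feeds
    every random draw.
    """

    contrasts: list = field(default_factory=lambda: list(synth.DEFAULT_CONTRASTS))
    block_length: int = 100
    reward_large: float = 2.0
    reward_small: float = 1.0
    n_sessions: int = 55
    n_trials: int = 400
    beta_range: list = field(default_factory=lambda: [0.5, 5.0])
    bias_range: list = field(default_factory=lambda: [0.3, 0.7])
    noise_sd: float = 0.5
    gain_by_beta: bool = True
    pseudocount: float = 1.0
    smoothing_w: float = 0.25
    beta_grid_min: float = 0.01
    beta_grid_max: float = 100.0
    beta_grid_num: int = 100
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def task(self) -> synth.TaskSpec:
        return synth.make_task(contrasts=self.contrasts,
                               block_length=self.block_length,
                               reward_large=self.reward_large,
                               reward_small=self.reward_small)

    def beta_grid(self) -> np.ndarray:
        return np.geomspace(self.beta_grid_min, self.beta_grid_max,
                            self.beta_grid_num)


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def write_trials(sessions: list[pd.DataFrame], path) -> None:
    """Write a multi-session trial table as a single CSV."""
    pd.concat(sessions, ignore_index=True).to_csv(path, index=False)


def read_trials(path) -> list[pd.DataFrame]:
    """Read a trial-table CSV, validate it, and split by session.

    Errors name the offending row and column.  Row order within sessions is
    preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    for col in ("contrast", "reward"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    bad_action = ~df["action"].isin(["left", "right"])
    if bad_action.any():
        row = int(df.index[bad_action][0])
        raise ValueError(f"unknown action label {df.loc[row, 'action']!r} "
                         f"in column 'action' at row {row}")
    neg = df["reward"] < 0
    if neg.any():
        row = int(df.index[neg][0])
        raise ValueError(f"negative reward in column 'reward' at row {row}")
    df["correct"] = df["correct"].astype(bool)
    mism = (df["reward"] > 0) != df["correct"]
    if mism.any():
        row = int(df.index[mism][0])
        raise ValueError(f"reward/correct inconsistency at row {row}: "
                         "reward must be positive iff correct")
    return [g.reset_index(drop=True) for _, g in df.groupby("session_id", sort=False)]


def write_trace(trace: synth.PhotometryTrace, path) -> None:
    """Write a trace as CSV: first column time_ms, one column per trial."""
    cols = {"time_ms": trace.time_ms}
    for j in range(trace.values.shape[1]):
        cols[f"trial_{j}"] = trace.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace(path) -> synth.PhotometryTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    vals = df.drop(columns=["time_ms"]).to_numpy(dtype=float)
    rate = 1000.0 / float(np.diff(t)[0])
    return synth.PhotometryTrace(time_ms=t, values=vals, sampling_rate=rate)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """A pipeline stage failed; names the stage (and session, if any)."""


def run_pipeline(config: RunConfig, sessions: list[pd.DataFrame] | None = None,
                 write: bool = True) -> dict:
    """Run every analysis stage; return (and optionally write) the bundle.

    If ``sessions`` is None a synthetic dataset is generated from the config.
    Returns a dict with the frontier, per-session metrics, regression fit,
    ΔBIC values, the beta-outcome correlation, and a summary of headline
    numbers.
    """
    t0 = time.time()
    task = config.task()
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time() - t0

    if sessions is None:
        sessions = synth.generate_dataset(
            n_sessions=config.n_sessions,
            beta_range=tuple(config.beta_range),
            bias_range=tuple(config.bias_range),
            n_trials=config.n_trials, seed=config.seed, task=task,
            noise_sd=config.noise_sd, gain_by_beta=config.gain_by_beta)
    stage("generate")

    # --- frontier on the programmed (block-averaged) value table
    q_task = synth.q_mean(task)
    front = info.frontier(q_task, np.asarray(task.state_probs),
                          config.beta_grid())
    stage("frontier")

    # --- per-session complexity, reward, deviation; policy fits; regression parts
    rows, y_parts, X_parts = [], [], []
    bic_bias = bic_free = 0.0
    for tr in sessions:
        sid = tr["session_id"].iloc[0]
        try:
            pol = info.estimate_policy(tr, pseudocount=config.pseudocount)
            complexity = info.mutual_information(pol)
            mean_reward = float(tr["reward"].mean())
            deviation = info.frontier_deviation(complexity, mean_reward, front)

            fit_b = policy_mod.fit_beta(tr, smoothing_w=config.smoothing_w,
                                        fill_q=q_task, include_bias=True)
            fit_f = policy_mod.fit_beta(tr, smoothing_w=config.smoothing_w,
                                        fill_q=q_task, include_bias=False)
            bic_bias += fit_b.bic
            bic_free += fit_f.bic

            row = {"session_id": sid, "n_trials": len(tr),
                   "complexity_bits": complexity, "mean_reward": mean_reward,
                   "deviation_pct": deviation, "beta_hat": fit_b.beta_hat,
                   "bias": fit_b.bias, "loglik": fit_b.loglik, "bic": fit_b.bic}

            if "response" in tr:
                q_emp = policy_mod.smooth_values(
                    policy_mod.empirical_q(tr, fill_q=q_task), config.smoothing_w)
                X = neural.build_regressors(tr, pol, q_emp)
                z = neural.zscore_within_session(
                    tr["response"].to_numpy(), tr["session_id"].to_numpy())
                y_parts.append(z)
                X_parts.append(X)
                sess_fit = neural.fit_dopamine_regression(z, X)
                row["outcome_coef"] = sess_fit["outcome"]
            rows.append(row)
        except Exception as e:  # noqa: BLE001 - annotate stage and session
            raise StageError(f"per-session analysis failed for session {sid!r}: {e}") from e
    metrics = pd.DataFrame(rows)
    delta_bic_bias = float(bic_free - bic_bias)
    stage("sessions")

    bundle: dict = {"config": asdict(config), "frontier": front,
                    "session_metrics": metrics,
                    "delta_bic_bias": delta_bic_bias,
                    "median_deviation_pct": float(metrics["deviation_pct"].median())}

    if y_parts:
        y = np.concatenate(y_parts)
        X = pd.concat(X_parts, ignore_index=True)
        try:
            reg = neural.fit_dopamine_regression(y, X)
            delta_bic_cost = neural.compare_cost_models(y, X)
        except Exception as e:
            raise StageError(f"regression stage failed: {e}") from e
        bundle["regression"] = reg
        bundle["delta_bic_cost"] = float(delta_bic_cost)
        bundle["partial_residual_cost"] = neural.partial_residuals(reg, X, "cost")
        r, p = neural.correlate_beta_outcome(
            metrics["beta_hat"].to_numpy(), metrics["outcome_coef"].to_numpy())
        bundle["beta_outcome_r"] = r
        bundle["beta_outcome_p"] = p
    stage("regression")

    summary = {
        "n_sessions": len(sessions),
        "n_trials_total": int(sum(len(s) for s in sessions)),
        "median_deviation_pct": bundle["median_deviation_pct"],
        "delta_bic_bias": delta_bic_bias,
    }
    if "regression" in bundle:
        reg = bundle["regression"]
        for term in ("outcome", "value", "cost"):
            i = reg.names.index(term)
            summary[f"coef_{term}"] = float(reg.coef[i])
            summary[f"t_{term}"] = float(reg.tstats[i])
        summary["delta_bic_cost"] = bundle["delta_bic_cost"]
        summary["beta_outcome_r"] = bundle["beta_outcome_r"]
        summary["beta_outcome_p"] = bundle["beta_outcome_p"]
    bundle["summary"] = summary

    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(sessions, out / "trials.csv")
        front.to_frame().to_csv(out / "frontier.csv", index=False)
        metrics.to_csv(out / "session_metrics.csv", index=False)
        if "regression" in bundle:
            bundle["regression"].summary_frame().to_csv(
                out / "regression_summary.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        cfg_bytes = json.dumps(asdict(config), sort_keys=True).encode()
        manifest = {
            "config": asdict(config),
            "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
            "seed": config.seed,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "stage_times_s": timings,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle
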