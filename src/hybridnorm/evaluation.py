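"""Predictive-ability statistics.

Predictive ability is assessed per environment as the Pearson correlation
r_i between predicted and observed yields, then averaged across the I
environments with inverse-sampling-variance weights:

    r_phi = sum_i(r_i / V(r_i)) / sum_i(1 / V(r_i)),
    V(r_i) = (1 - r_i^2) / (n_i - 2),

with a normal-approximation 95% CI r_phi +/- 1.96 * sqrt(1 / sum_i 1/V_i).
Environments with |r_i| = 1 get an epsilon variance floor so their weight is
large but finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalSummary",
    "env_correlations",
    "sampling_variance",
    "weighted_correlation",
    "evaluate",
    "percent_improvement",
    "design_sparsity",
]

#: variance floor applied when |r_i| = 1 makes the sampling variance 0
V_EPSILON = 1e-8


@dataclass
class EvalSummary:
    """Per-environment correlations and their weighted average for one run."""

    per_env: pd.DataFrame  # env, r, n, v
    r_phi: float
    ci95: tuple[float, float]
    model_id: str = ""
    scheme: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "model": self.model_id,
                "scheme": self.scheme,
                "r_phi": self.r_phi,
                "ci_lo": self.ci95[0],
                "ci_hi": self.ci95[1],
                "n_env": len(self.per_env),
            }]
        )


def env_correlations(pred_table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlation of predicted vs observed within each environment.

    Environments with fewer than ``min_n`` pairs, or with zero variance in
    either column, are dropped with a warning. Returns columns env, r, n.
    """
    rows = []
    dropped = []
    for env, g in pred_table.groupby("env"):
        obs = g["observed"].to_numpy(dtype=float)
        pred = g["predicted"].to_numpy(dtype=float)
        if len(g) < min_n or obs.std() == 0 or pred.std() == 0:
            dropped.append(env)
            continue
        r = float(stats.pearsonr(obs, pred).statistic)
        rows.append({"env": env, "r": r, "n": len(g)})
    if dropped:
        warnings.warn(
            f"environments dropped from evaluation (too few pairs or zero "
            f"variance): {dropped}"
        )
    return pd.DataFrame(rows, columns=["env", "r", "n"])


def sampling_variance(r: float, n: int) -> float:
    """Sampling variance of a Pearson correlation: (1 - r^2) / (n - 2).

    Returns exactly 0 when |r| = 1 (downstream weighting applies an epsilon
    floor); requires n >= 3.
    """
    if n < 3:
        raise ValueError("sampling variance needs n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return (1.0 - r * r) / (n - 2)


def weighted_correlation(
    rows: list[tuple[float, float]], fisher_z: bool = False
) -> tuple[float, tuple[float, float]]:
    """Inverse-variance-weighted mean correlation with a 95% CI.

    ``rows`` is a list of (r_i, V_i) pairs. The default weights the raw
    correlations; ``fisher_z=True`` instead averages on the Fisher z scale
    (with the supplied variances) and back-transforms, for sensitivity
    analysis.
    """
    if not rows:
        raise ValueError("weighted_correlation needs at least one environment")
    r = np.array([x[0] for x in rows], dtype=float)
    v = np.maximum(np.array([x[1] for x in rows], dtype=float), V_EPSILON)
    if fisher_z:
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        w = 1.0 / v
        z_phi = float(np.sum(z * w) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        return float(np.tanh(z_phi)), (float(np.tanh(z_phi - 1.96 * se)),
                                       float(np.tanh(z_phi + 1.96 * se)))
    w = 1.0 / v
    r_phi = float(np.sum(r * w) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return r_phi, (r_phi - 1.96 * se, r_phi + 1.96 * se)


def evaluate(
    pred_table: pd.DataFrame, model_id: str = "", scheme: str = "",
    fisher_z: bool = False,
) -> EvalSummary:
    """Full evaluation of a prediction table: per-env r, weighted r_phi, CI."""
    per_env = env_correlations(pred_table)
    if per_env.empty:
        raise ValueError("no environment had enough prediction pairs to evaluate")
    per_env["v"] = [sampling_variance(r, n) for r, n in zip(per_env["r"], per_env["n"])]
    r_phi, ci = weighted_correlation(
        list(zip(per_env["r"], per_env["v"])), fisher_z=fisher_z
    )
    return EvalSummary(per_env, r_phi, ci, model_id=model_id, scheme=scheme)


def percent_improvement(baseline: float, alternative: float) -> float:
    """Percentage change of `alternative` over `baseline`: 100*(alt-base)/base."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (alternative - baseline) / baseline


def design_sparsity(n_records: int, n_hybrids: int, n_envs: int) -> float:
    """Observed share (%) of the hybrid x environment table."""
    total = n_hybrids * n_envs
    if total <= 0:
        raise ValueError("need positive hybrid and environment counts")
    return 100.0 * n_records / total
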