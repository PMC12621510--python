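"""Monte-Carlo evaluation criteria for the simulation study.

Per (condition, strategy) cell the replication records are summarized into
relative/absolute bias of estimates and standard errors, RMSE, efficiency,
coverage of the 95% Wald intervals, rejection rate (power when the true value
is nonzero, false-positive rate when it is zero), and convergence rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .population_model import PathCoefficients
from .tssem import STATUS_FAILED

PARAM_NAMES = ("b_x_m1", "b_x_m2", "b_m1_y", "b_m2_y", "b_x_y", "psi_m1_m2")


class UndefinedMetricError(ValueError):
    """Relative bias requested for a zero population value."""


@dataclass
class ReplicationRecord:
    condition_id: str
    strategy: str
    replication: int
    estimates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reject: np.ndarray          # |z| > 1.96, element-wise
    stage1_status: int
    stage2_status: int

    @property
    def converged(self) -> bool:
        return self.stage1_status < STATUS_FAILED and self.stage2_status < STATUS_FAILED


def truth_vector(paths: PathCoefficients) -> np.ndarray:
    """Population values in parameter order (psi is the residual mediator
    covariance implied by the total mediator correlation)."""
    return paths.to_vector()


def relative_bias(estimates: Sequence[float], truth: float) -> float:
    """100 * (mean estimate - truth) / truth; undefined at truth = 0."""
    if truth == 0:
        raise UndefinedMetricError("relative bias undefined for a zero truth")
    return 100.0 * (float(np.mean(estimates)) - truth) / truth


def rmse(estimates: Sequence[float], truth: float) -> float:
    """sqrt(squared bias + sampling variance of the estimates)."""
    est = np.asarray(estimates, dtype=float)
    mean = est.mean()
    return float(np.sqrt((mean - truth) ** 2 + np.mean((est - mean) ** 2)))


def mc_interval(target: float, reps: int) -> tuple[float, float]:
    """Normal-approximation Monte-Carlo interval for an observed proportion
    around ``target`` at ``reps`` replications, to 3 decimals."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    half = 1.96 * np.sqrt(target * (1.0 - target) / reps)
    return (round(target - half, 3), round(target + half, 3))


@dataclass
class ConditionSummary:
    """Per-parameter evaluation metrics for one (condition, strategy) cell."""

    condition_id: str
    strategy: str
    table: pd.DataFrame         # one row per parameter
    n_total: int
    n_converged: int

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_total if self.n_total else np.nan


def summarize(
    records: Sequence[ReplicationRecord], truth: PathCoefficients | np.ndarray
) -> ConditionSummary:
    """Summarize replications against the population parameters.

    Non-converged replications are excluded from every metric and counted in
    the convergence rate.  Relative bias is NaN for parameters with a zero
    population value (the rejection rate is their false-positive rate).
    """
    if isinstance(truth, PathCoefficients):
        truth = truth_vector(truth)
    truth = np.asarray(truth, dtype=float)
    ok = [rec for rec in records if rec.converged]
    if len(ok) < 2:
        raise ValueError("need at least 2 converged replications")

    est = np.array([rec.estimates for rec in ok])
    se = np.array([rec.se for rec in ok])
    lo = np.array([rec.ci_low for rec in ok])
    hi = np.array([rec.ci_high for rec in ok])
    rej = np.array([rec.reject for rec in ok])

    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1)
    mean_se = se.mean(axis=0)
    abs_bias = mean - truth
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_bias = np.where(truth != 0, 100.0 * abs_bias / truth, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_se_bias = 100.0 * (mean_se - sd) / sd
    abs_se_bias = mean_se - sd
    rmse_vals = np.sqrt((mean - truth) ** 2 + est.var(axis=0, ddof=0))
    coverage = ((lo <= truth) & (truth <= hi)).mean(axis=0)
    rejection = rej.mean(axis=0)

    table = pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "truth": truth,
            "mean_estimate": mean,
            "rel_bias_pct": rel_bias,
            "abs_bias": abs_bias,
            "sd_estimates": sd,
            "mean_se": mean_se,
            "rel_se_bias_pct": rel_se_bias,
            "abs_se_bias": abs_se_bias,
            "rmse": rmse_vals,
            "coverage": coverage,
            "rejection_rate": rejection,
        }
    )
    rec0 = ok[0]
    return ConditionSummary(
        condition_id=rec0.condition_id,
        strategy=rec0.strategy,
        table=table,
        n_total=len(records),
        n_converged=len(ok),
    )
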