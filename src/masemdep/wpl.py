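"""Wilson-Polanin-Lipsey Stage 1: three-level meta-regression on cell dummies.

All effect records enter unreduced.  The model regresses the observed
correlations on six cell dummies with no intercept, adds a random intercept
at the study level (variance sigma2_study) and at the effect-within-study
level (variance sigma2_effect), both shared across cells, and treats the
per-effect sampling variances v_ij = (1 - r^2)^2 / (n - 1) as known.  The
marginal covariance of study j is therefore

    M_j = diag(v_j + sigma2_effect) + sigma2_study * 1 1',

a diagonal-plus-rank-one matrix, which makes the REML criterion cheap via the
Sherman-Morrison identity.  Fixed effects use the sample-size weighting the
approach prescribes: gamma = (X'WX)^{-1} X'W r with W = diag(n), and the
covariance of gamma is the sandwich (X'WX)^{-1} X'W M W X (X'WX)^{-1}
evaluated at the REML variance components.  ``weighting="inverse_variance"``
replaces W by M^{-1}, in which case gamma is the GLS estimate and the
sandwich collapses to (X'M^{-1}X)^{-1}.

Stage 2 is shared with the TSSEM module: the gamma vector and its covariance
play the role of the pooled correlations and the WLS weight matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .population_model import CELLS
from .simulate import MetaDataset
from .strategies import sampling_variance
from .tssem import STATUS_FAILED, STATUS_OK, STATUS_RETRIED, Stage1Result


@dataclass
class WplStage1Result:
    gamma: np.ndarray           # 6-vector of synthesized cell correlations
    acov: np.ndarray            # 6x6 covariance of gamma
    sigma2_study: float
    sigma2_effect: float
    status: int
    n_restarts: int = 0

    @property
    def converged(self) -> bool:
        return self.status < STATUS_FAILED

    def as_stage1(self) -> Stage1Result:
        """Adapter so the shared Stage-2 WLS fit can consume the result."""
        return Stage1Result(pooled=self.gamma, acov=self.acov, tau2=None,
                            status=self.status, n_restarts=self.n_restarts)


class _WplProblem:
    def __init__(self, records):
        df = records.sort_values(["study", "cell", "effect"], kind="stable")
        self.r = df["r"].to_numpy(dtype=float)
        self.n = df["n"].to_numpy(dtype=float)
        self.v = sampling_variance(self.r, self.n)
        cell_codes = {c: i for i, c in enumerate(CELLS)}
        self.cell = df["cell"].map(cell_codes).to_numpy(dtype=int)
        study_ids, self.study = np.unique(df["study"].to_numpy(), return_inverse=True)
        self.J = len(study_ids)
        counts = np.bincount(self.cell, minlength=6)
        if np.any(counts == 0):
            missing = [CELLS[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"cells observed in no study: {missing}")

    def neg2reml(self, s3: float, s2: float):
        """-2 restricted log-likelihood (constants dropped) plus the GLS
        pieces at the current variance components."""
        d = self.v + s2
        wd = 1.0 / d
        sw = np.bincount(self.study, weights=wd, minlength=self.J)
        c = s3 / (1.0 + s3 * sw)
        logdetM = np.log(d).sum() + np.log1p(s3 * sw).sum()

        # per-study, per-cell sums of 1/d and r/d
        T = np.zeros((self.J, 6))
        Tr = np.zeros((self.J, 6))
        np.add.at(T, (self.study, self.cell), wd)
        np.add.at(Tr, (self.study, self.cell), wd * self.r)
        XtMX = np.diag(np.bincount(self.cell, weights=wd, minlength=6))
        XtMX -= np.einsum("j,jc,jd->cd", c, T, T)
        swr = np.bincount(self.study, weights=wd * self.r, minlength=self.J)
        XtMr = np.bincount(self.cell, weights=wd * self.r, minlength=6)
        XtMr -= T.T @ (c * swr)
        beta = np.linalg.solve(XtMX, XtMr)

        e = self.r - beta[self.cell]
        swe = np.bincount(self.study, weights=wd * e, minlength=self.J)
        quad = float((wd * e * e).sum() - (c * swe**2).sum())
        sign, logdetX = np.linalg.slogdet(XtMX)
        if sign <= 0:
            return np.inf, beta, XtMX
        return logdetM + logdetX + quad, beta, XtMX

    def sandwich(self, s3: float, s2: float):
        """Sample-size-weighted fixed effects and their sandwich covariance."""
        w = self.n
        bread = np.bincount(self.cell, weights=w, minlength=6)
        gamma = np.bincount(self.cell, weights=w * self.r, minlength=6) / bread
        d = self.v + s2
        meat = np.diag(np.bincount(self.cell, weights=w * w * d, minlength=6))
        Q = np.zeros((self.J, 6))
        np.add.at(Q, (self.study, self.cell), w)
        meat += s3 * Q.T @ Q
        acov = meat / bread[:, None] / bread[None, :]
        return gamma, acov


def wpl_stage1_fit(
    data: MetaDataset,
    weighting: str = "sample_size",
    max_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> WplStage1Result:
    """Fit the three-level no-intercept meta-regression; REML for the two
    shared variance components, then fixed effects under the requested
    weighting ("sample_size", the approach's prescription, or
    "inverse_variance" for the model-implied GLS weights)."""
    if weighting not in ("sample_size", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    prob = _WplProblem(data.records)
    if rng is None:
        rng = np.random.default_rng(0)

    def objective(x):
        val, _, _ = prob.neg2reml(x[0], x[1])
        return val

    bounds = [(0.0, 1.0)] * 2
    start = np.array([0.01, 0.01])
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(objective, start, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-13})
        if res.success and np.isfinite(res.fun):
            best = (res, attempt)
            break
        start = np.abs(0.01 + rng.normal(0.0, 0.05, size=2))
    if best is None:
        nan6 = np.full(6, np.nan)
        return WplStage1Result(nan6, np.full((6, 6), np.nan), np.nan, np.nan,
                               status=STATUS_FAILED, n_restarts=max_restarts)
    res, attempt = best
    s3, s2 = np.maximum(res.x, 0.0)

    if weighting == "sample_size":
        gamma, acov = prob.sandwich(s3, s2)
    else:
        _, gamma, XtMX = prob.neg2reml(s3, s2)
        acov = np.linalg.inv(XtMX)
    return WplStage1Result(
        gamma=gamma,
        acov=acov,
        sigma2_study=float(s3),
        sigma2_effect=float(s2),
        status=STATUS_OK if attempt == 0 else STATUS_RETRIED,
        n_restarts=attempt,
    )
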