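"""Two-stage structural equation modeling on pooled correlations.

Stage 1 is a multivariate random-effects meta-analysis of the (possibly
incomplete) per-study correlation vectors: r_j ~ N(rho, T^2 + V_j) with
diagonal between-study covariance T^2 and known within-study sampling
covariance V_j from the Olkin-Siotani large-sample forms.  The likelihood is
maximized by profiling rho out via generalized least squares and optimizing
the six tau^2 elements under box constraints, with an analytic profile
gradient.  Stage 2 fits the partial-mediation path model to the pooled
correlation vector by weighted least squares, F(theta) =
(r - r_model(theta))' A^{-1} (r - r_model(theta)), where A is the asymptotic
covariance of the pooled correlations from Stage 1.

The path model is just identified (six free parameters, six correlations), so
F is ~0 at the solution and model fit is not assessed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .population_model import (
    CELLS,
    CELL_PAIRS,
    InvalidModelError,
    olkin_siotani_entry,
)
from .strategies import ReducedDataset

Z_CRIT = 1.959963984540054  # two-sided 5% normal quantile

STATUS_OK = 0
STATUS_RETRIED = 1
STATUS_FAILED = 2


class UnidentifiableError(ValueError):
    """A correlation cell is observed in no study."""


@dataclass
class Stage1Result:
    pooled: np.ndarray          # 6-vector, canonical cell order
    acov: np.ndarray            # 6x6 asymptotic covariance of the pooled vector
    tau2: np.ndarray | None     # 6-vector of between-study variances
    status: int
    n_restarts: int = 0

    @property
    def converged(self) -> bool:
        return self.status < STATUS_FAILED


@dataclass
class Stage2Result:
    estimates: np.ndarray       # (b_x_m1, b_x_m2, b_m1_y, b_m2_y, b_x_y, psi_m1_m2)
    se: np.ndarray
    z: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    fmin: float
    status: int
    n_restarts: int = 0

    @property
    def converged(self) -> bool:
        return self.status < STATUS_FAILED


def cells_to_matrix(r6: Sequence[float]) -> np.ndarray:
    """6-vector in canonical cell order -> 4x4 correlation matrix (X,M1,M2,Y)."""
    R = np.eye(4)
    for val, (i, j) in zip(r6, CELL_PAIRS):
        R[i, j] = R[j, i] = val
    return R


def matrix_to_cells(R: np.ndarray) -> np.ndarray:
    return np.array([R[i, j] for i, j in CELL_PAIRS])


def sampling_cov(
    r6: Sequence[float], n: int, cells: Sequence[int] | None = None
) -> np.ndarray:
    """Asymptotic covariance of a study's observed correlations.

    ``r6`` is the study's full 6-vector of correlations (missing cells filled
    with a consistent value, e.g. first-pass pooled means); ``cells`` selects
    the observed cell indices.  Olkin-Siotani entries divided by n - 1.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    R = cells_to_matrix(r6)
    idx = list(range(6)) if cells is None else list(cells)
    m = len(idx)
    V = np.empty((m, m))
    for a, ca in enumerate(idx):
        i, j = CELL_PAIRS[ca]
        for b, cb in enumerate(idx[: a + 1]):
            k, l = CELL_PAIRS[cb]
            V[a, b] = V[b, a] = olkin_siotani_entry(R, i, j, k, l)
    return V / (n - 1.0)


def _os_cov_batch(R6: np.ndarray, cells: Sequence[int]) -> np.ndarray:
    """Olkin-Siotani covariance (n-free) for a batch of studies sharing one
    observation pattern.  R6: (m, 6) full correlation vectors."""
    m = R6.shape[0]
    R = np.empty((m, 4, 4))
    R[:, np.arange(4), np.arange(4)] = 1.0
    for c, (i, j) in enumerate(CELL_PAIRS):
        R[:, i, j] = R[:, j, i] = R6[:, c]
    q = len(cells)
    V = np.empty((m, q, q))
    for a, ca in enumerate(cells):
        i, j = CELL_PAIRS[ca]
        for b in range(a + 1):
            k, l = CELL_PAIRS[cells[b]]
            rij, rkl = R[:, i, j], R[:, k, l]
            rik, ril = R[:, i, k], R[:, i, l]
            rjk, rjl = R[:, j, k], R[:, j, l]
            ent = (
                0.5 * rij * rkl * (rik**2 + ril**2 + rjk**2 + rjl**2)
                + rik * rjl + ril * rjk
                - (rij * rik * ril + rij * rjk * rjl
                   + rkl * rik * rjk + rkl * ril * rjl)
            )
            V[:, a, b] = V[:, b, a] = ent
    return V


class _Stage1Problem:
    """Pattern-grouped likelihood pieces for the multivariate meta-analysis."""

    def __init__(self, table):
        table = table.reindex(columns=["n", *CELLS])
        R = table[list(CELLS)].to_numpy(dtype=float)
        n = table["n"].to_numpy(dtype=float)
        obs = ~np.isnan(R)
        observed_per_cell = obs.sum(axis=0)
        if np.any(observed_per_cell == 0):
            missing = [CELLS[i] for i in np.flatnonzero(observed_per_cell == 0)]
            raise UnidentifiableError(f"cells observed in no study: {missing}")
        self.cell_means = np.nanmean(R, axis=0)
        Rfill = np.where(obs, R, self.cell_means)

        self.groups = []
        patterns = {}
        for j in range(R.shape[0]):
            key = tuple(np.flatnonzero(obs[j]))
            patterns.setdefault(key, []).append(j)
        for key, rows in patterns.items():
            idx = np.array(key, dtype=int)
            rows = np.array(rows, dtype=int)
            V = _os_cov_batch(Rfill[rows], key) / (n[rows, None, None] - 1.0)
            r = R[np.ix_(rows, idx)]
            self.groups.append((idx, V, r))

    def nll_grad(self, tau2: np.ndarray):
        """Profile negative log-likelihood in tau^2 (rho profiled by GLS) and
        its analytic gradient; also returns the GLS rho and information."""
        G = np.zeros((6, 6))
        h = np.zeros(6)
        pieces = []
        for idx, V, r in self.groups:
            S = V + np.diag(tau2[idx])[None, :, :]
            try:
                chol = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(6), None, None
            logdet = 2.0 * np.log(np.einsum("mii->mi", chol)).sum()
            Sinv = np.linalg.inv(S)
            G[np.ix_(idx, idx)] += Sinv.sum(axis=0)
            h[idx] += np.einsum("mij,mj->i", Sinv, r)
            pieces.append((idx, Sinv, r, logdet))
        rho = np.linalg.solve(G, h)
        nll = 0.0
        grad = np.zeros(6)
        for idx, Sinv, r, logdet in pieces:
            e = r - rho[idx]
            u = np.einsum("mij,mj->mi", Sinv, e)
            nll += 0.5 * (logdet + np.einsum("mi,mi->", e, u))
            diag = np.einsum("mii->mi", Sinv)
            np.add.at(grad, idx, 0.5 * (diag - u**2).sum(axis=0))
        return nll, grad, rho, G


def stage1_fit(
    data: ReducedDataset,
    fix_tau2: Sequence[float] | None = None,
    max_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> Stage1Result:
    """Random-effects multivariate ML pooling of incomplete correlation
    vectors; returns the pooled 6-vector, its asymptotic covariance
    A = (sum_j X_j'(T^2+V_j)^{-1}X_j)^{-1}, and the tau^2 estimates."""
    prob = _Stage1Problem(data.table)

    if fix_tau2 is not None:
        tau2 = np.asarray(fix_tau2, dtype=float)
        _, _, rho, G = prob.nll_grad(tau2)
        return Stage1Result(pooled=rho, acov=np.linalg.inv(G), tau2=tau2,
                            status=STATUS_OK)

    if rng is None:
        rng = np.random.default_rng(0)
    bounds = [(0.0, 1.0)] * 6
    start = np.full(6, 0.01)
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            lambda t: prob.nll_grad(t)[:2],
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res.success and np.isfinite(res.fun):
            best = (res, attempt)
            break
        start = np.abs(0.01 + rng.normal(0.0, 0.05, size=6))
    if best is None:
        means = prob.cell_means
        return Stage1Result(
            pooled=means, acov=np.full((6, 6), np.nan), tau2=None,
            status=STATUS_FAILED, n_restarts=max_restarts,
        )
    res, attempt = best
    tau2 = np.maximum(res.x, 0.0)
    _, _, rho, G = prob.nll_grad(tau2)
    return Stage1Result(
        pooled=rho,
        acov=np.linalg.inv(G),
        tau2=tau2,
        status=STATUS_OK if attempt == 0 else STATUS_RETRIED,
        n_restarts=attempt,
    )


# ---------------------------------------------------------------------------
# Stage 2: WLS path model
# ---------------------------------------------------------------------------

def implied_cell_correlations(theta: Sequence[float], validate: bool = True) -> np.ndarray:
    """Implied correlations of the 4-variable partial-mediation model.

    theta = (b_x_m1, b_x_m2, b_m1_y, b_m2_y, b_x_y, psi_m1_m2); all variables
    are scaled to unit variance, so psi_m1_m2 is the residual covariance of
    the mediators and the Y residual variance is fixed by the unit-variance
    constraint.
    """
    b1, b2, b3, b4, b5, psi = np.asarray(theta, dtype=float)
    r_xm1 = b1
    r_xm2 = b2
    r_m1m2 = b1 * b2 + psi
    r_xy = b5 + b3 * r_xm1 + b4 * r_xm2
    r_m1y = b3 + b4 * r_m1m2 + b5 * r_xm1
    r_m2y = b4 + b3 * r_m1m2 + b5 * r_xm2
    if validate:
        for name, b in (("M1", b1), ("M2", b2)):
            if 1.0 - b * b <= 0:
                raise InvalidModelError(f"non-positive residual variance for {name}")
        S = np.array([[1, r_xm1, r_xm2], [r_xm1, 1, r_m1m2], [r_xm2, r_m1m2, 1]])
        w = np.array([b5, b3, b4])
        if 1.0 - w @ S @ w <= 0:
            raise InvalidModelError("non-positive residual variance for Y")
    return np.array([r_xm1, r_xm2, r_xy, r_m1m2, r_m1y, r_m2y])


def implied_jacobian(theta: Sequence[float]) -> np.ndarray:
    """d r_model / d theta, rows in canonical cell order."""
    b1, b2, b3, b4, b5, psi = np.asarray(theta, dtype=float)
    r4 = b1 * b2 + psi
    return np.array(
        [
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [b3, b4, b1, b2, 1, 0],
            [b2, b1, 0, 0, 0, 1],
            [b4 * b2 + b5, b4 * b1, 1, r4, b1, b4],
            [b3 * b2, b3 * b1 + b5, r4, 1, b2, b3],
        ]
    )


def _weight_cholesky(acov: np.ndarray) -> np.ndarray:
    """Cholesky factor L with L L' = A^{-1}; ridge fallback for ill-
    conditioned A."""
    A = np.asarray(acov, dtype=float)
    for ridge in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            W = np.linalg.inv(A + ridge * np.eye(6))
            return np.linalg.cholesky((W + W.T) / 2.0)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("stage-1 asymptotic covariance not invertible")


_STAGE2_START = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.05])


def stage2_fit(
    stage1: Stage1Result,
    max_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> Stage2Result:
    """WLS fit of the path model to the pooled correlations, weighted by the
    inverse Stage-1 asymptotic covariance; Wald standard errors from
    (J' A^{-1} J)^{-1}."""
    nan6 = np.full(6, np.nan)
    if not stage1.converged or not np.all(np.isfinite(stage1.acov)):
        return Stage2Result(nan6, nan6, nan6, nan6, nan6, np.nan,
                            status=STATUS_FAILED)
    r = np.asarray(stage1.pooled, dtype=float)
    L = _weight_cholesky(stage1.acov)

    def resid(th):
        return L.T @ (r - implied_cell_correlations(th, validate=False))

    def jac(th):
        return -L.T @ implied_jacobian(th)

    if rng is None:
        rng = np.random.default_rng(0)
    start = _STAGE2_START.copy()
    sol = None
    for attempt in range(max_restarts + 1):
        res = optimize.least_squares(resid, start, jac=jac, method="lm",
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        fmin = float(2.0 * res.cost)
        if res.success and np.all(np.abs(res.x[:5]) < 1.0) and fmin < 1e-6:
            sol = (res, fmin, attempt)
            break
        start = _STAGE2_START + rng.normal(0.0, 0.05, size=6)
    if sol is None:
        return Stage2Result(nan6, nan6, nan6, nan6, nan6, np.nan,
                            status=STATUS_FAILED, n_restarts=max_restarts)
    res, fmin, attempt = sol
    theta = res.x
    J = implied_jacobian(theta)
    W = L @ L.T
    cov = np.linalg.inv(J.T @ W @ J)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, 0.0)
    return Stage2Result(
        estimates=theta,
        se=se,
        z=z,
        ci_low=theta - Z_CRIT * se,
        ci_high=theta + Z_CRIT * se,
        fmin=fmin,
        status=STATUS_OK if attempt == 0 else STATUS_RETRIED,
        n_restarts=attempt,
    )


def pseudo_true_paths(condition) -> np.ndarray:
    """Population values of the Stage-2 parameters for a design condition.

    The fitted 4-variable model sees Y through its indicators, so the
    Y-path coefficients it consistently estimates are the ones implied by
    the collapsed average population correlation matrix: attenuated by the
    mean loading (e.g. 0.7 * 0.2 = 0.14 at loadings 0.70), with a zero X->Y
    path staying exactly zero.  These are the values bias, coverage and
    rejection rates are judged against.
    """
    from .population_model import collapsed_population_cells

    return solve_paths_from_correlations(
        collapsed_population_cells(condition.implied_matrix())
    )


def solve_paths_from_correlations(r6: Sequence[float]) -> np.ndarray:
    """Closed-form path solution on a 4-variable correlation matrix: the model
    is just identified, so the paths are the regression coefficients of M1/M2
    on X and of Y on (X, M1, M2), with psi the residual mediator covariance.

    Kept as a public convenience; the WLS route in :func:`stage2_fit` must
    agree with it to optimizer precision.
    """
    R = cells_to_matrix(r6)
    b1, b2 = R[0, 1], R[0, 2]
    psi = R[1, 2] - b1 * b2
    Sxx = R[:3, :3]
    sxy = R[:3, 3]
    bx, bm1, bm2 = np.linalg.solve(Sxx, sxy)
    return np.array([b1, b2, bm1, bm2, bx, psi])
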