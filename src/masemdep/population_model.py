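"""Data-generating population model and simulation condition grid.

The population model is a partial-mediation path model with an exogenous
predictor X, two correlated mediators M1 and M2, and an outcome Y.  To induce
*dependent* effect sizes -- several reported correlations for the same cell of
the 4-variable correlation matrix -- Y is treated as a latent construct
measured by ``p`` indicators ``I1..Ip`` with loadings ``lambda_i``.  Every
correlation between an indicator and X/M1/M2 is then one version of the
corresponding Y-cell correlation, exactly as when a primary study reports the
same relationship for several instruments or time points.

All variables are scaled to unit variance, so the model-implied moment matrix
is a correlation matrix and the implied 6x6 (p=3) or 12x12 (p=9) matrix can be
fed directly to meta-analytic pooling.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical order of the structural variables
STRUCTURAL_VARS = ("X", "M1", "M2")

#: canonical order of the six cells of the 4-variable (X, M1, M2, Y) model
CELLS = ("x_m1", "x_m2", "x_y", "m1_m2", "m1_y", "m2_y")

#: cells that involve the outcome Y (the dependent cells), keyed by anchor
Y_CELLS = {"X": "x_y", "M1": "m1_y", "M2": "m2_y"}

#: variable-index pairs (into the order X=0, M1=1, M2=2, Y=3) for each cell
CELL_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

DISPARITY_OFFSETS = {"exchangeable": 0.0, "small": 0.10, "large": 0.20}


class InvalidModelError(ValueError):
    """Raised when a parameterization implies a non-positive residual variance."""


@dataclass(frozen=True)
class PathCoefficients:
    """Standardized structural paths of the partial-mediation model.

    ``rho_m1_m2`` is the implied *total* correlation between the mediators;
    the residual covariance between them is ``rho_m1_m2 - b_x_m1 * b_x_m2``.
    """

    b_x_m1: float = 0.20
    b_x_m2: float = 0.20
    b_m1_y: float = 0.20
    b_m2_y: float = 0.20
    b_x_y: float = 0.20
    rho_m1_m2: float = 0.20

    def __post_init__(self) -> None:
        for name in ("b_x_m1", "b_x_m2", "b_m1_y", "b_m2_y", "b_x_y", "rho_m1_m2"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise InvalidModelError(f"{name}={v} outside (-1, 1)")

    @property
    def psi_m1_m2(self) -> float:
        """Residual covariance between the mediators."""
        return self.rho_m1_m2 - self.b_x_m1 * self.b_x_m2

    def to_vector(self) -> np.ndarray:
        """Parameter vector in the order used by the Stage-2 path model."""
        return np.array(
            [self.b_x_m1, self.b_x_m2, self.b_m1_y, self.b_m2_y, self.b_x_y,
             self.psi_m1_m2]
        )


@dataclass(frozen=True)
class LoadingSpec:
    """Factor-loading pattern for the indicators of the latent outcome.

    ``base`` is the mean loading; ``disparity`` selects the pattern
    [l, l, l], [l-0.10, l, l+0.10] or [l-0.20, l, l+0.20]; for ``p`` a
    multiple of 3 the 3-value pattern is repeated.
    """

    base: float
    disparity: str = "exchangeable"
    p: int = 3

    def __post_init__(self) -> None:
        if self.disparity not in DISPARITY_OFFSETS:
            raise ValueError(f"unknown disparity {self.disparity!r}")
        if self.p < 3 or self.p % 3:
            raise ValueError("p must be a positive multiple of 3")
        lam = self.loadings()
        if np.any(lam <= 0) or np.any(lam >= 1):
            raise InvalidModelError(f"loadings {lam} not all in (0, 1)")

    def loadings(self) -> np.ndarray:
        off = DISPARITY_OFFSETS[self.disparity]
        pattern = self.base + off * np.array([-1.0, 0.0, 1.0])
        return np.tile(pattern, self.p // 3)


@dataclass(frozen=True)
class ImpliedMatrix:
    """A labelled correlation matrix in the order (X, M1, M2, I1..Ip)."""

    variables: tuple[str, ...]
    values: np.ndarray

    @property
    def p(self) -> int:
        return len(self.variables) - 3

    def index(self, var: str) -> int:
        return self.variables.index(var)


def build_implied_matrix(
    paths: PathCoefficients, loadings: LoadingSpec | Sequence[float]
) -> ImpliedMatrix:
    """Model-implied correlation matrix of X, M1, M2 and the indicators.

    The structural outcome eta = b_x_y*X + b_m1_y*M1 + b_m2_y*M2 + e is scaled
    to unit variance, and indicator i = lambda_i * eta + eps_i with residual
    variance 1 - lambda_i^2, so every variable has unit variance.
    """
    if isinstance(loadings, LoadingSpec):
        lam = loadings.loadings()
    else:
        lam = np.asarray(loadings, dtype=float)
    if np.any(lam < 0) or np.any(lam >= 1):
        bad = lam[(lam < 0) | (lam >= 1)][0]
        raise InvalidModelError(
            f"indicator loading {bad} gives non-positive residual variance"
        )

    S = np.array(
        [
            [1.0, paths.b_x_m1, paths.b_x_m2],
            [paths.b_x_m1, 1.0, paths.rho_m1_m2],
            [paths.b_x_m2, paths.rho_m1_m2, 1.0],
        ]
    )
    for name, b in (("M1", paths.b_x_m1), ("M2", paths.b_x_m2)):
        if 1.0 - b * b <= 0:
            raise InvalidModelError(f"non-positive residual variance for {name}")
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise InvalidModelError("structural block (X, M1, M2) not positive definite")

    w = np.array([paths.b_x_y, paths.b_m1_y, paths.b_m2_y])
    explained = float(w @ S @ w)
    if 1.0 - explained <= 0:
        raise InvalidModelError(
            f"non-positive residual variance for the latent outcome "
            f"(explained variance {explained:.3f})"
        )
    c = S @ w  # correlations of (X, M1, M2) with the unit-variance eta

    p = len(lam)
    d = 3 + p
    R = np.eye(d)
    R[:3, :3] = S
    R[:3, 3:] = np.outer(c, lam)
    R[3:, :3] = R[:3, 3:].T
    R[3:, 3:] = np.outer(lam, lam)
    np.fill_diagonal(R[3:, 3:], 1.0)

    variables = STRUCTURAL_VARS + tuple(f"I{i + 1}" for i in range(p))
    return ImpliedMatrix(variables=variables, values=R)


# ---------------------------------------------------------------------------
# large-sample (co)variances of Pearson correlations (Olkin-Siotani forms)
# ---------------------------------------------------------------------------

def olkin_siotani_entry(R: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """n * asymptotic cov between r_ij and r_kl under population matrix R."""
    rij, rkl = R[i, j], R[k, l]
    rik, ril, rjk, rjl = R[i, k], R[i, l], R[j, k], R[j, l]
    return (
        0.5 * rij * rkl * (rik**2 + ril**2 + rjk**2 + rjl**2)
        + rik * rjl
        + ril * rjk
        - (rij * rik * ril + rij * rjk * rjl + rkl * rik * rjk + rkl * ril * rjl)
    )


def effect_sampling_correlation(
    implied: ImpliedMatrix,
    anchor: str,
    ind_a: str,
    ind_b: str,
    n: int | None = None,
) -> float:
    """Large-sample correlation between the sampling errors of two dependent
    effect sizes r(anchor, ind_a) and r(anchor, ind_b).

    The two correlations share the anchor variable, so their sampling errors
    covary; the ratio of the Olkin-Siotani covariance to the product of the
    asymptotic standard deviations is free of ``n`` (the sample size cancels),
    which is why ``n`` is accepted but unused.
    """
    if anchor not in STRUCTURAL_VARS:
        raise ValueError(f"anchor must be one of {STRUCTURAL_VARS}, got {anchor!r}")
    R = implied.values
    a = implied.index(anchor)
    i = implied.index(ind_a)
    j = implied.index(ind_b)
    if i == j:
        return 1.0
    cov = olkin_siotani_entry(R, a, i, a, j)
    va = olkin_siotani_entry(R, a, i, a, i)
    vb = olkin_siotani_entry(R, a, j, a, j)
    return float(cov / np.sqrt(va * vb))


def dependency_correlations(implied: ImpliedMatrix) -> pd.DataFrame:
    """All pairwise dependency correlations, one row per (anchor, pair)."""
    rows = []
    p = implied.p
    for anchor in STRUCTURAL_VARS:
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "anchor": anchor,
                        "ind_a": f"I{i + 1}",
                        "ind_b": f"I{j + 1}",
                        "correlation": effect_sampling_correlation(
                            implied, anchor, f"I{i + 1}", f"I{j + 1}"
                        ),
                    }
                )
    return pd.DataFrame(rows)


def collapsed_population_cells(implied: ImpliedMatrix) -> np.ndarray:
    """Average population correlations at the level of the six reported cells.

    Merging the indicators into the single outcome Y makes each Y-cell
    correlation the average of the anchor-indicator correlations (every
    indicator subset of a given size is retained with equal probability, so
    the expectation over the reporting design is the plain mean).  This is
    the population the pooling strategies that average or sample symmetrically
    actually estimate -- attenuated relative to the latent-outcome cells by
    the mean loading.
    """
    R = implied.values
    return np.array(
        [
            R[0, 1],
            R[0, 2],
            R[0, 3:].mean(),
            R[1, 2],
            R[1, 3:].mean(),
            R[2, 3:].mean(),
        ]
    )


# ---------------------------------------------------------------------------
# condition grid
# ---------------------------------------------------------------------------

P_LEVELS = (3, 9)
LAMBDA_LEVELS = (0.30, 0.70)
DISPARITY_LEVELS = ("exchangeable", "small", "large")
K_LEVELS = (20, 60, 100)
TAU2_LEVELS = ("equal", "unequal")
B_X_Y_LEVELS = (0.0, 0.2)


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design."""

    loading_spec: LoadingSpec
    k_studies: int
    tau2_structure: str
    b_x_y: float

    @property
    def id(self) -> str:
        ls = self.loading_spec
        return (
            f"p{ls.p}-l{int(round(ls.base * 100)):02d}-{ls.disparity}"
            f"-k{self.k_studies}-t{self.tau2_structure}"
            f"-b{int(round(self.b_x_y * 10))}"
        )

    def paths(self) -> PathCoefficients:
        return PathCoefficients(b_x_y=self.b_x_y)

    def implied_matrix(self) -> ImpliedMatrix:
        return build_implied_matrix(self.paths(), self.loading_spec)


def make_condition_grid(
    p: Iterable[int] = P_LEVELS,
    base: Iterable[float] = LAMBDA_LEVELS,
    disparity: Iterable[str] = DISPARITY_LEVELS,
    k_studies: Iterable[int] = K_LEVELS,
    tau2_structure: Iterable[str] = TAU2_LEVELS,
    b_x_y: Iterable[float] = B_X_Y_LEVELS,
) -> list[Condition]:
    """Full factorial design in the canonical order
    (p, base loading, disparity, k, tau2 structure, b_x_y); 144 cells at the
    default levels.
    """
    grid = []
    for pv, lv, dv, kv, tv, bv in itertools.product(
        p, base, disparity, k_studies, tau2_structure, b_x_y
    ):
        grid.append(
            Condition(
                loading_spec=LoadingSpec(base=lv, disparity=dv, p=pv),
                k_studies=kv,
                tau2_structure=tv,
                b_x_y=bv,
            )
        )
    return grid


def grid_to_frame(conditions: Sequence[Condition]) -> pd.DataFrame:
    """One row per condition, columns for every design factor plus the id."""
    return pd.DataFrame(
        {
            "id": [c.id for c in conditions],
            "p": [c.loading_spec.p for c in conditions],
            "lambda": [c.loading_spec.base for c in conditions],
            "disparity": [c.loading_spec.disparity for c in conditions],
            "k_studies": [c.k_studies for c in conditions],
            "tau2_structure": [c.tau2_structure for c in conditions],
            "b_x_y": [c.b_x_y for c in conditions],
        }
    )


def condition_by_id(cond_id: str) -> Condition:
    for c in make_condition_grid():
        if c.id == cond_id:
            return c
    raise KeyError(f"no condition with id {cond_id!r}")
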