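"""Meta-analytic dataset generator with dependent effect sizes.

One replication produces ``k`` studies.  For each study a population
correlation matrix is drawn around the model-implied matrix (random effects
with diagonal between-study covariance), a sample correlation matrix is
computed from multivariate-normal data, and the indicator columns are
collapsed into multiple records for the three Y-cells.  A fixed share of the
studies (70%) reports more than one effect size per Y-cell, and 15% of the
records in the non-Y cells are deleted to emulate incompletely reported
correlation matrices.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population_model import CELLS, Condition, ImpliedMatrix

LOGNORMAL_MEAN_LOG = 5.13
LOGNORMAL_SD_LOG = 0.38
MIN_SAMPLE_SIZE = 10

DEPENDENT_SHARE = 0.70
NON_Y_DELETION_RATE = 0.15

NON_Y_CELLS = ("x_m1", "x_m2", "m1_m2")
Y_CELL_BY_ANCHOR = (("X", "x_y"), ("M1", "m1_y"), ("M2", "m2_y"))


class GenerationError(RuntimeError):
    """Raised when a positive-definite study matrix cannot be drawn."""


@dataclass(frozen=True)
class Tau2Spec:
    """Assignment of between-study variances to correlation-matrix elements.

    ``equal`` assigns ``base`` (0.01) to every off-diagonal element.
    ``unequal`` keeps ``base`` for all elements not involving the outcome and
    alternates ``base``/``elevated`` (0.01/0.03) over the indicators within
    each Y-cell, starting at ``base`` -- so each anchor sees a mix of both
    heterogeneity levels among its dependent effects.  Between-study
    covariances are always zero (diagonal T^2).
    """

    structure: str = "equal"
    base: float = 0.01
    elevated: float = 0.03

    def __post_init__(self) -> None:
        if self.structure not in ("equal", "unequal"):
            raise ValueError(f"unknown tau2 structure {self.structure!r}")
        if self.base < 0 or self.elevated < 0:
            raise ValueError("between-study variances must be >= 0")

    def element_variances(self, p: int) -> np.ndarray:
        """(3+p) x (3+p) symmetric matrix of element-wise variances (diag 0)."""
        d = 3 + p
        V = np.full((d, d), self.base)
        if self.structure == "unequal":
            for i in range(p):  # indicator i, columns 3+i, anchors rows 0..2
                v = self.elevated if i % 2 else self.base
                V[:3, 3 + i] = v
                V[3 + i, :3] = v
        np.fill_diagonal(V, 0.0)
        return V


@dataclass
class MetaDataset:
    """Long-format collection of correlation records.

    ``records`` has one row per reported correlation with columns
    ``study`` (int), ``effect`` (int, within study and cell), ``cell``
    (one of the six cell labels), ``r`` (Pearson correlation) and ``n``
    (study sample size, shared by all records of a study).
    """

    records: pd.DataFrame
    condition: Condition | None = None
    seed: int | None = None

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path, condition: Condition | None = None) -> "MetaDataset":
        df = pd.read_csv(path)
        missing = {"study", "effect", "cell", "r", "n"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns {sorted(missing)}")
        bad = set(df["cell"]) - set(CELLS)
        if bad:
            raise ValueError(f"unknown cell labels {sorted(bad)}")
        return MetaDataset(records=df, condition=condition)


def draw_sample_sizes(
    k: int,
    rng: np.random.Generator,
    mean_log: float = LOGNORMAL_MEAN_LOG,
    sd_log: float = LOGNORMAL_SD_LOG,
    floor: int = MIN_SAMPLE_SIZE,
) -> np.ndarray:
    """Per-study sample sizes: rounded lognormal draws with a floor.

    Defaults give a median study size of ~169 participants and a mean of
    ~182, the meta-analytic size distribution used throughout the design.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = np.rint(rng.lognormal(mean_log, sd_log, size=k)).astype(int)
    return np.maximum(n, floor)


def draw_study_population(
    implied: ImpliedMatrix,
    tau2: Tau2Spec | np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> ImpliedMatrix:
    """One study's population correlation matrix: the average matrix with
    independent normal perturbations on each unique off-diagonal element,
    redrawn until positive definite (rejection keeps the marginal element
    variances at their assigned T^2 apart from the rare rejections).
    """
    R = implied.values
    d = R.shape[0]
    V = tau2.element_variances(d - 3) if isinstance(tau2, Tau2Spec) else np.asarray(tau2)
    iu = np.triu_indices(d, 1)
    sd = np.sqrt(V[iu])
    for _ in range(max_tries):
        P = R.copy()
        pert = rng.normal(0.0, 1.0, size=len(sd)) * sd
        P[iu] = R[iu] + pert
        P.T[iu] = P[iu]
        if np.all(np.abs(P[iu]) < 1.0) and np.linalg.eigvalsh(P)[0] > 0:
            return ImpliedMatrix(variables=implied.variables, values=P)
    raise GenerationError(
        f"no positive-definite study matrix in {max_tries} tries "
        f"(dimension {d})"
    )


def sample_correlation_matrix(
    sigma: ImpliedMatrix | np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pearson correlation matrix of n multivariate-normal observations."""
    S = sigma.values if isinstance(sigma, ImpliedMatrix) else np.asarray(sigma)
    d = S.shape[0]
    if n < d + 1:
        raise ValueError(f"n={n} too small for a full-rank {d}-variable matrix")
    L = np.linalg.cholesky(S)
    X = rng.standard_normal((n, d)) @ L.T
    return np.corrcoef(X, rowvar=False)


def report_count_bins(p: int, k: int) -> list[object]:
    """Per-study report-count bin labels (unshuffled), exact up to rounding.

    p = 3: 30% of studies report 1 effect per Y-cell, 35% report 2, 35%
    report 3.  p = 9: 30% report 1, then seven 10% bins reporting
    {2 or 3}, 4, 5, 6, 7, 8, 9.  Counts are integer-exact via largest-
    remainder apportionment.
    """
    if p == 3:
        bins: list[tuple[object, float]] = [(1, 0.30), (2, 0.35), (3, 0.35)]
    elif p == 9:
        bins = [(1, 0.30), ("2or3", 0.10)] + [(m, 0.10) for m in range(4, 10)]
    else:
        raise ValueError(f"no dependency design for p={p}")
    raw = np.array([share * k for _, share in bins])
    counts = np.floor(raw).astype(int)
    rem = k - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for idx in order[:rem]:
        counts[idx] += 1
    labels: list[object] = []
    for (label, _), c in zip(bins, counts):
        labels.extend([label] * c)
    return labels


def generate_meta_dataset(condition: Condition, seed: int) -> MetaDataset:
    """One meta-analytic dataset for a design condition, reproducible from
    (condition, seed)."""
    rng = np.random.default_rng(seed)
    k = condition.k_studies
    p = condition.loading_spec.p
    implied = condition.implied_matrix()
    tau2 = Tau2Spec(structure=condition.tau2_structure)

    n_j = draw_sample_sizes(k, rng)
    bin_labels = report_count_bins(p, k)
    assignment = rng.permutation(k)  # study -> position in bin_labels

    studies, effects, cells, values, ns = [], [], [], [], []
    for j in range(k):
        pop = draw_study_population(implied, tau2, rng)
        samp = sample_correlation_matrix(pop, int(n_j[j]), rng)

        label = bin_labels[assignment[j]]
        m = int(rng.integers(2, 4)) if label == "2or3" else int(label)
        retained = np.sort(rng.choice(p, size=m, replace=False))

        # non-Y cells from the structural block
        for cell, (a, b) in zip(NON_Y_CELLS, ((0, 1), (0, 2), (1, 2))):
            studies.append(j)
            effects.append(1)
            cells.append(cell)
            values.append(samp[a, b])
            ns.append(int(n_j[j]))
        # dependent Y-cell records: anchor x retained indicators
        for a, (anchor, cell) in enumerate(Y_CELL_BY_ANCHOR):
            for e, idx in enumerate(retained, start=1):
                studies.append(j)
                effects.append(e)
                cells.append(cell)
                values.append(samp[a, 3 + idx])
                ns.append(int(n_j[j]))

    df = pd.DataFrame(
        {"study": studies, "effect": effects, "cell": cells, "r": values, "n": ns}
    )

    non_y = df.index[df["cell"].isin(NON_Y_CELLS)].to_numpy()
    n_del = int(round(NON_Y_DELETION_RATE * len(non_y)))
    if n_del:
        drop = rng.choice(non_y, size=n_del, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)

    return MetaDataset(records=df, condition=condition, seed=seed)
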