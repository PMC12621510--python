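"""Two-stage SEM: sampling covariances, Stage-1 ML pooling, Stage-2 WLS."""
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla

from masemdep import (
    LoadingSpec,
    PathCoefficients,
    apply_strategy,
    build_implied_matrix,
    collapsed_population_cells,
    condition_by_id,
    generate_meta_dataset,
    implied_cell_correlations,
    pseudo_true_paths,
    sampling_cov,
    solve_paths_from_correlations,
    stage1_fit,
    stage2_fit,
)
from masemdep.population_model import CELLS
from masemdep.strategies import ReducedDataset
from masemdep.tssem import Stage1Result, UnidentifiableError, cells_to_matrix


def _reduced_from_rows(rows):
    return ReducedDataset(table=pd.DataFrame(rows), strategy="simple_average")


class TestSamplingCov:
    def test_independence_gives_diagonal(self):
        V = sampling_cov(np.zeros(6), n=101)
        assert np.allclose(V, np.eye(6) / 100.0)

    def test_variance_entry_direct(self):
        r6 = np.array([0.5, 0, 0, 0, 0, 0])
        V = sampling_cov(r6, n=101)
        assert V[0, 0] == pytest.approx((1 - 0.25) ** 2 / 100)

    def test_subset_selection(self):
        r6 = np.array([0.2, 0.2, 0.28, 0.2, 0.28, 0.28])
        full = sampling_cov(r6, n=200)
        sub = sampling_cov(r6, n=200, cells=[2, 4, 5])
        assert np.allclose(sub, full[np.ix_([2, 4, 5], [2, 4, 5])])

    def test_monte_carlo_agreement(self, rng):
        theta = np.array([0.2, 0.25, 0.15, 0.3, 0.25, 0.1])
        R = cells_to_matrix(implied_cell_correlations(theta))
        n, reps = 150, 60_000
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((reps, n, 4)) @ L.T
        Xc = X - X.mean(axis=1, keepdims=True)
        C = np.einsum("sni,snj->sij", Xc, Xc)
        sd = np.sqrt(np.einsum("sii->si", C))
        corr = C / sd[:, :, None] / sd[:, None, :]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        rvals = np.stack([corr[:, i, j] for i, j in pairs], axis=1)
        mc = np.cov(rvals, rowvar=False) * (n - 1)
        analytic = sampling_cov(implied_cell_correlations(theta), n) * (n - 1)
        assert np.allclose(mc, analytic, rtol=0.05, atol=0.01)


class TestStage1:
    def test_single_study_fixed_tau2_reproduces_observations(self):
        obs = {c: v for c, v in zip(CELLS, [0.2, 0.1, 0.3, 0.25, 0.28, 0.22])}
        red = _reduced_from_rows([{"study": 0, "n": 150, **obs}])
        res = stage1_fit(red, fix_tau2=np.zeros(6))
        assert np.allclose(res.pooled, list(obs.values()), atol=1e-10)

    def test_two_equal_variance_studies_pool_to_midpoint(self):
        a = [0.2, 0.1, 0.3, 0.25, 0.28, 0.22]
        b = [0.1, 0.2, 0.2, 0.15, 0.18, 0.32]
        rows = [
            {"study": 0, "n": 200, **dict(zip(CELLS, a))},
            {"study": 1, "n": 200, **dict(zip(CELLS, b))},
        ]
        # force equal V by symmetrizing: same n; V depends on each study's r,
        # so fix tau2 and give both studies the same correlations magnitude
        red = _reduced_from_rows(rows)
        res = stage1_fit(red, fix_tau2=np.zeros(6))
        # equal-n studies with V from their own r are not exactly equal-V;
        # use the GLS closed form as the oracle instead
        from masemdep.tssem import _Stage1Problem

        prob = _Stage1Problem(red.table)
        _, _, rho, _ = prob.nll_grad(np.zeros(6))
        assert np.allclose(res.pooled, rho, atol=1e-12)
        G = np.zeros((6, 6))
        h = np.zeros(6)
        for row, vals in zip(rows, (a, b)):
            V = sampling_cov(vals, row["n"])
            Vi = np.linalg.inv(V)
            G += Vi
            h += Vi @ np.array(vals)
        assert np.allclose(res.pooled, np.linalg.solve(G, h), atol=1e-10)

    def test_identical_studies_pool_to_common_value(self):
        vals = np.array([0.2, 0.1, 0.3, 0.25, 0.28, 0.22])
        rows = [
            {"study": 0, "n": 300, **dict(zip(CELLS, vals))},
            {"study": 1, "n": 300, **dict(zip(CELLS, vals))},
        ]
        res = stage1_fit(_reduced_from_rows(rows), fix_tau2=np.zeros(6))
        assert np.allclose(res.pooled, vals, atol=1e-10)

    def test_homogeneous_recovery_and_information_rate(self, rng):
        theta = PathCoefficients().to_vector()
        truth = implied_cell_correlations(theta)
        R4 = cells_to_matrix(truth)
        L = np.linalg.cholesky(R4)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

        def make(k, n=500):
            rows = []
            for j in range(k):
                X = rng.standard_normal((n, 4)) @ L.T
                C = np.corrcoef(X, rowvar=False)
                rows.append(
                    {"study": j, "n": n, **{c: C[i, l] for c, (i, l) in zip(CELLS, pairs)}}
                )
            return _reduced_from_rows(rows)

        res = stage1_fit(make(150))
        se = np.sqrt(np.diag(res.acov))
        assert np.all(np.abs(res.pooled - truth) < 3 * se)
        assert np.all(res.tau2 < 0.002)
        res_small = stage1_fit(make(30))
        ratio = np.diag(res_small.acov) / np.diag(res.acov)
        assert np.all((ratio > 2.5) & (ratio < 10.0))  # ~k ratio of 5

    def test_unidentifiable_cell_raises(self):
        rows = [{"study": 0, "n": 100, "x_m1": 0.2}]
        with pytest.raises(UnidentifiableError):
            stage1_fit(_reduced_from_rows(rows))

    def test_matches_metafor_multivariate_ml(self, tmp_path):
        cond = condition_by_id("p3-l70-exchangeable-k20-tequal-b2")
        ds = generate_meta_dataset(cond, 99)
        red = apply_strategy(ds, "simple_average")
        res = stage1_fit(red)

        tab = red.table
        rows, blocks = [], []
        cell_means = tab[list(CELLS)].mean()
        for _, row in tab.iterrows():
            obs = [i for i, c in enumerate(CELLS) if not pd.isna(row[c])]
            r6 = np.array(
                [row[c] if not pd.isna(row[c]) else cell_means[c] for c in CELLS]
            )
            blocks.append(sampling_cov(r6, int(row["n"]), obs))
            for i in obs:
                rows.append({"study": int(row["study"]), "cell": CELLS[i], "r": row[CELLS[i]]})
        pd.DataFrame(rows).to_csv(tmp_path / "long.csv", index=False)
        np.savetxt(tmp_path / "V.csv", sla.block_diag(*blocks), delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            library(metafor)
            d <- read.csv("{tmp_path}/long.csv")
            V <- as.matrix(read.csv("{tmp_path}/V.csv", header=FALSE))
            d$cell <- factor(d$cell, levels=c({','.join(repr(c) for c in CELLS)}))
            fit <- rma.mv(r, V, mods=~cell-1, random=~cell|study, struct="DIAG",
                          data=d, method="ML", control=list(rel.tol=1e-10))
            write.csv(data.frame(pooled=coef(fit), tau2=fit$tau2),
                      "{tmp_path}/out.csv", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        assert np.allclose(res.pooled, ref["pooled"], atol=2e-4)
        assert np.allclose(res.tau2, ref["tau2"], atol=2e-4)


class TestImpliedModel:
    def test_null_model_implies_zero_correlations(self):
        assert np.allclose(implied_cell_correlations(np.zeros(6)), 0.0)

    def test_matches_collapsed_population_matrix(self):
        # the attenuated parameter vector reproduces the collapsed average
        # population correlations of the latent-indicator model
        for lam in (0.3, 0.7):
            imp = build_implied_matrix(PathCoefficients(), LoadingSpec(lam, "small", 9))
            cells = collapsed_population_cells(imp)
            theta = np.array([0.2, 0.2, lam * 0.2, lam * 0.2, lam * 0.2, 0.16])
            assert np.allclose(implied_cell_correlations(theta), cells, atol=1e-12)

    def test_round_trip_just_identified(self, rng):
        for _ in range(25):
            theta = np.concatenate([rng.uniform(-0.4, 0.4, 5), rng.uniform(-0.15, 0.3, 1)])
            r6 = implied_cell_correlations(theta, validate=False)
            if np.abs(r6).max() >= 0.95:
                continue
            assert np.allclose(solve_paths_from_correlations(r6), theta, atol=1e-10)


class TestStage2:
    @staticmethod
    def _stage1(pooled, acov=None):
        if acov is None:
            acov = 0.001 * np.eye(6)
        return Stage1Result(pooled=np.asarray(pooled), acov=acov, tau2=np.zeros(6), status=0)

    def test_population_input_recovers_paths_exactly(self):
        cond = condition_by_id("p3-l70-exchangeable-k20-tequal-b2")
        pooled = collapsed_population_cells(cond.implied_matrix())
        res = stage2_fit(self._stage1(pooled))
        assert res.fmin < 1e-10
        assert np.allclose(res.estimates, pseudo_true_paths(cond), atol=1e-7)

    def test_wls_oracle_equivalence_random_inputs(self, rng):
        # numeric WLS solution must match the closed-form path solution of
        # the just-identified model for arbitrary SPD weight matrices
        for _ in range(20):
            theta = np.concatenate([rng.uniform(-0.35, 0.35, 5), rng.uniform(-0.1, 0.25, 1)])
            pooled = implied_cell_correlations(theta, validate=False)
            A = rng.standard_normal((6, 6))
            A = 1e-3 * (A @ A.T + 6 * np.eye(6))
            res = stage2_fit(self._stage1(pooled, A))
            oracle = solve_paths_from_correlations(pooled)
            assert res.fmin < 1e-10
            assert np.allclose(res.estimates, oracle, atol=1e-6)

    def test_weight_scaling_homogeneity(self):
        pooled = implied_cell_correlations(PathCoefficients().to_vector())
        A = 1e-3 * np.eye(6)
        base = stage2_fit(self._stage1(pooled, A))
        scaled = stage2_fit(self._stage1(pooled, 4.0 * A))
        assert np.allclose(base.estimates, scaled.estimates, atol=1e-8)
        assert np.allclose(scaled.se, 2.0 * base.se, rtol=1e-6)

    def test_zero_population_path_gives_zero_wald(self):
        theta0 = PathCoefficients(b_x_y=0.0).to_vector()
        pooled = implied_cell_correlations(theta0)
        res = stage2_fit(self._stage1(pooled))
        assert res.estimates[4] == pytest.approx(0.0, abs=1e-8)
        assert abs(res.z[4]) < 1e-6
        assert res.ci_low[4] < 0 < res.ci_high[4]

    def test_failed_stage1_propagates(self):
        bad = Stage1Result(pooled=np.full(6, np.nan), acov=np.full((6, 6), np.nan),
                           tau2=None, status=2)
        res = stage2_fit(bad)
        assert not res.converged
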