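"""Core model machinery: designs, marginal covariance, likelihood, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag
from scipy.stats import multivariate_normal

from methodcompare import (
    MeasurementTable,
    MethodComparisonModel,
    MethodComparisonResults,
    ModelSpec,
    build_subject_designs,
    cov_param_count,
    marginal_covariance,
    minus2_loglik,
    null_model_lrt_df,
    overall_block,
    profile_means,
)
from methodcompare.model import SubjectDesign

from conftest import random_small_table, random_spd


def _table(rows):
    return MeasurementTable(
        pd.DataFrame(rows, columns=["subject", "method", "replicate", "value"])
    )


def _design_only_method1():
    return SubjectDesign(
        subject_id="x", p_i=1,
        observed_mask=np.array([True, False]),
        X_rows=np.array([[1.0, 0.0]]), Z_rows=np.array([[1.0, 0.0]]),
        values=np.array([0.5]), methods=np.array([1]),
    )


class TestBuildSubjectDesigns:
    def test_complete_case(self):
        t = _table([("a", m, s, 0.1 * m + s) for m in (1, 2) for s in (1, 2)]
                   + [("b", 1, 1, 0.0), ("b", 2, 1, 0.1)])
        d = {x.subject_id: x for x in build_subject_designs(t)}
        assert d["a"].n_obs == 4
        assert d["a"].observed_mask.all()
        assert d["a"].p_i == 2

    def test_unequal_replicates_missing_cell(self):
        rows = [("a", 1, s, 0.1) for s in (1, 2, 3)] + [
            ("a", 2, s, 0.2) for s in (1, 2)
        ] + [("b", 1, 1, 0.0), ("b", 2, 1, 0.1)]
        d = {x.subject_id: x for x in build_subject_designs(_table(rows))}
        a = d["a"]
        assert a.p_i == 3
        assert a.n_obs == 5
        assert list(a.observed_mask) == [True] * 5 + [False]

    def test_cell_order_session_major_method_minor(self):
        rows = [("a", 2, 1, 21.0), ("a", 1, 2, 12.0), ("a", 1, 1, 11.0),
                ("a", 2, 2, 22.0), ("b", 1, 1, 0.0), ("b", 2, 1, 0.1)]
        a = [x for x in build_subject_designs(_table(rows)) if x.subject_id == "a"][0]
        assert list(a.values) == [11.0, 21.0, 12.0, 22.0]
        assert list(a.methods) == [1, 2, 1, 2]

    def test_single_record_subject_unit_z_row(self):
        # degenerate but admissible subject alongside a replicated one
        rows = [("a", 1, s, 0.1) for s in (1, 2)] + [
            ("a", 2, s, 0.2) for s in (1, 2)
        ] + [("c", 1, 1, 0.7)]
        d = {x.subject_id: x for x in build_subject_designs(_table(rows))}
        c = d["c"]
        assert c.n_obs == 1
        np.testing.assert_array_equal(c.Z_rows, [[1.0, 0.0]])


class TestMarginalCovariance:
    def test_zero_random_effects(self):
        d = SubjectDesign("x", 1, np.array([True, True]),
                          np.eye(2), np.eye(2),
                          np.zeros(2), np.array([1, 2]))
        np.testing.assert_allclose(
            marginal_covariance(np.zeros((2, 2)), np.eye(2), d), np.eye(2)
        )

    def test_two_session_block_structure(self):
        D = np.array([[1.0, 0.5], [0.5, 1.0]])
        S = np.array([[0.2, 0.1], [0.1, 0.2]])
        d = SubjectDesign("x", 2, np.ones(4, dtype=bool),
                          np.tile(np.eye(2), (2, 1)), np.tile(np.eye(2), (2, 1)),
                          np.zeros(4), np.array([1, 2, 1, 2]))
        om = marginal_covariance(D, S, d)
        expect = np.block([[D + S, D], [D, D + S]])
        np.testing.assert_allclose(om, expect, atol=1e-14)
        # cross-check against the generative model's empirical covariance
        rng = np.random.default_rng(3)
        n = 200_000
        b = rng.multivariate_normal(np.zeros(2), D, size=n)
        y = np.hstack([
            b + rng.multivariate_normal(np.zeros(2), S, size=n),
            b + rng.multivariate_normal(np.zeros(2), S, size=n),
        ])
        np.testing.assert_allclose(np.cov(y.T), expect, atol=0.03)

    def test_mask_deletion_principal_submatrix(self):
        D = np.array([[1.0, 0.5], [0.5, 1.0]])
        S = np.array([[0.2, 0.1], [0.1, 0.2]])
        full_design = SubjectDesign("x", 2, np.ones(4, dtype=bool),
                                    np.tile(np.eye(2), (2, 1)),
                                    np.tile(np.eye(2), (2, 1)),
                                    np.zeros(4), np.array([1, 2, 1, 2]))
        mask = np.array([True, True, True, False])
        masked = SubjectDesign("x", 2, mask, np.eye(3, 2), np.eye(3, 2),
                               np.zeros(3), np.array([1, 2, 1]))
        full = marginal_covariance(D, S, full_design)
        np.testing.assert_allclose(
            marginal_covariance(D, S, masked), full[:3, :3], atol=1e-14
        )

    def test_non_pd_inputs_rejected_with_eigenvalue(self):
        d = SubjectDesign("x", 1, np.array([True, True]),
                          np.eye(2), np.eye(2), np.zeros(2), np.array([1, 2]))
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            marginal_covariance(np.zeros((2, 2)), bad, d)


def brute_force_deviance(mu, D, Sigma, table):
    """Independent oracle: explicit block assembly + generic MVN density."""
    mu = np.asarray(mu, float)
    total = 0.0
    for d in build_subject_designs(table):
        p = d.p_i
        om = np.zeros((2 * p, 2 * p))
        for t in range(p):
            for s in range(p):
                om[2 * t: 2 * t + 2, 2 * s: 2 * s + 2] = D + (
                    Sigma if t == s else 0.0
                )
        keep = np.where(d.observed_mask)[0]
        om = om[np.ix_(keep, keep)]
        mean = mu[d.methods - 1]
        total += -2.0 * multivariate_normal.logpdf(d.values, mean, om)
    return total


class TestMinus2Loglik:
    def test_single_cell_closed_form(self):
        d = _design_only_method1()
        dev = minus2_loglik([0.5, 0.0], np.zeros((2, 2)), np.eye(2), [d])
        assert dev == pytest.approx(math.log(2 * math.pi), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            t = random_small_table(rng, max_subjects=3, max_sessions=2)
            D = random_spd(rng, 0.7)
            S = random_spd(rng, 0.7)
            mu = rng.normal(0, 1, 2)
            ours = minus2_loglik(mu, D, S, build_subject_designs(t))
            oracle = brute_force_deviance(mu, D, S, t)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_gaussian_scaling_identity(self):
        rng = np.random.default_rng(5)
        t = random_small_table(rng, max_subjects=4, max_sessions=2, missing=0.1)
        D, S = random_spd(rng), random_spd(rng)
        mu = np.array([0.3, -0.2])
        designs = build_subject_designs(t)
        dev0 = minus2_loglik(mu, D, S, designs)
        scaled = t.frame.copy()
        mu_per_row = np.where(scaled["method"] == 1, mu[0], mu[1])
        scaled["value"] = mu_per_row + math.sqrt(2) * (scaled["value"] - mu_per_row)
        designs2 = build_subject_designs(MeasurementTable(scaled))
        dev2 = minus2_loglik(mu, 2 * D, 2 * S, designs2)
        n_total = sum(d.n_obs for d in designs)
        assert dev2 - dev0 == pytest.approx(n_total * math.log(2), abs=1e-8)


class TestProfileMeans:
    def test_balanced_equals_grand_means(self, balanced_table):
        designs = build_subject_designs(balanced_table)
        D, S = np.eye(2) * 0.3, np.eye(2) * 0.2 + 0.05
        mu, _ = profile_means(D, S, designs)
        assert mu[0] == pytest.approx(balanced_table.method_values(1).mean(), abs=1e-10)
        assert mu[1] == pytest.approx(balanced_table.method_values(2).mean(), abs=1e-10)

    def test_absent_method_rejected(self):
        designs = [_design_only_method1(), _design_only_method1()]
        with pytest.raises(ValueError, match="method 2"):
            profile_means(np.zeros((2, 2)), np.eye(2), designs)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        t = random_small_table(rng, max_subjects=5, max_sessions=3, missing=0.25)
        D, S = random_spd(rng), random_spd(rng)
        designs = build_subject_designs(t)
        mu, fc = profile_means(D, S, designs)
        X = np.vstack([d.X_rows for d in designs])
        y = np.concatenate([d.values for d in designs])
        Om = block_diag(*[marginal_covariance(D, S, d) for d in designs])
        Oi = np.linalg.inv(Om)
        A = X.T @ Oi @ X
        mu_oracle = np.linalg.solve(A, X.T @ Oi @ y)
        np.testing.assert_allclose(mu, mu_oracle, atol=1e-10)
        np.testing.assert_allclose(fc, np.linalg.inv(A), atol=1e-10)


def grid_refine_oracle(model, spec, theta0, sweeps=80, span=2.0, npts=13):
    """Cyclic one-dimensional grid refinement; independent of the
    quasi-Newton path used by fit()."""
    theta = np.array(theta0, float)
    width = np.full(theta.size, span)
    best = model.profiled_deviance(theta, spec)
    for _ in range(sweeps):
        for j in range(theta.size):
            grid = theta[j] + np.linspace(-width[j], width[j], npts)
            vals = [
                model.profiled_deviance(
                    np.concatenate([theta[:j], [g], theta[j + 1:]]), spec
                )
                for g in grid
            ]
            k = int(np.argmin(vals))
            theta[j], best = grid[k], vals[k]
        width *= 0.75
    return best, theta


class TestFit:
    def test_tiny_instance_matches_grid_oracle(self):
        rng = np.random.default_rng(23)
        rows = []
        for i in range(4):
            for t in (1, 2):
                for m in (1, 2):
                    rows.append((f"s{i}", m, t, float(rng.normal(0.2 * m, 0.8))))
        table = _table(rows)
        model = MethodComparisonModel(table)
        spec = ModelSpec("UN", "UN")
        res = model.fit(spec)
        theta0 = model._starts(spec, 1, 0)[0]
        dev_oracle, _ = grid_refine_oracle(model, spec, theta0)
        assert res.minus2loglik == pytest.approx(dev_oracle, abs=1e-4)

    def test_zero_between_variance_boundary(self):
        from methodcompare import SimulationConfig, simulate

        cfg = SimulationConfig(
            n_subjects=200, replicates=4, mu=(0.0, 0.0),
            D_true=np.zeros((2, 2)),
            Sigma_true=np.array([[0.1, 0.0], [0.0, 0.1]]), seed=2,
        )
        res = MethodComparisonModel(simulate(cfg)).fit(ModelSpec("UN", "UN"))
        assert np.linalg.eigvalsh(res.D_hat).max() < 0.03

    def test_cs_constraint_equal_diagonals(self, sim_table):
        model = MethodComparisonModel(sim_table)
        res = model.fit(ModelSpec("CS", "CS"))
        assert res.D_hat[0, 0] == pytest.approx(res.D_hat[1, 1], abs=1e-14)
        assert res.Sigma_hat[0, 0] == pytest.approx(res.Sigma_hat[1, 1], abs=1e-14)
        np.testing.assert_allclose(res.D_hat, res.D_hat.T)
        np.testing.assert_allclose(res.Sigma_hat, res.Sigma_hat.T)

    def test_nesting_monotonicity(self, sim_table):
        model = MethodComparisonModel(sim_table)
        dev = {
            (d, s): model.fit(ModelSpec(d, s)).minus2loglik
            for d in ("UN", "CS") for s in ("UN", "CS")
        }
        tol = 1e-6
        assert dev[("UN", "UN")] <= dev[("UN", "CS")] + tol
        assert dev[("UN", "CS")] <= dev[("CS", "CS")] + tol
        assert dev[("UN", "UN")] <= dev[("CS", "UN")] + tol
        assert dev[("CS", "UN")] <= dev[("CS", "CS")] + tol

    def test_permutation_invariance(self, demo_table):
        model = MethodComparisonModel(demo_table)
        res = model.fit(ModelSpec("UN", "UN"))
        shuffled = demo_table.frame.sample(frac=1.0, random_state=4)
        res2 = MethodComparisonModel(MeasurementTable(shuffled)).fit(
            ModelSpec("UN", "UN")
        )
        assert res2.minus2loglik == pytest.approx(res.minus2loglik, abs=1e-10)
        np.testing.assert_allclose(res2.mu, res.mu, atol=1e-10)
        np.testing.assert_allclose(res2.D_hat, res.D_hat, atol=1e-10)
        np.testing.assert_allclose(res2.Sigma_hat, res.Sigma_hat, atol=1e-10)

    def test_method_swap_symmetry(self, sim_table):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = MethodComparisonModel(sim_table).fit(ModelSpec("UN", "UN"))
        res_sw = MethodComparisonModel(sim_table.swap_methods()).fit(
            ModelSpec("UN", "UN")
        )
        assert res_sw.minus2loglik == pytest.approx(res.minus2loglik, abs=1e-5)
        np.testing.assert_allclose(res_sw.mu, res.mu[::-1], atol=1e-4)
        np.testing.assert_allclose(res_sw.D_hat, P @ res.D_hat @ P, atol=1e-3)
        np.testing.assert_allclose(res_sw.Sigma_hat, P @ res.Sigma_hat @ P, atol=1e-3)

    def test_estimate_consistency_rmse_decreases(self):
        from methodcompare import SimulationConfig, simulate

        D = np.array([[0.05, 0.02], [0.02, 0.08]])
        S = np.array([[0.3, 0.05], [0.05, 0.1]])
        idx = [(0, 0), (0, 1), (1, 1)]
        rmse = {}
        for N in (50, 200, 800):
            errs = []
            for rep in range(40):
                cfg = SimulationConfig(
                    n_subjects=N, replicates=3, mu=(0.1, 0.0),
                    D_true=D, Sigma_true=S, seed=1000 * N + rep,
                )
                r = MethodComparisonModel(simulate(cfg)).fit(ModelSpec("UN", "UN"))
                errs.append(
                    [r.D_hat[i] - D[i] for i in idx]
                    + [r.Sigma_hat[i] - S[i] for i in idx]
                )
            rmse[N] = np.sqrt((np.array(errs) ** 2).mean(axis=0))
        assert (rmse[200] < rmse[50]).all()
        assert (rmse[800] < rmse[200]).all()


class TestParamCountsAndOverallBlock:
    @pytest.mark.parametrize(
        "d,s,count,null_df",
        [("UN", "UN", 6, 5), ("UN", "CS", 5, 4), ("CS", "UN", 5, 4),
         ("CS", "CS", 4, 3)],
    )
    def test_cov_param_count(self, d, s, count, null_df):
        spec = ModelSpec(d, s)
        assert cov_param_count(spec) == count
        assert null_model_lrt_df(spec) == null_df

    def _stub(self, D, S):
        return MethodComparisonResults(
            model=None, spec=ModelSpec("UN", "UN"), theta=None,
            mu=np.zeros(2), D_hat=np.asarray(D, float),
            Sigma_hat=np.asarray(S, float), minus2loglik=0.0,
            n_cov_params=6, fixed_cov=np.eye(2), converged=True,
            n_subjects=2, n_obs_total=4,
        )

    @pytest.mark.parametrize(
        "between,within,overall",
        [((0.0413, 0.0670), (0.3396, 0.1047), (0.3809, 0.1717)),
         ((0.0273, 0.0848), (0.0485, 0.0825), (0.0758, 0.1673))],
    )
    def test_overall_variance_additivity(self, between, within, overall):
        res = self._stub(np.diag(between), np.diag(within))
        ob = overall_block(res)
        assert ob.omega[0, 0] == pytest.approx(overall[0], abs=1e-12)
        assert ob.omega[1, 1] == pytest.approx(overall[1], abs=1e-12)
        np.testing.assert_allclose(np.diag(ob.corr), 1.0)

    def test_omega_equals_sigma_when_d_zero(self):
        S = np.array([[0.2, 0.05], [0.05, 0.3]])
        ob = overall_block(self._stub(np.zeros((2, 2)), S))
        np.testing.assert_array_equal(ob.omega, S)

    def test_correlation_bounded(self):
        D = np.array([[1.0, 0.9], [0.9, 1.0]])
        ob = overall_block(self._stub(D, 1e-12 * np.eye(2)))
        assert abs(ob.corr[0, 1]) <= 1.0
        assert ob.corr[0, 1] == pytest.approx(0.9, abs=1e-6)

    def test_zero_variance_correlation_undefined(self):
        ob = overall_block(self._stub(np.zeros((2, 2)), np.zeros((2, 2))))
        assert math.isnan(ob.corr[0, 1])
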