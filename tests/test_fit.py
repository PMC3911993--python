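"""ML estimation: moments, implied covariance, discrepancy, fit, indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pathsem as ps
from pathsem.errors import (
    IdentificationError,
    NotPositiveDefiniteError,
    PathsemError,
    SingularStructureError,
)
from pathsem.fit import _chol_logdet, _f_and_grad, default_start


class TestSampleCovariance:
    def test_collinear_pair_closed_form(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        mom = ps.sample_covariance(data)
        assert np.allclose(mom.S, [[1.0, 2.0], [2.0, 4.0]])
        assert mom.n == 3

    def test_matches_double_loop_oracle(self, rng):
        data = rng.standard_normal((37, 4))
        mom = ps.sample_covariance(pd.DataFrame(data, columns=list("abcd")))
        n = data.shape[0]
        xbar = data.mean(axis=0)
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                acc = 0.0
                for t in range(n):
                    acc += (data[t, i] - xbar[i]) * (data[t, j] - xbar[j])
                expected[i, j] = acc / (n - 1)
        assert np.allclose(mom.S, expected)

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"ok": [1.0, 2.0, 3.0, 4.0], "flat": [5.0] * 4})
        with pytest.raises(PathsemError, match="flat"):
            ps.sample_covariance(data)

    def test_listwise_deletion_and_minimum_n(self):
        data = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(PathsemError, match="3 complete"):
            ps.sample_covariance(data)


class TestImpliedCovariance:
    def test_no_paths_identity_measurement(self):
        structure = ps.ModelStructure(observed=["a", "b"])
        model = ps.build_sem_model(structure)
        theta = model.theta_from_dict({"a~~a": 2.0, "b~~b": 3.0})
        assert np.allclose(ps.implied_covariance(model, theta), np.diag([2.0, 3.0]))

    def test_single_path_tracing_closed_form(self):
        structure = ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        model = ps.build_sem_model(structure)
        b, psi_y = 0.8, 0.5
        theta = model.theta_from_dict({"y~x": b, "x~~x": 1.0, "y~~y": psi_y})
        sigma = ps.implied_covariance(model, theta)
        names = model.observed_names
        ix, iy = names.index("x"), names.index("y")
        assert sigma[ix, iy] == pytest.approx(b)
        assert sigma[iy, iy] == pytest.approx(b**2 + psi_y)

    def test_monte_carlo_agreement_on_random_recursive_model(self, rng):
        """Sigma(theta) must match the empirical covariance of simulated draws."""
        obs = [f"v{i}" for i in range(5)]
        regressions = {}
        for i in range(1, 5):
            preds = [obs[j] for j in range(i) if rng.random() < 0.6]
            if preds:
                regressions[obs[i]] = preds
        model = ps.build_sem_model(ps.ModelStructure(observed=obs, regressions=regressions))
        values = {}
        for s in model.theta_map:
            if s.matrix == "beta":
                values[s.name] = float(rng.uniform(-0.8, 0.8))
            else:
                values[s.name] = float(rng.uniform(0.5, 1.5))
        tm = ps.TrueModel(model, model.theta_from_dict(values))
        n = 1_000_000
        data = ps.simulate(tm, n=n, seed=9)
        emp = np.cov(data.to_numpy(), rowvar=False)
        sigma = ps.implied_covariance(model, tm.theta_true)
        # entrywise 3 standard errors of a sample covariance
        se = np.sqrt(
            (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n
        )
        assert np.all(np.abs(emp - sigma) < 3.5 * se)

    def test_unit_feedback_loop_is_named(self):
        structure = ps.ModelStructure(observed=["x"], regressions={"x": ["x"]})
        model = ps.build_sem_model(structure)
        theta = model.theta_from_dict({"x~x": 1.0, "x~~x": 1.0})
        with pytest.raises(SingularStructureError, match="x"):
            ps.implied_covariance(model, theta)


class TestMlDiscrepancy:
    def test_perfect_fit_is_zero(self, rng):
        a = rng.standard_normal((4, 4))
        S = a @ a.T + 4 * np.eye(4)
        assert ps.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_value(self):
        assert ps.ml_discrepancy([[2.0]], [[1.0]]) == pytest.approx(1.0 - math.log(2.0))

    def test_permutation_invariance(self, rng):
        a = rng.standard_normal((5, 5))
        S = a @ a.T + 5 * np.eye(5)
        b = rng.standard_normal((5, 5))
        Sigma = b @ b.T + 5 * np.eye(5)
        perm = rng.permutation(5)
        f1 = ps.ml_discrepancy(S, Sigma)
        f2 = ps.ml_discrepancy(S[np.ix_(perm, perm)], Sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_rejects_indefinite_input(self):
        with pytest.raises(NotPositiveDefiniteError):
            ps.ml_discrepancy([[1.0, 2.0], [2.0, 1.0]], np.eye(2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative_property(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 5))
        a = rng.standard_normal((p, p))
        S = a @ a.T + p * np.eye(p)
        b = rng.standard_normal((p, p))
        Sigma = b @ b.T + p * np.eye(p)
        assert ps.ml_discrepancy(S, Sigma) >= 0.0


class TestFitMl:
    def test_single_path_recovers_ols_slope(self, rng):
        n = 100_000
        x = rng.standard_normal(n)
        y = 0.65 * x + rng.standard_normal(n) * 0.7
        data = pd.DataFrame({"x": x, "y": y})
        model = ps.build_sem_model(
            ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        )
        fit = ps.fit_ml(model, ps.sample_covariance(data))
        assert fit.converged
        assert fit.estimates()["y~x"] == pytest.approx(0.65, abs=0.01)

    def test_multi_predictor_equals_ols_closed_form(self, rng):
        """With a saturated exogenous block the ML paths are exactly OLS."""
        n = 500
        x1 = rng.standard_normal(n)
        x2 = 0.5 * x1 + rng.standard_normal(n)
        y = 0.3 * x1 - 0.7 * x2 + rng.standard_normal(n)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        model = ps.build_sem_model(
            ps.ModelStructure(
                observed=["y", "x1", "x2"],
                regressions={"y": ["x1", "x2"]},
                covariances=[("x1", "x2")],
            )
        )
        fit = ps.fit_ml(model, ps.sample_covariance(data))
        X = np.column_stack([x1, x2])
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        est = fit.estimates()
        assert est["y~x1"] == pytest.approx(b_ols[0], abs=1e-6)
        assert est["y~x2"] == pytest.approx(b_ols[1], abs=1e-6)

    def test_saturated_model_reproduces_sample_covariance(self, rng):
        n = 200
        data = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        model = ps.build_sem_model(
            ps.ModelStructure(
                observed=["a", "b", "c"],
                covariances=[("a", "b"), ("a", "c"), ("b", "c")],
            )
        )
        mom = ps.sample_covariance(data)
        fit = ps.fit_ml(model, mom)
        T = (mom.n - 1) * fit.fmin
        assert T == pytest.approx(0.0, abs=1e-4)
        sigma = ps.implied_covariance(model, fit.theta_hat)
        assert np.allclose(sigma, mom.S, atol=1e-6)
        assert fit.indices is None  # df = 0: no fit indices

    def test_overparameterized_model_rejected_before_optimizing(self, rng):
        model = ps.build_sem_model(
            ps.ModelStructure(
                observed=["a", "b"],
                regressions={"b": ["a"]},
                covariances=[("a", "b")],
            )
        )
        data = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        with pytest.raises(IdentificationError):
            ps.fit_ml(model, ps.sample_covariance(data))

    def test_analytic_gradient_matches_finite_differences(self, final_truth):
        model = final_truth.model
        S = ps.implied_covariance(model, final_truth.theta_true) + 0.05 * np.eye(10)
        _, logdet_s = _chol_logdet(S)
        theta = final_truth.theta_true * 1.1
        f0, grad = _f_and_grad(theta, model, S, logdet_s)
        for k in range(model.q):
            h = 1e-6 * max(1.0, abs(theta[k]))
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] -= h
            fu, _ = _f_and_grad(up, model, S, logdet_s)
            fd, _ = _f_and_grad(dn, model, S, logdet_s)
            assert grad[k] == pytest.approx((fu - fd) / (2 * h), rel=1e-4, abs=1e-7)

    def test_heywood_case_is_flagged(self):
        # two indicators correlated beyond what their variances support
        S = np.array(
            [[1.0, 0.99, 0.30], [0.99, 1.0, 0.20], [0.30, 0.20, 1.0]]
        )
        mom = ps.SampleMoments(S, 60, ["m1", "m2", "x"])
        model = ps.build_sem_model(
            ps.ModelStructure(
                observed=["m1", "m2", "x"],
                measurement={"f": ["m1", "m2"]},
                regressions={"f": ["x"]},
            )
        )
        fit = ps.fit_ml(model, mom)
        assert any("heywood" in w for w in fit.warnings)


class TestFitIndices:
    def test_direct_formula_arithmetic(self):
        ix = ps.fit_indices(20.0, 10, 101, np.eye(2), np.eye(2))
        assert ix.rmsea == pytest.approx(math.sqrt(10.0 / 1000.0))

    def test_truncation_at_zero(self):
        ix = ps.fit_indices(5.0, 10, 101, np.eye(2), np.eye(2))
        assert ix.rmsea == 0.0

    def test_perfect_fit_srmr_zero(self, rng):
        a = rng.standard_normal((3, 3))
        S = a @ a.T + 3 * np.eye(3)
        ix = ps.fit_indices(1.0, 2, 50, S, S)
        assert ix.srmr == 0.0

    def test_ci_brackets_point_estimate(self):
        ix = ps.fit_indices(55.0, 34, 48, np.eye(2), np.eye(2))
        assert ix.rmsea_ci_low <= ix.rmsea <= ix.rmsea_ci_high
        assert 0.0 <= ix.rmsea_pclose <= 1.0

    def test_rmsea_monotone_nonincreasing_in_df(self):
        vals = [ps.fit_indices(30.0, df, 100, np.eye(2), np.eye(2)).rmsea
                for df in range(1, 31)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_df_zero_is_an_error(self):
        with pytest.raises(PathsemError, match="df"):
            ps.fit_indices(1.0, 0, 50, np.eye(2), np.eye(2))


class TestStandardize:
    def test_unit_variances_leave_coefficients_alone(self):
        structure = ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        model = ps.build_sem_model(structure)
        theta = model.theta_from_dict({"y~x": 0.6, "x~~x": 1.0, "y~~y": 1.0 - 0.36})
        std = ps.standardize(model, theta)
        assert std["y~x"] == pytest.approx(0.6)

    def test_single_predictor_standardized_equals_correlation(self, rng):
        n = 2000
        x = rng.standard_normal(n) * 3.0
        y = 0.4 * x + rng.standard_normal(n)
        data = pd.DataFrame({"x": x, "y": y})
        model = ps.build_sem_model(
            ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        )
        fit = ps.fit_ml(model, ps.sample_covariance(data))
        r = np.corrcoef(x, y)[0, 1]
        assert fit.standardized["y~x"] == pytest.approx(r, abs=1e-6)

    def test_invariance_to_rescaling_observed_variables(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        model = ps.build_sem_model(
            ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        )
        f1 = ps.fit_ml(model, ps.sample_covariance(pd.DataFrame({"x": x, "y": y})))
        f2 = ps.fit_ml(
            model, ps.sample_covariance(pd.DataFrame({"x": 7.0 * x, "y": 0.2 * y}))
        )
        assert f1.standardized["y~x"] == pytest.approx(f2.standardized["y~x"], abs=1e-6)


class TestWald:
    def test_quantile_anchors(self):
        structure = ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        model = ps.build_sem_model(structure)
        fit = ps.FitResult(
            model=model,
            theta_hat=np.array([1.959964, 0.0, 1.0]),
            se=np.array([1.0, 1.0, 1.0]),
            z=np.zeros(3),
            p=np.zeros(3),
            standardized={},
            indices=None,
            converged=True,
            n_iter=1,
            warnings=[],
            fmin=0.0,
            n=100,
        )
        tab = ps.wald_tests(fit, alpha=0.05)
        assert tab.loc["y~x", "p"] == pytest.approx(0.05, abs=1e-6)
        assert tab.iloc[1]["p"] == pytest.approx(1.0)

    def test_zero_se_rejected(self):
        structure = ps.ModelStructure(observed=["x", "y"], regressions={"y": ["x"]})
        model = ps.build_sem_model(structure)
        fit = ps.FitResult(
            model=model,
            theta_hat=np.ones(3),
            se=np.array([0.0, 1.0, 1.0]),
            z=np.zeros(3),
            p=np.zeros(3),
            standardized={},
            indices=None,
            converged=True,
            n_iter=1,
            warnings=[],
            fmin=0.0,
            n=100,
        )
        with pytest.raises(PathsemError, match="zero standard error"):
            ps.wald_tests(fit)


def test_default_start_uses_observed_variances(final_truth, study_data):
    mom = ps.sample_covariance(study_data)
    theta0 = default_start(final_truth.model, mom)
    var = dict(zip(mom.names, np.diag(mom.S)))
    for k, slot in enumerate(final_truth.model.theta_map):
        if slot.matrix in ("lambda", "beta"):
            assert theta0[k] == 0.5
        elif slot.matrix == "theta":
            name = final_truth.model.observed_names[slot.row]
            assert theta0[k] == pytest.approx(0.5 * var[name])
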