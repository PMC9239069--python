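"""Single-balance regression: OLS factorisation, metrics, permutation test."""

import numpy as np
import pytest

from nearbalance import (
    BalancingElement,
    RegressionDesign,
    SingleBalanceRegression,
    balance_impact,
    classify_by_balance,
    fit_ols,
    fit_single_balance,
    nearest_balance,
    orthogonal_complement_test,
    pivot_basis,
    r_squared,
)
from nearbalance.compo import ClrVector, basis_from_partition
from nearbalance.nearest import enumerate_elements
from nearbalance.simulate import (
    CaseControlSimConfig,
    simulate_case_control,
    taxon_accuracy,
)


def small_design(rng, d=5, n=24, k=1, signal=None):
    labels = tuple(f"t{i}" for i in range(1, d + 1))
    basis = pivot_basis(labels)
    x = rng.standard_normal(n)
    Z = rng.standard_normal((n, k)) if k else None
    Y = rng.standard_normal((n, d - 1))
    if signal is not None:
        Y = Y * 0.1 + np.outer(x, signal)
    return RegressionDesign.build(Y, x, basis, covariates=Z)


class TestFitOls:
    def test_mean_shift_case(self, rng):
        """x ≡ 1 with no intercept: the coefficient is the sample mean."""
        basis = pivot_basis(tuple("abcd"))
        Y = rng.standard_normal((15, 3))
        design = RegressionDesign.build(
            Y, np.ones(15), basis, include_intercept=False
        )
        fit = fit_ols(design)
        assert np.allclose(fit.v_star, Y.mean(axis=0), atol=1e-9)

    def test_noiseless_recovery(self, rng):
        basis = pivot_basis(tuple("abcde"))
        v_true = rng.standard_normal(4)
        x = rng.standard_normal(30)
        Y = np.outer(x, v_true)
        fit = fit_ols(RegressionDesign.build(Y, x, basis))
        assert np.allclose(fit.v_star, v_true, atol=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_normal_equation_oracle(self, rng):
        design = small_design(rng, k=2)
        fit = fit_ols(design)
        X = design.design_matrix
        B = np.linalg.solve(X.T @ X, X.T @ design.Y)
        assert np.allclose(fit.v_star, B[0], atol=1e-8)
        assert np.allclose(fit.covariate_coefficients, B[1:], atol=1e-8)

    def test_collinear_columns_named(self, rng):
        basis = pivot_basis(tuple("abcd"))
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="collinear"):
            RegressionDesign.build(
                rng.standard_normal((20, 3)), x, basis, covariates=x[:, None],
                covariate_names=("copy_of_x",),
            )


class TestFitSingleBalance:
    def test_exact_two_group_balance(self, rng):
        labels = tuple(f"t{i}" for i in range(1, 7))
        basis = pivot_basis(labels)
        el = BalancingElement({"t1", "t2"}, {"t5"}, labels)
        e_ilr = el.clr().coords @ basis.psi.T
        x = np.repeat([0.0, 1.0], 12)
        Y = np.outer(x, 1.7 * e_ilr)
        fit = fit_single_balance(RegressionDesign.build(Y, x, basis))
        assert fit.balance.element.same_direction(el)
        assert fit.balance.coefficient == pytest.approx(1.7, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.impact == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_balance_under_noise(self):
        cfg = CaseControlSimConfig(d=12, n_per_group=150, seed=5)
        data = simulate_case_control(cfg)
        fit = fit_single_balance(RegressionDesign.build(data.Y, data.x, data.basis))
        assert taxon_accuracy(data.element, fit.balance.element) == 1.0

    def test_rss_optimal_over_exhaustive_balances(self, rng):
        """Fixing any other element and its implied covariate matrix cannot
        beat the factorised least-squares fit."""
        for k in (0, 2):
            design = small_design(rng, d=5, n=20, k=k)
            fit = fit_single_balance(design)
            v_ls = fit.ols.v_star
            basis = design.basis
            for el in enumerate_elements(basis.labels):
                e_ilr = el.clr().coords @ basis.psi.T
                beta = (v_ls @ e_ilr) * e_ilr
                resid = design.Y - np.outer(design.x, beta)
                A = np.linalg.lstsq(design.Z, resid, rcond=None)[0]
                rss = float(((resid - design.Z @ A) ** 2).sum())
                assert fit.rss <= rss + 1e-9

    def test_mean_shift_equals_nearest_balance_of_mean(self, rng):
        basis = pivot_basis(tuple("abcdef"))
        Y = rng.standard_normal((25, 5)) + np.array([1.0, -0.4, 0.3, 0.0, -0.2])
        design = RegressionDesign.build(Y, np.ones(25), basis, include_intercept=False)
        fit = fit_single_balance(design)
        mean_clr = ClrVector(Y.mean(axis=0) @ basis.psi, basis.labels)
        direct = nearest_balance(mean_clr)
        assert fit.balance.element.same_direction(direct.balance.element)

    def test_intercept_identity_single_predictor(self, rng):
        design = small_design(rng, d=5, n=30, k=0)
        fit = fit_single_balance(design)
        a_ls = fit.covariate_coefficients[0]
        expect = design.Y.mean(axis=0) - design.x.mean() * fit.beta_ilr
        assert np.allclose(a_ls, expect, atol=1e-9)

    def test_basis_invariance(self, rng):
        labels = tuple("abcde")
        b1 = pivot_basis(labels)
        b2 = basis_from_partition(
            [({"b"}, {"a", "c", "d", "e"}), ({"c", "d"}, {"a", "e"}),
             ({"c"}, {"d"}), ({"a"}, {"e"})],
            labels,
        )
        x = rng.standard_normal(30)
        clr_rows = rng.standard_normal((30, 5))
        clr_rows -= clr_rows.mean(axis=1, keepdims=True)
        f1 = fit_single_balance(RegressionDesign.build(clr_rows @ b1.psi.T, x, b1))
        f2 = fit_single_balance(RegressionDesign.build(clr_rows @ b2.psi.T, x, b2))
        assert f1.balance.element.same_direction(f2.balance.element)
        assert np.allclose(
            f1.beta_ilr @ b1.psi, f2.beta_ilr @ b2.psi, atol=1e-8
        )

    def test_zero_coefficient_rejected(self, rng):
        basis = pivot_basis(tuple("abcd"))
        x = np.repeat([0.0, 1.0], 10)
        Y = np.tile(np.array([0.3, -0.1, 0.2]), (20, 1))  # no x-dependence
        with pytest.raises(ValueError, match="predictor-associated"):
            fit_single_balance(RegressionDesign.build(Y, x, basis))


class TestMetrics:
    def test_r_squared_perfect_and_mean(self, rng):
        design = small_design(rng, d=5, n=30, k=0,
                              signal=np.array([0.5, -0.5, 0.2, 0.1]))
        fit = fit_single_balance(design)
        assert r_squared(fit, design.Y, design.x) == pytest.approx(
            fit.r_squared, abs=1e-9
        )
        # scoring the training mean alone gives R² = 0
        class MeanFit:
            beta_ilr = np.zeros(4)
            covariate_coefficients = design.Y.mean(axis=0)[None, :]
        assert r_squared(MeanFit, design.Y, design.x) == pytest.approx(0.0, abs=1e-9)

    def test_train_at_least_test_in_expectation(self):
        diffs = []
        for seed in range(20):
            cfg = CaseControlSimConfig(d=8, n_per_group=40, seed=seed,
                                       noise_to_shift=0.3)
            data = simulate_case_control(cfg)
            rng = np.random.default_rng(seed + 500)
            idx = rng.permutation(80)
            tr, te = idx[:40], idx[40:]
            fit = fit_single_balance(
                RegressionDesign.build(data.Y[tr], data.x[tr], data.basis)
            )
            diffs.append(
                fit.r_squared - r_squared(fit, data.Y[te], data.x[te])
            )
        assert np.mean(diffs) > 0

    def test_recentering_removes_location_offset(self, rng):
        design = small_design(rng, d=5, n=30, k=0,
                              signal=np.array([0.5, -0.5, 0.2, 0.1]))
        fit = fit_single_balance(design)
        shifted = design.Y + 5.0
        assert r_squared(fit, shifted, design.x) < 0
        corrected = r_squared(fit, shifted, design.x, recenter=True)
        assert corrected == pytest.approx(fit.r_squared, abs=1e-9)

    def test_impact_equals_a1_impact(self, rng):
        design = small_design(rng, d=6, n=25, k=1)
        fit = fit_single_balance(design)
        v_clr = ClrVector(fit.ols.v_star @ design.basis.psi, design.basis.labels)
        assert balance_impact(fit) == pytest.approx(
            nearest_balance(v_clr).impact, abs=1e-12
        )

    def test_impact_decreases_with_noise(self):
        means = []
        for ratio in (0.05, 0.4):
            vals = []
            for seed in range(10):
                cfg = CaseControlSimConfig(d=10, n_per_group=60, seed=seed,
                                           noise_to_shift=ratio)
                data = simulate_case_control(cfg)
                fit = fit_single_balance(
                    RegressionDesign.build(data.Y, data.x, data.basis)
                )
                vals.append(fit.impact)
            means.append(np.mean(vals))
        assert means[0] > means[1]


class TestOrthogonalComplementTest:
    def _fit(self, data):
        design = RegressionDesign.build(data.Y, data.x, data.basis)
        return design, fit_single_balance(design)

    def test_deterministic_under_seed(self):
        data = simulate_case_control(CaseControlSimConfig(d=8, n_per_group=30, seed=3))
        design, fit = self._fit(data)
        p1 = orthogonal_complement_test(design, fit, n_permutations=99, seed=11)
        p2 = orthogonal_complement_test(design, fit, n_permutations=99, seed=11)
        assert p1["p_value"] == p2["p_value"]

    def test_type_one_error_calibrated(self):
        """Under a pure single-balance group difference the test rejects at
        roughly the nominal rate."""
        rejections = 0
        n_sim = 120
        for seed in range(n_sim):
            cfg = CaseControlSimConfig(d=6, n_per_group=25, seed=seed,
                                       noise_to_shift=0.05)
            data = simulate_case_control(cfg)
            design, fit = self._fit(data)
            res = orthogonal_complement_test(design, fit, n_permutations=99,
                                             seed=seed + 7)
            rejections += res["p_value"] < 0.05
        rate = rejections / n_sim
        assert 0.0 <= rate < 0.13

    def test_power_against_orthogonal_component(self):
        hits = 0
        for seed in range(10):
            cfg = CaseControlSimConfig(d=6, n_per_group=100, seed=seed,
                                       noise_to_shift=0.05)
            data = simulate_case_control(cfg)
            # add a group shift orthogonal to the planted balance
            e_ilr = data.element.clr().coords @ data.basis.psi.T
            g = np.random.default_rng(seed).standard_normal(5)
            g -= (g @ e_ilr) * e_ilr
            g *= 0.5 / np.linalg.norm(g)
            Y = data.Y + np.outer(data.x, g)
            design = RegressionDesign.build(Y, data.x, data.basis)
            fit = fit_single_balance(design)
            res = orthogonal_complement_test(design, fit, n_permutations=99,
                                             seed=seed)
            hits += res["p_value"] < 0.05
        assert hits >= 9

    def test_minimum_permutations_enforced(self):
        data = simulate_case_control(CaseControlSimConfig(d=6, n_per_group=20, seed=0))
        design, fit = self._fit(data)
        with pytest.raises(ValueError, match="99"):
            orthogonal_complement_test(design, fit, n_permutations=10)


class TestClassification:
    def test_separated_groups_auc_one(self):
        data = simulate_case_control(
            CaseControlSimConfig(d=8, n_per_group=50, seed=2, noise_to_shift=0.02)
        )
        design = RegressionDesign.build(data.Y, data.x, data.basis)
        fit = fit_single_balance(design)
        _, auc = classify_by_balance(fit, data.Y, labels=data.x)
        assert auc == pytest.approx(1.0, abs=1e-6)

    def test_null_labels_auc_half(self):
        aucs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            data = simulate_case_control(
                CaseControlSimConfig(d=8, n_per_group=40, seed=seed)
            )
            design = RegressionDesign.build(data.Y, data.x, data.basis)
            fit = fit_single_balance(design)
            shuffled = rng.permutation(data.x)
            _, auc = classify_by_balance(fit, data.Y, labels=shuffled)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        data = simulate_case_control(CaseControlSimConfig(d=6, n_per_group=20, seed=0))
        design = RegressionDesign.build(data.Y, data.x, data.basis)
        fit = fit_single_balance(design)
        with pytest.raises(ValueError, match="both classes"):
            classify_by_balance(fit, data.Y, labels=np.zeros(40))


class TestModelSurface:
    def test_from_compositions_and_summary(self, rng):
        import pandas as pd

        labels = tuple(f"t{i}" for i in range(1, 7))
        cfg = CaseControlSimConfig(d=6, n_per_group=30, seed=9)
        data = simulate_case_control(cfg)
        clr_rows = data.Y @ data.basis.psi
        props = np.exp(clr_rows)
        props /= props.sum(axis=1, keepdims=True)
        table = pd.DataFrame(props.T, index=labels,
                             columns=[f"s{i}" for i in range(60)])
        model = SingleBalanceRegression.from_compositions(table, data.x)
        res = model.fit()
        assert taxon_accuracy(data.element, res.balance.element) == 1.0
        text = res.summary()
        assert "numerator" in text and "impact" in text
        payload = res.to_dict()
        assert set(payload) >= {"numerator", "denominator", "impact", "r_squared"}
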