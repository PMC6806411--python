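import numpy as np
import pandas as pd
import pytest

from qsarpipe import (
    MLRModel,
    SyntheticSpec,
    ValidationReport,
    acceptance_checklist,
    adjusted_r2,
    coefficient_inference,
    contribution_percents,
    crp2,
    f_statistic,
    fit_mlr,
    generate_dataset,
    pearson_matrix,
    predict,
    q2_loo,
    r2_external,
    r_squared,
    standardized_contributions,
    summarize_randomization,
    validate_model,
    vif,
    y_randomization,
)
from qsarpipe.validation import loo_predictions, randomization_permutations


class TestRSquared:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_formula_oracle(self):
        y = np.array([1.0, 4.0, 2.0, 8.0])
        yhat = np.array([1.5, 3.0, 2.5, 7.0])
        sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
        sst = sum((a - y.mean()) ** 2 for a in y)
        assert r_squared(y, yhat) == pytest.approx(1 - sse / sst)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestAdjustedR2:
    def test_printed_value(self):
        # printed R^2 0.9156, n=36, p=6 -> 0.8981 (paper's 0.8982 came from
        # the unrounded R^2)
        assert round(adjusted_r2(0.9156, 36, 6), 4) == 0.8981

    def test_p_zero_identity(self):
        assert adjusted_r2(0.7, 10, 0) == pytest.approx(0.7)

    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 25, 5) == 1.0

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, 7, 6)


class TestQ2LOO:
    def test_noise_free_is_one(self, noise_free):
        ds, truth = noise_free
        assert q2_loo(ds.X[truth.descriptor_names], ds.y.to_numpy()) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_intercept_only_hand_case(self):
        X = np.empty((3, 0))
        y = np.array([0.0, 1.0, 2.0])
        preds = loo_predictions(X, y, names=[])
        np.testing.assert_allclose(preds, [1.5, 1.0, 0.5])
        assert q2_loo(X, y, names=[]) == pytest.approx(1 - 4.5 / 2)

    def test_press_identity_against_hat_matrix(self):
        # independent oracle: r_i / (1 - h_ii) from the full-data fit
        rng = np.random.default_rng(12)
        X = rng.standard_normal((25, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.3 * rng.standard_normal(25)
        preds = loo_predictions(X, y)
        design = np.column_stack([np.ones(25), X])
        hat = design @ np.linalg.solve(design.T @ design, design.T)
        resid = y - hat @ y
        loo_resid = resid / (1.0 - np.diag(hat))
        np.testing.assert_allclose(y - preds, loo_resid, atol=1e-10)

    def test_q2_below_r2_on_noisy_data(self, noisy_small):
        ds, truth = noisy_small
        names = truth.descriptor_names
        model = fit_mlr(ds.X[names], ds.y.to_numpy(), names)
        q2 = q2_loo(ds.X[names], ds.y.to_numpy())
        assert q2 < model.r2


class TestR2External:
    @staticmethod
    def _setup():
        model = MLRModel(1.0, {"x": 2.0})
        X_test = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        return model, X_test

    def test_perfect_predictions_both_variants(self):
        model, X = self._setup()
        y = predict(model, X)
        for variant in ("standard", "as_printed"):
            assert r2_external(model, X, y, y_train_mean=2.0, variant=variant) == 1.0

    def test_degenerate_case_distinguishes_variants(self):
        model = MLRModel(5.0, {"x": 0.0})  # predicts the train mean everywhere
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        y = np.array([4.0, 5.0, 6.0])
        assert r2_external(model, X, y, y_train_mean=5.0) == pytest.approx(0.0)
        with pytest.raises(ZeroDivisionError):
            r2_external(model, X, y, y_train_mean=5.0, variant="as_printed")

    def test_five_point_hand_case(self):
        model, X = self._setup()
        y = np.array([1.2, 2.9, 5.3, 6.8, 9.1])
        ybar = 4.0
        yhat = 1.0 + 2.0 * X["x"].to_numpy()
        sse = float(np.sum((yhat - y) ** 2))
        standard = 1 - sse / float(np.sum((y - ybar) ** 2))
        printed = 1 - sse / float(np.sum((yhat - ybar) ** 2))
        assert r2_external(model, X, y, ybar) == pytest.approx(standard)
        assert r2_external(model, X, y, ybar, variant="as_printed") == pytest.approx(printed)


class TestContributions:
    def test_table2_percent_replay(self, fixture_model):
        bstar = [fixture_model.table2_contributions[n][0]
                 for n in fixture_model.descriptor_order]
        expected = [fixture_model.table2_contributions[n][1]
                    for n in fixture_model.descriptor_order]
        got = contribution_percents(bstar)
        assert [round(g, 1) for g in got] == expected

    def test_equal_bstar_equal_percents(self):
        assert contribution_percents([0.5, -0.5, 0.5, -0.5]) == pytest.approx([25.0] * 4)

    def test_unit_standardization(self):
        # s_j == S_y and b_j == 1 -> b* == 1
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        y = x + 10.0  # same spread, coefficient 1
        model = MLRModel(10.0, {"x": 1.0})
        contrib = standardized_contributions(model, x[:, None], y)
        assert contrib["x"][0] == pytest.approx(1.0)

    def test_percents_sum_to_100(self, noisy_small):
        ds, truth = noisy_small
        names = truth.descriptor_names
        model = fit_mlr(ds.X[names], ds.y.to_numpy(), names)
        contrib = standardized_contributions(model, ds.X, ds.y.to_numpy())
        assert sum(p for _, p in contrib.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_sy_errors(self):
        model = MLRModel(0.0, {"x": 1.0})
        with pytest.raises(ValueError):
            standardized_contributions(model, np.arange(5.0)[:, None], np.ones(5))


class TestPearsonMatrix:
    def test_identical_columns(self):
        x = np.arange(6.0)
        m = pearson_matrix(np.column_stack([x, x]))
        assert m.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_column(self):
        x = np.arange(6.0)
        m = pearson_matrix(np.column_stack([x, -x]))
        assert m.iloc[0, 1] == pytest.approx(-1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 3))
        m = pearson_matrix(X).to_numpy()
        for i in range(3):
            for j in range(3):
                a, b = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                expected = float(a @ b / np.sqrt((a @ a) * (b @ b)))
                assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError):
            pearson_matrix(np.column_stack([np.ones(5), np.arange(5.0)]))


class TestVIF:
    def test_orthogonal_is_one(self):
        rng = np.random.default_rng(7)
        raw = rng.standard_normal((20, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # exactly uncorrelated
        out = vif(q)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_two_variable_closed_form(self):
        r = 0.6377
        corr = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = vif(corr)
        expected = 1.0 / (1.0 - r * r)
        assert out["a"] == pytest.approx(expected, abs=1e-12)
        assert round(out["a"], 4) == 1.6854

    def test_printed_matrix_recomputation(self, fixture_model):
        """VIFs the printed 6x6 matrix actually implies (frozen values).

        Note these do NOT match the paper's printed VIF column for
        GGI10/RDF75u — the two tables are mutually inconsistent in the
        source; see the acceptance suite.
        """
        corr = pd.DataFrame(
            np.array(fixture_model.table4_correlations),
            index=fixture_model.descriptor_order,
            columns=fixture_model.descriptor_order,
        )
        out = vif(corr)
        expected = {"ALogP": 1.5168, "AATS7i": 1.4099, "ATSC3p": 1.4350,
                    "IC2": 1.4857, "GGI10": 1.9480, "RDF75u": 1.8950}
        for name, v in expected.items():
            assert out[name] == pytest.approx(v, abs=5e-4)

    def test_matches_explicit_regressions(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.3 * rng.standard_normal(40)
        out = vif(X)
        for j, name in enumerate(out):
            others = np.delete(X, j, axis=1)
            model = fit_mlr(others, X[:, j])
            expected = 1.0 / (1.0 - model.r2)
            assert out[name] == pytest.approx(expected, abs=1e-8)

    def test_singular_matrix_errors(self):
        x = np.arange(10.0)
        with pytest.raises(np.linalg.LinAlgError):
            vif(np.column_stack([x, x]))


class TestCoefficientInference:
    def test_noise_free_infinite_t(self, noise_free):
        ds, truth = noise_free
        names = truth.descriptor_names
        model = fit_mlr(ds.X[names], ds.y.to_numpy(), names)
        inf_rec = coefficient_inference(model, ds.X[names], ds.y.to_numpy())
        for name in names:
            assert inf_rec[name]["t"] in (float("inf"), float("-inf")) or abs(
                inf_rec[name]["t"]) > 1e6

    def test_single_descriptor_textbook_formulas(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(15)
        y = 2.0 + 1.5 * x + 0.4 * rng.standard_normal(15)
        model = fit_mlr(x[:, None], y, ["x"])
        rec = coefficient_inference(model, x[:, None], y)
        # textbook simple-regression standard error of the slope
        resid = y - (model.intercept + model.coefficients["x"] * x)
        s2 = resid @ resid / (15 - 2)
        se_slope = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        assert rec["x"]["se"] == pytest.approx(se_slope, abs=1e-12)
        assert rec["x"]["t"] == pytest.approx(model.coefficients["x"] / se_slope)

    def test_null_descriptor_type_one_error(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)  # coefficient truly zero
            model = fit_mlr(x[:, None], y, ["x"])
            rec = coefficient_inference(model, x[:, None], y)
            if rec["x"]["p"] < 0.05:
                hits += 1
        assert 0.045 * n_rep <= hits <= 0.055 * n_rep


class TestYRandomization:
    def test_permutations_preserve_multiset(self):
        for perm in randomization_permutations(30, 10, seed=4):
            assert sorted(perm.tolist()) == list(range(30))

    def test_strong_signal_breaks_under_permutation(self, noisy_small):
        ds, truth = noisy_small
        names = truth.descriptor_names
        result = y_randomization(ds.X[names], ds.y.to_numpy(),
                                 n_iterations=10, seed=77)
        assert result.original[1] > 0.9
        assert result.average_r2 < 0.3
        assert result.crp2 > 0.5
        assert result.n_iterations == 10

    def test_table5_fixture_replay(self, fixture_model):
        result = summarize_randomization(
            fixture_model.table5_randomized, fixture_model.table5_original
        )
        assert result.average_r == pytest.approx(0.3599, abs=5.1e-5)
        assert result.average_r2 == pytest.approx(0.1363, abs=5.1e-5)
        assert result.average_q2 == pytest.approx(-0.3555, abs=5.1e-5)

    def test_zero_iterations_errors(self, noisy_small):
        ds, truth = noisy_small
        with pytest.raises(ValueError):
            y_randomization(ds.X[truth.descriptor_names], ds.y.to_numpy(),
                            n_iterations=0, seed=1)


class TestCRP2:
    def test_printed_inputs(self):
        # R=0.9545, R^2=0.9111, Rr=0.3599 -> 0.8438 (paper prints 0.8439
        # from unrounded inputs)
        assert crp2(0.9545, 0.3599, r2_original=0.9111) == pytest.approx(
            0.8438, abs=1e-4
        )

    def test_zero_rr_gives_r2(self):
        assert crp2(0.9, 0.0) == pytest.approx(0.81)

    def test_r_equals_rr_gives_zero(self):
        assert crp2(0.4, 0.4) == 0.0

    def test_randomized_better_than_original_errors(self):
        with pytest.raises(ValueError):
            crp2(0.3, 0.5)


class TestChecklist:
    @staticmethod
    def _paper_report(fixture_model, **overrides):
        coeffs = {
            name: {"estimate": fixture_model.coefficients[name], "se": 1.0,
                   "t": fixture_model.table4_t[name], "p": 0.0}
            for name in fixture_model.descriptor_order
        }
        values = dict(
            r2=0.911, r2_adjusted=0.893, see=0.3, f_statistic=52.0,
            q2_loo=0.870, r2_test=0.585, n_train=36, n_test=14,
            coefficients=coeffs, vif=dict(fixture_model.table4_vif),
            pearson=pd.DataFrame(np.array(fixture_model.table4_correlations),
                                 index=fixture_model.descriptor_order,
                                 columns=fixture_model.descriptor_order),
            contributions={n: tuple(fixture_model.table2_contributions[n])
                           for n in fixture_model.descriptor_order},
        )
        values.update(overrides)
        return ValidationReport(**values)

    def test_paper_values_all_pass(self, fixture_model):
        report = self._paper_report(fixture_model)
        yrand = summarize_randomization(
            fixture_model.table5_randomized, fixture_model.table5_original
        )
        out = acceptance_checklist(report, yrand, n_test=14)
        failing = [k for k, v in out.items()
                   if k != "overall" and v["verdict"] != "pass"]
        assert failing == []
        assert out["overall"]["verdict"] == "pass"

    def test_low_r2_fails(self, fixture_model):
        report = self._paper_report(fixture_model, r2=0.5)
        yrand = summarize_randomization(
            fixture_model.table5_randomized, fixture_model.table5_original
        )
        out = acceptance_checklist(report, yrand, n_test=14)
        assert out["r2"]["verdict"] == "fail"
        assert out["overall"]["verdict"] == "fail"

    def test_r2_q2_gap_rule(self, fixture_model):
        report = self._paper_report(fixture_model, r2=0.95, q2_loo=0.55)
        yrand = summarize_randomization(
            fixture_model.table5_randomized, fixture_model.table5_original
        )
        out = acceptance_checklist(report, yrand, n_test=14)
        assert out["r2_minus_q2"]["verdict"] == "fail"
        assert out["overall"]["verdict"] == "fail"

    def test_missing_field_not_evaluable(self, fixture_model):
        report = self._paper_report(fixture_model, r2_test=None, n_test=None)
        out = acceptance_checklist(report, None, n_test=None)
        assert out["r2_test"]["verdict"] == "not evaluable"
        assert out["crp2"]["verdict"] == "not evaluable"
        assert out["overall"]["verdict"] == "fail"


class TestValidateModel:
    def test_full_battery_on_synthetic(self, noisy_small):
        ds, truth = noisy_small
        names = truth.descriptor_names
        model = fit_mlr(ds.X[names], ds.y.to_numpy(), names)
        report = validate_model(model, ds)
        assert report.q2_loo <= report.r2
        assert all(v >= 1.0 - 1e-12 for v in report.vif.values())
        assert sum(p for _, p in report.contributions.values()) == pytest.approx(100.0)
        assert report.f_statistic > 0

    def test_f_statistic_formula(self):
        assert f_statistic(0.5, 12, 2) == pytest.approx((0.5 / 2) / (0.5 / 9))


class TestParameterRecovery:
    def test_bias_vanishes_as_noise_shrinks(self):
        biases = []
        for noise in (0.5, 0.05):
            errs = []
            for seed in range(5):
                spec = SyntheticSpec(
                    n_compounds=36, n_descriptors=10, n_correlated_blocks=0,
                    n_near_constant=0, true_support=(1, 4, 8),
                    true_coefficients=(1.0, -0.8, 0.6), noise_sd=noise,
                    activity_range_target=None, seed=100 + seed,
                )
                ds, truth = generate_dataset(spec)
                names = truth.descriptor_names
                model = fit_mlr(ds.X[names], ds.y.to_numpy(), names)
                errs.append(np.mean([
                    abs(model.coefficients[n] - truth.coefficients[n]) for n in names
                ]))
            biases.append(np.mean(errs))
        assert biases[1] < biases[0] / 3
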