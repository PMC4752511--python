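"""OLS against a normal-equations oracle; hinge-regression breakpoint
recovery; clinical-score regressions."""

import numpy as np
import pandas as pd
import pytest

from antirace.regression import (
    HingeRegression,
    clinical_regressions,
    mars_fit,
    ols_fit,
    stage_regression,
)


class TestOls:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = ols_fit(pd.DataFrame({"x": x}), 2.0 * x)
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_response_low_r2(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        res = ols_fit(X, rng.normal(size=500))
        assert res.r_squared < 0.05

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        beta = np.array([1.5, -2.0, 0.3, 0.0])
        y = 0.7 + X @ beta + rng.normal(scale=0.1, size=80)
        res = ols_fit(pd.DataFrame(X, columns=list("wxyz")), y)
        Xc = np.column_stack([np.ones(80), X])
        oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(res.coefficients.to_numpy(), oracle, atol=1e-8)
        assert res.adj_r_squared <= res.r_squared

    def test_rank_deficient_design_raises(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(X, x)

    def test_listwise_deletion(self):
        x = np.arange(30.0)
        X = pd.DataFrame({"x": x})
        y = 3.0 * x
        X.loc[5, "x"] = np.nan
        res = ols_fit(X, y)
        assert res.n_obs == 29


class TestHingeRegression:
    def test_recovers_planted_breakpoint(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 4, 200)
        y = -1.5 * np.maximum(0.0, x - 2.0) + rng.normal(scale=0.05, size=200)
        hm = mars_fit(x, y)
        assert len(hm.hinges_) == 1
        knot, coef = hm.hinges_[0]
        assert 1.75 <= knot <= 2.25
        assert coef == pytest.approx(-1.5, abs=0.15)

    def test_linear_response_keeps_no_hinge(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 4, 200)
        y = 1.0 - 0.8 * x + rng.normal(scale=0.2, size=200)
        hm = mars_fit(x, y)
        assert hm.hinges_ == []
        assert hm.slope_ == pytest.approx(-0.8, abs=0.1)

    def test_constant_response(self):
        x = np.linspace(0, 4, 50)
        hm = mars_fit(x, np.full(50, 3.0))
        assert hm.hinges_ == []
        assert hm.slope_ == pytest.approx(0.0, abs=1e-10)
        assert hm.intercept_ == pytest.approx(3.0)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant predictor"):
            HingeRegression().fit(np.ones(30), np.arange(30.0))

    def test_prediction_reproduces_training_signal(self):
        x = np.linspace(0, 4, 41)  # grid contains the knot at 1.5
        y = 2.0 + 0.5 * x - 1.0 * np.maximum(0.0, x - 1.5)
        hm = HingeRegression().fit(x, y)
        np.testing.assert_allclose(hm.predict(x), y, atol=1e-8)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mars_fit(np.arange(10.0), np.arange(10.0))


def _params_table(rng, n=300, planted=True):
    stage = rng.integers(0, 5, size=n)
    v_exec = 7.1 - (0.6 * stage if planted else 0.0) + rng.normal(0, 0.8, n)
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "stage": stage,
            "v_pre": 5.2 + rng.normal(0, 0.8, n),
            "v_inhib": 6.0 - (planted * 1.2) * np.maximum(0, stage - 2) + rng.normal(0, 0.8, n),
            "v_exec": v_exec,
            "a_mean": 1.0 + rng.normal(0, 0.1, n),
            "t": 0.15 + rng.normal(0, 0.02, n),
            "t_exec": 0.05 + rng.normal(0, 0.01, n).clip(-0.04),
        }
    )
    return table


class TestClinicalRegressions:
    def test_planted_link_gives_negative_v_exec_slope(self):
        rng = np.random.default_rng(21)
        table = _params_table(rng)
        tms = np.round(np.exp(0.7 + 0.7 * table["stage"] + rng.normal(0, 0.4, len(table)))) - 1
        clinical = pd.DataFrame(
            {
                "subject_id": table["subject_id"],
                "tms": tms.clip(lower=0),
                "tfc": (13 - table["stage"] + rng.normal(0, 0.5, len(table))).clip(0, 13),
                "cag": np.round(rng.normal(43, 3, len(table))),
            }
        )
        rep = clinical_regressions(table, clinical)
        assert rep.models["log_tms"].coefficients["v_exec"] < 0
        assert rep.models["log_tms"].r_squared > 0.1

    def test_independent_scores_low_r2(self):
        rng = np.random.default_rng(22)
        table = _params_table(rng, planted=False)
        clinical = pd.DataFrame(
            {
                "subject_id": table["subject_id"],
                "tms": rng.integers(0, 40, len(table)).astype(float),
                "tfc": rng.integers(5, 14, len(table)).astype(float),
                "cag": np.round(rng.normal(43, 3, len(table))),
            }
        )
        rep = clinical_regressions(table, clinical)
        for res in rep.models.values():
            assert res.r_squared < 0.05

    def test_no_overlap_raises(self):
        rng = np.random.default_rng(23)
        table = _params_table(rng, n=30)
        clinical = pd.DataFrame({"subject_id": ["zz1"], "tms": [5.0]})
        with pytest.raises(ValueError):
            clinical_regressions(table, clinical)


def test_regression_of_variable_on_itself_is_perfect():
    y = np.random.default_rng(24).normal(size=50)
    res = ols_fit(pd.DataFrame({"y": y}), y)
    assert res.r_squared == pytest.approx(1.0)


def test_stage_regression_recovers_planted_direction():
    table = _params_table(np.random.default_rng(25))
    res = stage_regression(table)
    assert res.coefficients["v_exec"] < 0
    assert res.r_squared > 0.2
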