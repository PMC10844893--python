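"""Cox partial likelihood, risk stratification, KM/log-rank and exact Spearman."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import histocomp as hc
from histocomp.errors import EmptyResultError, MissingGeneError, SeparationError
from histocomp.survival import CONTRAST_ACINAR, CONTRAST_LEPIDIC


def _toy6():
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 1, 1],
        "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    }, index=[f"s{i}" for i in range(6)])


def _breslow_loglik(beta, df):
    """Independent scalar oracle: direct Breslow partial likelihood."""
    ll = 0.0
    for i in df.index[df["event"] == 1]:
        risk = df.index[df["time"] >= df.at[i, "time"]]
        ll += beta * df.at[i, "x"] - math.log(
            sum(math.exp(beta * df.at[j, "x"]) for j in risk))
    return ll


def test_cox_matches_grid_search_oracle():
    df = _toy6()
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = [_breslow_loglik(b, df) for b in grid]
    b_star = grid[int(np.argmax(lls))]
    model = hc.cox_fit(df, ["x"])
    assert abs(float(model.coef["x"]) - b_star) < 1e-3
    assert model.converged


def test_cox_gradient_norm_small_at_solution():
    df = _toy6()
    model = hc.cox_fit(df, ["x"])
    b = float(model.coef["x"])
    num_grad = (_breslow_loglik(b + 1e-6, df) - _breslow_loglik(b - 1e-6, df)) / 2e-6
    assert abs(num_grad) < 1e-6


def test_cox_null_covariate_coef_near_zero():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"time": rng.exponential(1, 400),
                       "event": 1,
                       "x": np.tile([0.0, 1.0], 200)})
    model = hc.cox_fit(df, ["x"])
    assert abs(float(model.coef["x"])) < 0.25
    assert model.p["x"] > 0.01


def test_cox_parameter_recovery():
    df = hc.simulate_survival_cohort(2000, {"x": 1.0}, seed=1, binary=("x",))
    model = hc.cox_fit(df, ["x"])
    assert abs(float(model.coef["x"]) - 1.0) <= 0.15


def test_cox_agrees_with_independent_implementation():
    from lifelines import CoxPHFitter
    df = hc.simulate_survival_cohort(400, {"x": 0.8, "age": 0.3}, seed=3,
                                     binary=("x",))
    model = hc.cox_fit(df, ["x", "age"])
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", "x", "age"]], "time", "event")
    # continuous times, no ties: Breslow and Efron coincide
    np.testing.assert_allclose(model.coef.to_numpy(),
                               cph.params_[["x", "age"]].to_numpy(), atol=5e-3)


def test_cox_error_paths():
    df = _toy6()
    with pytest.raises(ValueError):
        hc.cox_fit(df.assign(c=1.0), ["c"])
    with pytest.raises(EmptyResultError):
        hc.cox_fit(df.assign(event=0), ["x"])
    sep = pd.DataFrame({"time": [1, 2, 3, 10, 20, 30],
                        "event": [1, 1, 1, 1, 1, 1],
                        "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
    with pytest.raises(SeparationError):
        hc.cox_fit(sep, ["x"])


def test_screen_confounders_power_and_empty():
    hits = 0
    for seed in range(40):
        df = hc.simulate_survival_cohort(500, {"smoking": 2.0}, seed=seed)
        hits += "smoking" in hc.screen_confounders(df, ("smoking",))
    assert hits >= 38          # >= 95% power at beta=2, n=500
    df = hc.simulate_survival_cohort(100, seed=0)
    assert hc.screen_confounders(df, ()) == []


def test_screen_confounders_type_one_calibration():
    hits = 0
    n_rep = 150
    for seed in range(n_rep):
        df = hc.simulate_survival_cohort(150, None, seed=10_000 + seed)
        hits += "sex" in hc.screen_confounders(df, ("sex",))
    rate = hits / n_rep
    assert 0.005 <= rate <= 0.11   # ~5% nominal


def test_risk_score_formula():
    coef = pd.Series({"g1": 0.5, "g2": -1.0})
    expr = pd.DataFrame({"g1": [1.0, 2.0], "g2": [2.0, 2.0]}, index=["p1", "p2"])
    scores = hc.risk_score(coef, expr)
    np.testing.assert_allclose(scores, [-1.5, -1.0])
    np.testing.assert_allclose(hc.risk_score(coef * 0, expr), 0.0)
    with pytest.raises(MissingGeneError, match="g3"):
        hc.risk_score(pd.Series({"g3": 1.0}), expr)


def test_stratify_four_groups_rules():
    lep = pd.Series({"a": 1.0, "b": -1.0, "c": 1.0, "d": -1.0})
    aci = pd.Series({"a": -1.0, "b": 1.0, "c": 1.0, "d": -1.0})
    out = hc.stratify_four_groups(lep, aci)
    assert out.loc["a", "group"] == CONTRAST_LEPIDIC
    assert out.loc["b", "group"] == CONTRAST_ACINAR
    assert out.loc["c", "group"] == ""       # concordant high/high excluded
    assert out.loc["d", "group"] == ""       # concordant low/low excluded


def test_stratify_all_equal_scores_everyone_low():
    with pytest.warns(UserWarning):
        out = hc.stratify_four_groups(pd.Series([1.0] * 4), pd.Series([2.0] * 4))
    assert (~out["lepidic_high"]).all() and (~out["acinar_high"]).all()
    assert (out["group"] == "").all()


def test_stratify_anticorrelated_scores_populates_both_groups():
    rng = np.random.default_rng(5)
    lep = pd.Series(rng.normal(size=100))
    out = hc.stratify_four_groups(lep, -lep + rng.normal(0, 0.1, 100))
    counts = out["group"].value_counts()
    assert counts.get(CONTRAST_LEPIDIC, 0) > 20
    assert counts.get(CONTRAST_ACINAR, 0) > 20


def test_km_closed_form_two_subjects():
    km = hc.km_estimate([1.0, 2.0], [1, 1])["all"]["curve"]["survival"]
    assert km.loc[1.0] == pytest.approx(0.5)
    assert km.loc[2.0] == pytest.approx(0.0)
    km = hc.km_estimate([1.0, 2.0], [0, 1])["all"]["curve"]["survival"]
    assert km.loc[1.0] == pytest.approx(1.0)    # censored at 1
    assert km.loc[2.0] == pytest.approx(0.0)
    km = hc.km_estimate([1.0, 2.0], [0, 0])["all"]["curve"]["survival"]
    assert (km == 1.0).all()                    # no events


def test_km_curves_monotone_in_unit_interval():
    df = hc.simulate_survival_cohort(200, seed=8)
    km = hc.km_estimate(df["time"], df["event"])["all"]["curve"]["survival"]
    assert km.iloc[0] == 1.0
    assert ((km.diff().dropna()) <= 1e-12).all()
    assert km.between(0, 1).all()


def test_logrank_identical_groups_and_errors():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1, 1, 1, 1, 1, 1]
    res = hc.logrank_test(times, events, ["a", "a", "a", "b", "b", "b"])
    assert res["statistic"] == pytest.approx(0.0, abs=1e-10)
    assert res["p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hc.logrank_test(times, events, ["a"] * 6)


def test_logrank_power_under_hazard_ratio_two():
    rejections = 0
    for seed in range(50):
        df = hc.simulate_survival_cohort(200, {"x": np.log(2)}, seed=seed,
                                         binary=("x",))
        res = hc.logrank_test(df["time"], df["event"], df["x"])
        rejections += res["p"] < 0.05
    assert rejections >= 40


def test_spearman_reproduces_printed_pair():
    res = hc.spearman_exact([1, 2, 3, 4, 5, 6], [5, 6, 4, 3, 1, 2])
    assert res["method"] == "exact"
    assert round(res["rho"], 3) == -0.886
    assert round(res["p"], 3) == 0.033


def test_spearman_exact_enumeration_cases():
    res = hc.spearman_exact([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
    assert res["rho"] == pytest.approx(1.0)
    assert res["p"] == pytest.approx(2 / 720)
    res = hc.spearman_exact([1, 2, 3], [3, 2, 1])
    assert res["rho"] == pytest.approx(-1.0)
    assert res["p"] == pytest.approx(2 / 6)


def test_spearman_invariances_and_method_flag():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=8), rng.normal(size=8)
    a = hc.spearman_exact(x, y)
    b = hc.spearman_exact(y, x)
    c = hc.spearman_exact(-x, -y)
    assert a["p"] == b["p"] == c["p"]
    assert a["rho"] == pytest.approx(b["rho"]) == pytest.approx(c["rho"])
    big = hc.spearman_exact(rng.normal(size=30), rng.normal(size=30))
    assert big["method"] == "approximate"
    tied = hc.spearman_exact([1, 1, 2, 3, 4], [2, 3, 1, 5, 4])
    assert tied["method"] == "approximate"
    with pytest.raises(ValueError):
        hc.spearman_exact([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_exact_close_to_t_approximation_at_n9():
    rng = np.random.default_rng(1)
    for _ in range(5):
        x, y = rng.normal(size=9), rng.normal(size=9)
        exact = hc.spearman_exact(x, y)
        approx = stats.spearmanr(x, y)
        assert abs(exact["p"] - approx.pvalue) < 0.02


def test_risk_stratification_pipeline_end_to_end():
    beta = {"g1": 0.8, "g2": -0.8, "age": 0.5}
    df = hc.simulate_survival_cohort(300, beta, seed=12)
    result = hc.risk_stratification_pipeline(df, ["g1"], ["g2"])
    assert "age" in result["confounders"]
    assert result["logrank"] is not None
    strata = result["strata"]
    assert set(strata["group"].unique()) >= {CONTRAST_LEPIDIC, CONTRAST_ACINAR}
    # risk scores follow the linear formula
    m = result["models"]["lepidic"]
    np.testing.assert_allclose(
        strata["lepidic_score"],
        df["g1"] * float(m.coef["g1"]), rtol=1e-10)
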