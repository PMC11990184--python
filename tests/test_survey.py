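import numpy as np
import pandas as pd
import pytest

from upfpdi.survey import (
    MODEL2_COVARIATES,
    RankDeficientError,
    SurveyDesign,
    SurveyWLS,
    build_design_matrix,
    filter_cohort,
    fit_index_models,
    moderation_models,
    quintile_table,
    weighted_chi2,
    weighted_estimate,
)


def equal_design(n, r=4, index=None):
    index = index if index is not None else pd.RangeIndex(n)
    pw = pd.Series(1.0, index=index)
    reps = pd.DataFrame(
        np.ones((n, r)) * r / (r - 1), index=index, columns=[f"rw_{i}" for i in range(r)]
    )
    groups = np.arange(n) % r
    arr = reps.to_numpy()
    arr[np.arange(n), groups] = 0.0
    return SurveyDesign(pw, pd.DataFrame(arr, index=index, columns=reps.columns))


# -------------------------------------------------------------- design


def test_design_validation():
    pw = pd.Series([1.0, 2.0])
    with pytest.raises(ValueError, match="replicate"):
        SurveyDesign(pw, pd.DataFrame({"r1": [1.0, 1.0]}))
    with pytest.raises(ValueError, match="positive"):
        SurveyDesign(pd.Series([0.0, 1.0]), pd.DataFrame({"r1": [1, 1], "r2": [1, 1]}))
    d = SurveyDesign(pw, pd.DataFrame({"r1": [1.0, 1.0], "r2": [1.0, 1.0]}))
    assert d.variance_scale == pytest.approx(0.5)  # (R-1)/R with R=2


# -------------------------------------------------------------- estimates


def test_weighted_mean_equals_unweighted_with_equal_weights():
    rng = np.random.default_rng(0)
    v = pd.Series(rng.normal(size=40))
    est, _ = weighted_estimate(v, equal_design(40), "mean")
    assert est == pytest.approx(v.mean())


def test_replicate_se_zero_when_replicates_agree():
    n = 12
    pw = pd.Series(1.0, index=pd.RangeIndex(n))
    reps = pd.DataFrame(np.ones((n, 3)), index=pw.index, columns=list("abc"))
    v = pd.Series(np.arange(n, dtype=float), index=pw.index)
    est, se = weighted_estimate(v, SurveyDesign(pw, reps), "mean")
    assert est == pytest.approx(v.mean())
    assert se == pytest.approx(0.0, abs=1e-12)


def test_replicate_se_matches_hand_formula_three_replicates():
    # values and replicate weights chosen so replicate means are hand-computable
    v = pd.Series([1.0, 2.0, 3.0])
    pw = pd.Series([1.0, 1.0, 1.0])
    reps = pd.DataFrame({"r1": [0.0, 1.5, 1.5], "r2": [1.5, 0.0, 1.5], "r3": [1.5, 1.5, 0.0]})
    design = SurveyDesign(pw, reps, variance_scale=2 / 3)
    est, se = weighted_estimate(v, design, "mean")
    theta = 2.0
    thetas = np.array([2.5, 2.0, 1.5])  # delete-one means
    expected = np.sqrt(2 / 3 * ((thetas - theta) ** 2).sum())
    assert est == pytest.approx(theta)
    assert se == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------------- WLS


def test_wls_matches_normal_equations_oracle():
    rng = np.random.default_rng(1)
    n = 20
    X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    y = pd.Series(1.0 + 2.0 * X["x1"] - 0.5 * X["x2"] + rng.normal(size=n))
    res = SurveyWLS(y, X, equal_design(n)).fit()
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)  # unweighted normal equations
    assert np.allclose(res.params.to_numpy(), beta_oracle, atol=1e-8)


def test_exact_linear_outcome_recovers_slope_with_zero_residual():
    rng = np.random.default_rng(2)
    n = 15
    x = pd.Series(rng.normal(size=n))
    X = pd.DataFrame({"const": 1.0, "x": x})
    y = 2.0 * x
    pw = pd.Series(rng.uniform(0.5, 2.0, n))
    reps = pd.DataFrame({f"r{i}": pw * rng.uniform(0.5, 1.5, n) for i in range(4)})
    res = SurveyWLS(y, X, SurveyDesign(pw, reps)).fit()
    assert res.params["x"] == pytest.approx(2.0, abs=1e-10)
    assert res.bse["x"] == pytest.approx(0.0, abs=1e-10)
    assert res.resid.abs().max() < 1e-10


def test_duplicate_row_with_halved_weight_leaves_estimate_unchanged():
    rng = np.random.default_rng(3)
    n = 10
    x = rng.normal(size=n)
    y = 1 + 0.5 * x + rng.normal(size=n)
    X = pd.DataFrame({"const": 1.0, "x": x})
    pw = pd.Series(np.ones(n))
    reps = pd.DataFrame({"r1": np.ones(n), "r2": np.ones(n)})
    res1 = SurveyWLS(pd.Series(y), X, SurveyDesign(pw, reps)).fit()

    X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
    y2 = pd.Series(np.append(y, y[0]))
    w2 = np.ones(n + 1)
    w2[0] = w2[n] = 0.5
    reps2 = pd.DataFrame({"r1": w2, "r2": w2})
    res2 = SurveyWLS(y2, X2, SurveyDesign(pd.Series(w2), reps2)).fit()
    assert np.allclose(res1.params, res2.params, atol=1e-10)


def test_rank_deficiency_names_collinear_column():
    n = 10
    x = pd.Series(np.arange(n, dtype=float))
    X = pd.DataFrame({"const": 1.0, "x": x, "x_copy": 2 * x})
    with pytest.raises(RankDeficientError, match="rank deficient"):
        SurveyWLS(x, X, equal_design(n)).fit()


def test_results_object_surface():
    rng = np.random.default_rng(4)
    n = 30
    X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
    y = pd.Series(0.3 * X["x"] + rng.normal(size=n))
    res = SurveyWLS(y, X, equal_design(n, r=8)).fit()
    ci = res.conf_int()
    assert (ci["ci_low"] <= res.params).all() and (res.params <= ci["ci_high"]).all()
    assert ((res.pvalues >= 0) & (res.pvalues <= 1)).all()
    text = res.summary()
    assert "x" in text and "coef" in text
    # p monotone in |z|
    order_p = res.pvalues.rank()
    order_z = (-res.tvalues.abs()).rank()
    assert (order_p == order_z).all()


# -------------------------------------------------------------- chi2


def test_chi2_hand_example_2x2():
    a = pd.Series(["x"] * 30 + ["y"] * 30)
    b = pd.Series(["u"] * 10 + ["v"] * 20 + ["u"] * 20 + ["v"] * 10)
    stat, df, p = weighted_chi2(a, b, equal_design(60))
    assert stat == pytest.approx(20 / 3, abs=1e-9)  # 6.667
    assert df == 1


def test_chi2_zero_for_homogeneous_table():
    a = pd.Series(["x", "x", "y", "y"] * 5)
    b = pd.Series(["u", "v", "u", "v"] * 5)
    stat, _, p = weighted_chi2(a, b, equal_design(20))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_rao_scott_correction_shrinks_statistic_under_clustering(small_analysis):
    table, design, _ = small_analysis
    q = pd.Series(
        pd.qcut(table["updi"], 5, labels=False, duplicates="drop") + 1, index=table.index
    ).astype(str)
    raw, _, _ = weighted_chi2(table["education"], q, design, rao_scott=False)
    corr, _, _ = weighted_chi2(table["education"], q, design, rao_scott=True)
    assert corr > 0 or raw == 0
    assert corr != raw  # correction engaged


# -------------------------------------------------------------- cohort filter


def test_filter_cohort_sequential_ledger():
    n = 100
    df = pd.DataFrame(
        {
            "age": [15.0] * 10 + [30.0] * 90,
            "pregnant": [False] * 10 + [True] * 2 + [False] * 88,
            "breastfeeding": False,
            "missing_upf": False,
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="participant_id"),
    )
    kept, ledger = filter_cohort(df)
    assert ledger["under19"] == 10
    assert ledger["pregnant"] == 2
    assert ledger["breastfeeding"] == 0
    assert ledger["included"] == 88
    assert len(kept) == 88


def test_filter_cohort_identity_when_nothing_flagged():
    df = pd.DataFrame(
        {"age": [25.0, 40.0], "pregnant": False, "breastfeeding": False},
        index=pd.Index(["A", "B"], name="participant_id"),
    )
    kept, ledger = filter_cohort(df)
    assert len(kept) == 2 and ledger["included"] == 2


# -------------------------------------------------------------- table shapes


def test_fit_index_models_shape_and_constant_covariate(small_analysis):
    table, design, _ = small_analysis
    out = fit_index_models(table, design)
    assert len(out) == 9
    assert set(out["model"]) == {"crude", "model1", "model2"}
    # constant ei_bmr_ratio makes model 2 collapse onto model 1
    t2 = table.copy()
    t2["ei_bmr_ratio"] = 1.3
    out2 = fit_index_models(t2, design)
    m1 = out2[out2.model == "model1"].set_index("index")["beta"]
    m2 = out2[out2.model == "model2"].set_index("index")["beta"]
    assert np.allclose(m1, m2, atol=1e-8)


def test_quintile_table_flat_variable_has_no_trend(small_analysis):
    table, design, _ = small_analysis
    t = table.copy()
    t["energy_kcal"] = 2000.0
    out = quintile_table(t, design, "updi")
    row = out[out["row"] == "energy_kcal"].iloc[0]
    means = [row[f"q{k}"] for k in range(1, 6)]
    assert np.allclose(means, 2000.0, atol=1e-9)
    # the trend slope itself is exactly zero (up to float noise)
    t["quintile"] = 1.0 + (t["updi"].rank(pct=True) * 5).clip(upper=5).astype(int).clip(1, 5)
    res = SurveyWLS.from_dataframe(t, "energy_kcal", ["quintile"], design).fit()
    assert abs(res.params["quintile"]) < 1e-9


def test_moderation_sign_flip_when_reference_level_swapped(small_analysis):
    table, design, _ = small_analysis
    out = moderation_models(table, design, moderators=("sex",))
    inter = out[(out.model == "interaction") & (out["index"] == "updi")].iloc[0]
    # recode the binary moderator: swapping levels flips the interaction beta
    flipped = table.copy()
    flipped["sex"] = np.where(flipped["sex"] == "female", "male", "female")
    out_f = moderation_models(flipped, design, moderators=("sex",))
    inter_f = out_f[(out_f.model == "interaction") & (out_f["index"] == "updi")].iloc[0]
    assert inter["beta"] == pytest.approx(-inter_f["beta"], abs=1e-8)


def test_design_matrix_levels_and_unknown_level():
    df = pd.DataFrame({"age": [30.0, 40.0], "sex": ["male", "female"]})
    X = build_design_matrix(df, ["age", "sex"])
    assert list(X.columns) == ["const", "age", "sex[female]"]
    df_bad = pd.DataFrame({"sex": ["male", "robot"]})
    with pytest.raises(ValueError, match="robot"):
        build_design_matrix(df_bad, ["sex"])
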