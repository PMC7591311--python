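"""Boosted-tree ensemble and Friedman relative influence."""

import numpy as np
import pandas as pd
import pytest

from nutrineq.exceptions import DegenerateDataError, ValidationError
from nutrineq.influence import (
    BoostConfig,
    GradientBoostedTrees,
    fit_brt,
    rank_risk_factors,
    select_n_trees,
)


@pytest.fixture(scope="module")
def single_signal_data():
    rng = np.random.default_rng(42)
    n = 1000
    signal = rng.integers(0, 2, n)
    X = pd.DataFrame({"signal": signal,
                      **{f"noise{i}": rng.integers(0, 2, n) for i in range(7)}})
    return signal.astype(float), X


def test_config_validation():
    with pytest.raises(ValidationError):
        BoostConfig(bag_fraction=1.5)
    with pytest.raises(ValidationError):
        BoostConfig(max_depth=0)


def test_constant_predictors_rejected():
    y = np.array([0, 1] * 20)
    X = pd.DataFrame({"a": np.zeros(40), "b": np.ones(40)})
    with pytest.raises(DegenerateDataError):
        fit_brt(y, X)


def test_zero_learning_rate_keeps_base_rate(single_signal_data):
    y, X = single_signal_data
    res = fit_brt(y, X, BoostConfig(n_trees=5, learning_rate=0.0, seed=1))
    p = res.predict_proba(X.to_numpy())
    assert np.allclose(p, y.mean())


def test_training_deviance_decreases_at_small_rate(single_signal_data):
    y, X = single_signal_data
    res = fit_brt(y, X, BoostConfig(n_trees=150, learning_rate=0.01, max_depth=2, seed=5))
    assert np.all(np.diff(res.deviance_path) <= 1e-9)


def test_influences_sum_to_100_and_signal_dominates(single_signal_data):
    y, X = single_signal_data
    res = fit_brt(y, X, BoostConfig(n_trees=200, learning_rate=0.1, max_depth=2, seed=3))
    rep = res.relative_influence()
    assert (rep.influence >= 0).all()
    assert rep.influence.sum() == pytest.approx(100.0, abs=1e-9)
    assert rep.influence["signal"] >= 90.0
    assert rep.ordering[0] == "signal"


def test_seed_reproducibility(single_signal_data):
    y, X = single_signal_data
    cfg = BoostConfig(n_trees=40, learning_rate=0.1, seed=9)
    a = fit_brt(y, X, cfg)
    b = fit_brt(y, X, cfg)
    assert np.array_equal(a.deviance_path, b.deviance_path)
    assert a.relative_influence().influence.equals(b.relative_influence().influence)
    c = fit_brt(y, X, BoostConfig(n_trees=40, learning_rate=0.1, seed=10))
    assert not np.array_equal(a.deviance_path, c.deviance_path)


def test_column_order_invariance(single_signal_data):
    y, X = single_signal_data
    cfg = BoostConfig(n_trees=60, learning_rate=0.1, seed=4)
    a = fit_brt(y, X, cfg).relative_influence().influence
    cols = list(X.columns)[::-1]
    b = fit_brt(y, X[cols], cfg).relative_influence().influence
    for name in X.columns:
        assert b[name] == pytest.approx(a[name], abs=1e-9)


def test_no_splits_is_an_error():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 30).astype(float)
    X = pd.DataFrame({"a": rng.integers(0, 2, 30), "b": rng.integers(0, 2, 30)})
    res = fit_brt(y, X, BoostConfig(n_trees=5, min_node=20, seed=1))  # nodes can't split
    with pytest.raises(DegenerateDataError, match="no structure"):
        res.relative_influence()


def test_duplicated_predictor_shares_influence(single_signal_data):
    y, X = single_signal_data
    X2 = X.copy()
    X2["signal_copy"] = X2["signal"]
    combined = []
    for seed in (1, 2, 3):
        rep = fit_brt(y, X2, BoostConfig(n_trees=150, learning_rate=0.1,
                                         max_depth=2, seed=seed)).relative_influence()
        combined.append(rep.influence["signal"] + rep.influence["signal_copy"])
        assert (rep.influence >= 0).all()
    assert np.mean(combined) >= 90.0


def test_select_n_trees_returns_valid_count(single_signal_data):
    y, X = single_signal_data
    cfg = BoostConfig(n_trees=30, learning_rate=0.1, seed=2)
    m = select_n_trees(y, X, cfg, n_folds=3)
    assert 1 <= m <= 30


def test_ranking_agrees_with_reference_implementation(single_signal_data):
    """Ordering (not values) cross-checked against an established GBM library."""
    sklearn = pytest.importorskip("sklearn.ensemble")
    rng = np.random.default_rng(7)
    n = 800
    strong = rng.integers(0, 2, n)
    weak = rng.integers(0, 2, n)
    lp = -1.0 + 2.0 * strong + 0.7 * weak
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    X = pd.DataFrame({"strong": strong, "weak": weak,
                      **{f"noise{i}": rng.integers(0, 2, n) for i in range(4)}})
    ours = fit_brt(y, X, BoostConfig(n_trees=200, learning_rate=0.1,
                                     max_depth=2, seed=1)).relative_influence()
    ref = sklearn.GradientBoostingClassifier(
        n_estimators=200, learning_rate=0.1, max_depth=2, random_state=1
    ).fit(X, y)
    ref_rank = pd.Series(ref.feature_importances_, index=X.columns)
    assert ours.ordering[0] == ref_rank.idxmax() == "strong"
    assert ours.ordering[1] == "weak"
    assert ref_rank.sort_values(ascending=False).index[1] == "weak"


def test_rank_risk_factors_shape_and_na(ne_survey_small):
    from nutrineq.pipeline import build_analysis_frame

    frame = build_analysis_frame(ne_survey_small.children, ne_survey_small.households)
    frame = frame.copy()
    frame["water_source"] = "improved"  # force a zero-variance indicator
    cfg = BoostConfig(n_trees=80, learning_rate=0.1, seed=11)
    rep = rank_risk_factors(frame, "stunted", region="north_eastern", config=cfg)
    assert np.isnan(rep.influence["nonimproved_water_source"])
    assert rep.influence.dropna().sum() == pytest.approx(100.0, abs=1e-9)
    assert len(rep.influence) == 8


def test_rank_risk_factors_row_order_invariance(ne_survey_small):
    from nutrineq.pipeline import build_analysis_frame

    frame = build_analysis_frame(ne_survey_small.children, ne_survey_small.households)
    cfg = BoostConfig(n_trees=60, learning_rate=0.1, seed=13)
    a = rank_risk_factors(frame, "stunted", config=cfg)
    shuffled = frame.sample(frac=1.0, random_state=99)
    b = rank_risk_factors(shuffled, "stunted", config=cfg)
    pd.testing.assert_series_equal(a.influence, b.influence)


def test_rank_risk_factors_single_class_region(ne_survey_small):
    from nutrineq.pipeline import build_analysis_frame

    frame = build_analysis_frame(ne_survey_small.children, ne_survey_small.households)
    frame = frame.copy()
    frame["stunted"] = 0
    with pytest.raises(ValidationError):
        rank_risk_factors(frame, "stunted")
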