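"""Logistic fit oracles and the five-step inequality decomposition."""

import numpy as np
import pandas as pd
import pytest

from nutrineq.decomposition import (
    InequalityDecomposition,
    decompose,
    decompose_from_printed,
    decompose_row,
    fit_logit,
    group_percent,
)
from nutrineq.exceptions import SeparationError, UndefinedIndexError, ValidationError
from nutrineq.pipeline import load_fixture


def test_intercept_only_closed_form():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    fit = fit_logit(y, pd.DataFrame(index=range(10)))
    assert fit.intercept == pytest.approx(np.log(3 / 7), abs=1e-8)
    assert fit.linear_predictor_mean == pytest.approx(np.log(3 / 7), abs=1e-8)


def test_two_by_two_odds_ratio_closed_form():
    # cells: x=0 -> 10 events / 40 non-events; x=1 -> 20 / 20 => OR = 4
    y = np.concatenate([np.ones(10), np.zeros(40), np.ones(20), np.zeros(20)])
    x = np.concatenate([np.zeros(50), np.ones(40)])
    fit = fit_logit(y, pd.DataFrame({"x": x}))
    assert fit.coefficients["x"] == pytest.approx(np.log(4.0), abs=1e-6)


def test_balanced_independent_predictor_is_null():
    y = np.array([1, 0, 1, 0] * 10)
    x = np.array([1, 1, 0, 0] * 10)
    fit = fit_logit(y, pd.DataFrame({"x": x}))
    assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)


def test_single_class_outcome_rejected():
    with pytest.raises(ValidationError):
        fit_logit(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}))


def test_perfect_separation_names_column():
    y = np.array([0] * 10 + [1] * 10)
    sep = y.astype(float)
    noise = np.array([0, 1] * 10, dtype=float)
    with pytest.raises(SeparationError, match="sep"):
        fit_logit(y, pd.DataFrame({"noise": noise, "sep": sep}))


def test_worked_example_row():
    row = decompose_row(beta=-0.059, mean=0.325, lnodds_mean=-1.109,
                        determinant_ci=0.307, outcome_ci=0.196)
    assert row.elasticity == pytest.approx(0.01729, abs=5e-5)
    assert row.contribution == pytest.approx(0.005, abs=5e-4)
    assert row.percent == pytest.approx(2.71, abs=0.1)


def test_wasting_richest_row():
    row = decompose_row(beta=-0.4665, mean=0.1041, lnodds_mean=-1.7832,
                        determinant_ci=0.8966, outcome_ci=0.0782)
    assert row.contribution == pytest.approx(0.0244, abs=5e-4)
    assert row.percent == pytest.approx(31.2, abs=0.5)


def test_zero_coefficient_row_is_null():
    row = decompose_row(0.0, 0.5, -1.0, 0.3, 0.2)
    assert row.elasticity == 0.0 and row.contribution == 0.0 and row.percent == 0.0


def test_degenerate_denominators_rejected():
    with pytest.raises(UndefinedIndexError):
        decompose_row(1.0, 0.5, 0.0, 0.3, 0.2)
    with pytest.raises(UndefinedIndexError):
        decompose_row(1.0, 0.5, -1.0, 0.3, 0.0)


def test_fixture_identity_and_homogeneity():
    rows, meta = load_fixture("wasting_ne")
    table = decompose_from_printed(rows, meta["lnodds_mean"], meta["outcome_ci"])
    explained = sum(r.contribution for r in table.rows if not r.is_na)
    assert explained + table.residual == pytest.approx(table.outcome_ci, abs=1e-12)
    # scaling every coefficient and the mean log-odds by c leaves percents unchanged
    c = 3.7
    scaled = rows.assign(coefficient=rows["coefficient"] * c)
    table2 = decompose_from_printed(scaled, meta["lnodds_mean"] * c, meta["outcome_ci"])
    for r1, r2 in zip(table.rows, table2.rows):
        if not r1.is_na:
            assert r2.percent == pytest.approx(r1.percent, abs=1e-10)


@pytest.mark.parametrize(
    "table, family, printed",
    [
        ("stunting_ne", "wealth", 61.45),
        ("stunting_pp", "wealth", 67.54),
        ("stunting_ne", "education", 18.56),
        ("wasting_ne", "wealth", 51.16),
        ("wasting_ne", "sanitation", 25.96),
    ],
)
def test_group_percent_reproduces_printed_family_sums(table, family, printed):
    rows, meta = load_fixture(table)
    result = decompose_from_printed(rows, meta["lnodds_mean"], meta["outcome_ci"])
    fam_rows = [r for r in result.rows if r.family == family]
    assert group_percent(fam_rows) == pytest.approx(printed, abs=0.5)


def test_group_percent_singleton_and_empty():
    rows, meta = load_fixture("wasting_ne")
    result = decompose_from_printed(rows, meta["lnodds_mean"], meta["outcome_ci"])
    gender = [r for r in result.rows if r.family == "gender"]
    assert group_percent(gender) == pytest.approx(gender[0].percent)
    with pytest.raises(ValidationError):
        group_percent([])


def test_zero_variance_determinant_becomes_na_row():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.integers(0, 2, n).astype(float)
    z = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + x)))).astype(float)
    X = pd.DataFrame({"x": x, "flat": np.zeros(n)})
    res = InequalityDecomposition(y, X, z).fit()
    frame = res.frame().set_index("name")
    assert bool(frame.loc["flat", "na"])
    assert not bool(frame.loc["x", "na"])
    explained = frame.loc[~frame["na"], "contribution"].sum()
    assert explained + res.residual == pytest.approx(res.outcome_ci, abs=1e-10)


def test_single_signal_determinant_dominates_contributions():
    """A lone rank-correlated effect should carry nearly all the explained inequality."""
    rng = np.random.default_rng(17)
    n = 4000
    z = rng.normal(size=n)
    signal = (z + rng.normal(scale=0.5, size=n) > 0).astype(float)
    noise1 = rng.integers(0, 2, n).astype(float)
    noise2 = rng.integers(0, 2, n).astype(float)
    lp = -1.5 + 1.2 * signal
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    X = pd.DataFrame({"signal": signal, "noise1": noise1, "noise2": noise2})
    res = InequalityDecomposition(y, X, z).fit()
    frame = res.frame().set_index("name")
    total_abs = frame["contribution"].abs().sum()
    assert abs(frame.loc["signal", "contribution"]) / total_abs >= 0.95


def test_rank_independent_determinants_contribute_nothing():
    rng = np.random.default_rng(23)
    n = 5000
    z = rng.normal(size=n)  # living standard independent of everything
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.integers(0, 2, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.8 * x1)))).astype(float)
    res = InequalityDecomposition(y, pd.DataFrame({"x1": x1, "x2": x2}), z).fit()
    for r in res.table.rows:
        assert abs(r.contribution) < 0.01
    assert res.residual == pytest.approx(res.outcome_ci - sum(
        r.contribution for r in res.table.rows), abs=1e-12)
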