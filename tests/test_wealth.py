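"""First-principal-component wealth index and quintile assignment."""

import numpy as np
import pandas as pd
import pytest

from nutrineq.exceptions import DegenerateDataError, ValidationError
from nutrineq.wealth import QUINTILE_LABELS, WealthIndex, assign_quintiles, fit_wealth_index


def _quintile_oracle(scores):
    """The stated rule, evaluated independently: count cuts strictly below each score."""
    cuts = np.percentile(scores, [20, 40, 60, 80])
    return [sum(c < s for c in cuts) for s in scores]


def test_single_varying_asset_orders_owners():
    assets = pd.DataFrame(
        {"television": [0, 0, 1, 1], "radio": [1, 1, 1, 1]},
        index=["h1", "h2", "h3", "h4"],
    )
    with pytest.warns(UserWarning, match="radio"):
        ws = fit_wealth_index(assets, anchor="television")
    vals = ws.scores.round(9)
    assert vals.nunique() == 2
    assert ws.scores["h3"] > ws.scores["h1"]


def test_first_pc_matches_eigen_oracle():
    assets = pd.DataFrame(
        {"a": [0, 0, 1, 1, 1, 0], "b": [0, 1, 1, 1, 0, 0]},
        index=[f"h{i}" for i in range(6)],
    )
    ws = fit_wealth_index(assets, anchor="a")
    # independent oracle: direct eigendecomposition of the 2x2 correlation matrix
    Z = (assets - assets.mean()) / assets.std(ddof=0)
    corr = np.asarray(Z.T @ Z) / len(Z)
    vals, vecs = np.linalg.eigh(corr)
    v1 = vecs[:, np.argmax(vals)]
    expected = np.asarray(Z) @ v1
    if np.corrcoef(expected, ws.scores)[0, 1] < 0:
        expected = -expected
    assert np.allclose(np.sort(expected), np.sort(ws.scores), atol=1e-10)
    assert ws.explained_variance_fraction == pytest.approx(vals.max() / vals.sum())


def test_all_constant_assets_is_degenerate():
    assets = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]})
    with pytest.warns(UserWarning):
        with pytest.raises(DegenerateDataError):
            fit_wealth_index(assets)


def test_wash_columns_refused():
    with pytest.raises(ValidationError, match="WASH"):
        WealthIndex(pd.DataFrame({"water_source": [0, 1], "radio": [1, 0]}))


@pytest.mark.parametrize("n, expected_size", [(10, 2), (100, 20)])
def test_quintiles_equal_sizes_on_distinct_scores(n, expected_size):
    rng = np.random.default_rng(0)
    scores = pd.Series(rng.normal(size=n), index=[f"h{i}" for i in range(n)])
    ws = fit_wealth_index(
        pd.DataFrame({"a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n)},
                     index=scores.index)
    )
    ws.scores = scores  # inject known distinct scores
    ws = assign_quintiles(ws)
    counts = ws.quintiles.value_counts()
    assert all(counts[q] == expected_size for q in QUINTILE_LABELS)


def test_quintile_tie_block_stays_together():
    scores = pd.Series([1.0, 2.0, 3.0, 3.0, 3.0, 4.0], index=[f"h{i}" for i in range(6)])
    rng = np.random.default_rng(1)
    ws = fit_wealth_index(
        pd.DataFrame({"a": rng.integers(0, 2, 6), "b": rng.integers(0, 2, 6)},
                     index=scores.index)
    )
    ws.scores = scores
    ws = assign_quintiles(ws)
    tied = ws.quintiles[scores == 3.0]
    assert tied.nunique() == 1
    expected_codes = _quintile_oracle(scores.to_numpy())
    assert list(ws.quintiles.cat.codes) == expected_codes


def test_quintiles_need_five_households():
    ws = fit_wealth_index(pd.DataFrame({"a": [0, 1, 0], "b": [1, 0, 1]}))
    with pytest.raises(ValidationError):
        assign_quintiles(ws)


def test_recoding_flip_preserves_ordering():
    rng = np.random.default_rng(2)
    assets = pd.DataFrame(
        {"a": rng.integers(0, 2, 40), "b": rng.integers(0, 2, 40),
         "c": rng.integers(0, 2, 40)},
        index=[f"h{i}" for i in range(40)],
    )
    ws = fit_wealth_index(assets, anchor="a")
    flipped = assets.assign(b=1 - assets["b"])
    ws2 = fit_wealth_index(flipped, anchor="a")
    assert np.sign(ws2.loadings["b"]) == -np.sign(ws.loadings["b"])
    assert np.allclose(ws.scores, ws2.scores, atol=1e-10)


def test_nested_ownership_monotone():
    # household owning a strict superset scores higher when all loadings positive
    assets = pd.DataFrame(
        {"a": [1, 0, 0, 1, 1, 0, 1, 1], "b": [1, 0, 0, 1, 1, 0, 1, 1],
         "c": [1, 0, 0, 1, 1, 0, 0, 0]},
        index=[f"h{i}" for i in range(8)],
    )
    ws = fit_wealth_index(assets, anchor="a")
    assert all(v > 0 for v in ws.loadings.values())
    superset, subset = "h0", "h1"  # owns everything vs nothing
    assert ws.scores[superset] > ws.scores[subset]
    assert ws.scores["h0"] > ws.scores["h6"] > ws.scores["h1"]  # {a,b,c} > {a,b} > {}
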