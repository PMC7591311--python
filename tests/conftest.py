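import pandas as pd
import pytest

from nutrineq.survey import FOOD_GROUPS, ChildRecord
from nutrineq.synthetic import generate, preset


@pytest.fixture(scope="session")
def ne_survey_small():
    """A modest north-eastern-like draw shared across tests."""
    return generate(preset("ne_like", n_children=1200, seed=7))


@pytest.fixture
def make_child():
    """Factory for a valid child record with overridable fields."""

    def _make(**overrides):
        base = dict(
            child_id="c1",
            household_id="h1",
            age_months=15.0,
            sex="female",
            laz=-1.0,
            wlz=-0.5,
            muac_mm=140.0,
            oedema=False,
            breastfed_now=True,
            bottle_fed=False,
            food_groups=(True, False, True, False, True, False, False),
            meal_count=3,
            birth_certificate=True,
            campaign_access=True,
            region="north_eastern",
        )
        base.update(overrides)
        return ChildRecord(**base)

    return _make


@pytest.fixture
def survey_csvs(tmp_path, ne_survey_small):
    """Small on-disk children/households CSV pair in the canonical schema."""
    children = ne_survey_small.children.head(30)
    households = ne_survey_small.households.head(30)
    cpath, hpath = tmp_path / "children.csv", tmp_path / "households.csv"
    children.to_csv(cpath, index=False)
    households.to_csv(hpath, index=False)
    return cpath, hpath, children, households
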