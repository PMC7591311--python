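"""Child feeding index rubric, meal-frequency thresholds and monotonicity."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from nutrineq.exceptions import ValidationError
from nutrineq.feeding import (
    cfi_class,
    cfi_score,
    cfi_score_frame,
    dietary_diversity_count,
    minimum_meal_frequency,
)


@pytest.mark.parametrize(
    "flags, expected",
    [
        ((False,) * 7, 0),
        ((True, False, False, False, True, True, False), 3),
        ((True,) * 7, 7),
    ],
)
def test_dietary_diversity_count(flags, expected):
    assert dietary_diversity_count(flags) == expected


@pytest.mark.parametrize(
    "age, breastfed, expected",
    [(7, True, 2), (15, True, 3), (20, False, 4), (6, True, 2), (8.9, True, 2),
     (9, True, 3), (23.9, True, 3), (6, False, 4)],
)
def test_minimum_meal_frequency_rules(age, breastfed, expected):
    assert minimum_meal_frequency(age, breastfed) == expected


def test_minimum_meal_frequency_age_domain():
    with pytest.raises(ValidationError):
        minimum_meal_frequency(24.0, True)
    with pytest.raises(ValidationError):
        minimum_meal_frequency(5.9, False)


def test_cfi_maximum(make_child):
    child = make_child(breastfed_now=True, bottle_fed=False, meal_count=5,
                       food_groups=(True, True, True, True, True, False, False))
    res = cfi_score(child)
    assert res.score == 7 and res.cfi_class == "high"


def test_cfi_minimum(make_child):
    child = make_child(breastfed_now=False, bottle_fed=True, meal_count=0,
                       food_groups=(False,) * 7)
    res = cfi_score(child)
    assert res.score == 0 and res.cfi_class == "low"


def test_cfi_score_four_is_medium(make_child):
    # breastfed (+2) + bottle (0) + meals at minimum (+2) + no diversity (0) = 4
    child = make_child(age_months=15.0, breastfed_now=True, bottle_fed=True,
                       meal_count=3, food_groups=(False,) * 7)
    res = cfi_score(child)
    assert res.score == 4 and res.cfi_class == "medium"


@pytest.mark.parametrize("score, expected", [
    (0, "low"), (1, "low"), (2, "low"), (3, "low"),
    (4, "medium"), (5, "medium"), (6, "high"), (7, "high"),
])
def test_class_bands(score, expected):
    assert cfi_class(score) == expected


@given(
    breastfed=st.booleans(),
    bottle=st.booleans(),
    meals=st.integers(min_value=0, max_value=8),
    groups=st.lists(st.booleans(), min_size=7, max_size=7),
    age=st.floats(min_value=6.0, max_value=23.89),
)
@settings(max_examples=200, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_cfi_monotone_in_each_behaviour(make_child, breastfed, bottle, meals, groups, age):
    """Adding a meal or a food group never lowers the score."""
    child = make_child(age_months=age, breastfed_now=breastfed, bottle_fed=bottle,
                       meal_count=meals, food_groups=tuple(groups))
    base = cfi_score(child).score
    more_meals = make_child(age_months=age, breastfed_now=breastfed, bottle_fed=bottle,
                            meal_count=meals + 1, food_groups=tuple(groups))
    assert cfi_score(more_meals).score >= base
    if not all(groups):
        i = groups.index(False)
        richer = groups.copy()
        richer[i] = True
        more_food = make_child(age_months=age, breastfed_now=breastfed, bottle_fed=bottle,
                               meal_count=meals, food_groups=tuple(richer))
        assert cfi_score(more_food).score >= base


@given(groups=st.permutations([True, True, False, True, False, False, False]))
@settings(max_examples=30, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_cfi_invariant_to_food_group_order(make_child, groups):
    ref = cfi_score(make_child(food_groups=(True, True, False, True, False, False, False)))
    assert cfi_score(make_child(food_groups=tuple(groups))).score == ref.score


def test_frame_scoring_agrees_with_per_record(ne_survey_small):
    ch = ne_survey_small.children.head(200)
    vec = cfi_score_frame(ch)
    from nutrineq.survey import FOOD_GROUPS, ChildRecord

    for i in range(0, len(ch), 17):
        row = ch.iloc[i]
        rec = ChildRecord(
            child_id=row["child_id"], household_id=row["household_id"],
            age_months=row["age_months"], sex=row["sex"], laz=row["laz"],
            wlz=row["wlz"], muac_mm=row["muac_mm"], oedema=bool(row["oedema"]),
            breastfed_now=bool(row["breastfed_now"]), bottle_fed=bool(row["bottle_fed"]),
            food_groups=tuple(bool(row[f"fg_{g}"]) for g in FOOD_GROUPS),
            meal_count=int(row["meal_count"]),
            birth_certificate=bool(row["birth_certificate"]),
            campaign_access=bool(row["campaign_access"]), region=row["region"],
        )
        res = cfi_score(rec)
        assert vec.iloc[i]["cfi_score"] == res.score
        assert vec.iloc[i]["cfi_class"] == res.cfi_class
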