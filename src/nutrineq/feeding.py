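"""IYCF indicators and the composite child feeding index (CFI, 0-7).

Four behaviours observed over the previous 24 h are combined into a 0-7
score: continued breastfeeding, bottle use, dietary diversity over seven
food groups, and meal frequency relative to the age-specific minimum
(2 meals for breastfed 6-8 months, 3 for breastfed 9-23 months, 4 for any
non-breastfed child).  Scores are classed low (0-3), medium (4-5),
high (6-7).

The exact per-behaviour point allocation is a documented rubric shipped as
configuration (``DEFAULT_RUBRIC``); a study team with its own allocation can
swap the table via YAML/JSON without code change.  The default awards:
+2 continued breastfeeding, +1 no bottle, meal frequency +2 at/above the
minimum and +1 one meal short, dietary diversity +2 for >=4 groups and +1
for 2-3 groups — maximum 7, minimum 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError, ValidationError
from .survey import FOOD_GROUPS, ChildRecord

__all__ = [
    "DEFAULT_RUBRIC",
    "CFIResult",
    "dietary_diversity_count",
    "minimum_meal_frequency",
    "cfi_score",
    "cfi_score_frame",
    "cfi_class",
    "load_rubric",
]

#: Points per behaviour. Conditions are keyed by behaviour name; each maps an
#: ordered list of (condition, points) evaluated top-down, first match wins.
DEFAULT_RUBRIC = {
    "continued_breastfeeding": {"yes": 2, "no": 0},
    "bottle": {"not_used": 1, "used": 0},
    "meal_frequency": {"at_or_above_minimum": 2, "one_below_minimum": 1, "otherwise": 0},
    "dietary_diversity": {"ge_4_groups": 2, "2_to_3_groups": 1, "otherwise": 0},
}

CLASS_BANDS = {"low": (0, 3), "medium": (4, 5), "high": (6, 7)}


@dataclass(frozen=True)
class CFIResult:
    score: int
    cfi_class: str
    components: dict
    age_band: str  # m6_8 / m9_11 / m12_23


def load_rubric(path) -> dict:
    """Load a rubric table from YAML or JSON and validate its shape."""
    text = Path(path).read_text()
    rubric = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    for behaviour, table in DEFAULT_RUBRIC.items():
        if behaviour not in rubric:
            raise ConfigError(f"rubric missing behaviour {behaviour!r}")
        for cond in table:
            if cond not in rubric[behaviour]:
                raise ConfigError(f"rubric behaviour {behaviour!r} missing condition {cond!r}")
    return rubric


def dietary_diversity_count(food_groups) -> int:
    """Number of the seven food groups consumed."""
    flags = tuple(food_groups)
    if len(flags) != len(FOOD_GROUPS):
        raise ValidationError(f"expected {len(FOOD_GROUPS)} food-group flags, got {len(flags)}")
    return int(sum(bool(f) for f in flags))


def minimum_meal_frequency(age_months: float, breastfed: bool) -> int:
    """Age-specific minimum meal count: 2 (breastfed 6-8 m), 3 (breastfed 9-23 m), 4 (non-breastfed)."""
    if not (6.0 <= age_months < 24.0):
        raise ValidationError(f"age {age_months} outside [6, 24) months")
    if not breastfed:
        return 4
    return 2 if age_months < 9 else 3


def _feeding_age_band(age_months: float) -> str:
    if age_months < 9:
        return "m6_8"
    if age_months < 12:
        return "m9_11"
    return "m12_23"


def cfi_class(score: int) -> str:
    """Class bands: {0..3} low, {4,5} medium, {6,7} high."""
    for name, (lo, hi) in CLASS_BANDS.items():
        if lo <= score <= hi:
            return name
    raise ValidationError(f"CFI score {score} outside [0, 7]")


def cfi_score(child: ChildRecord, rubric: dict | None = None) -> CFIResult:
    """Composite child feeding index for one child under the given rubric."""
    rubric = rubric if rubric is not None else DEFAULT_RUBRIC
    for fieldname in ("breastfed_now", "bottle_fed", "meal_count", "food_groups", "age_months"):
        if getattr(child, fieldname, None) is None:
            raise ValidationError(f"missing feeding field {fieldname!r}")

    bf = rubric["continued_breastfeeding"]["yes" if child.breastfed_now else "no"]
    bottle = rubric["bottle"]["used" if child.bottle_fed else "not_used"]

    threshold = minimum_meal_frequency(child.age_months, child.breastfed_now)
    mf_table = rubric["meal_frequency"]
    if child.meal_count >= threshold:
        mf = mf_table["at_or_above_minimum"]
    elif child.meal_count == threshold - 1:
        mf = mf_table["one_below_minimum"]
    else:
        mf = mf_table["otherwise"]

    dd_count = dietary_diversity_count(child.food_groups)
    dd_table = rubric["dietary_diversity"]
    if dd_count >= 4:
        dd = dd_table["ge_4_groups"]
    elif dd_count >= 2:
        dd = dd_table["2_to_3_groups"]
    else:
        dd = dd_table["otherwise"]

    components = {
        "continued_breastfeeding": bf,
        "bottle": bottle,
        "meal_frequency": mf,
        "dietary_diversity": dd,
    }
    score = int(min(7, max(0, sum(components.values()))))
    return CFIResult(
        score=score,
        cfi_class=cfi_class(score),
        components=components,
        age_band=_feeding_age_band(child.age_months),
    )


def cfi_score_frame(df, rubric: dict | None = None):
    """Vectorized CFI over a children frame.

    Requires columns ``age_months``, ``breastfed_now``, ``bottle_fed``,
    ``meal_count`` and the seven ``fg_*`` flags; returns a DataFrame with
    ``cfi_score`` and ``cfi_class``.  Agrees element-wise with
    :func:`cfi_score` (that equivalence is under test).
    """
    import numpy as np
    import pandas as pd

    rubric = rubric if rubric is not None else DEFAULT_RUBRIC
    age = df["age_months"].to_numpy(dtype=float)
    if (age < 6).any() or (age >= 24).any():
        raise ValidationError("age outside [6, 24) months")
    bf = df["breastfed_now"].to_numpy(dtype=bool)
    bottle = df["bottle_fed"].to_numpy(dtype=bool)
    meals = df["meal_count"].to_numpy(dtype=int)
    dd_count = sum(df[f"fg_{g}"].to_numpy(dtype=bool).astype(int) for g in FOOD_GROUPS)

    r = rubric
    bf_pts = np.where(bf, r["continued_breastfeeding"]["yes"], r["continued_breastfeeding"]["no"])
    bottle_pts = np.where(bottle, r["bottle"]["used"], r["bottle"]["not_used"])
    threshold = np.where(~bf, 4, np.where(age < 9, 2, 3))
    mf = r["meal_frequency"]
    mf_pts = np.select(
        [meals >= threshold, meals == threshold - 1],
        [mf["at_or_above_minimum"], mf["one_below_minimum"]],
        default=mf["otherwise"],
    )
    dd = r["dietary_diversity"]
    dd_pts = np.select(
        [dd_count >= 4, dd_count >= 2],
        [dd["ge_4_groups"], dd["2_to_3_groups"]],
        default=dd["otherwise"],
    )
    score = np.clip(bf_pts + bottle_pts + mf_pts + dd_pts, 0, 7).astype(int)
    klass = np.select([score <= 3, score <= 5], ["low", "medium"], default="high")
    return pd.DataFrame({"cfi_score": score, "cfi_class": klass}, index=df.index)
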