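"""Typed survey records, anthropometric outcome rules and CSV round-trip I/O.

The schema mirrors a household nutrition survey of children aged 6-23.9 months:
child anthropometry (length-for-age z, weight-for-length z, MUAC, oedema),
infant and young child feeding behaviours over the previous 24 h, and
household living-standard indicators (assets, maternal education, WASH).

Outcome rules
-------------
* stunting: length-for-age z-score strictly below -2 SD.
* wasting: weight-for-length z-score strictly below -2 SD, and/or MUAC
  strictly below 125 mm, and/or presence of nutritional oedema.

Both rules are pure functions of a single record; cut-offs are strict, so a
z-score of exactly -2 is *not* classified.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

__all__ = [
    "FOOD_GROUPS",
    "ChildRecord",
    "HouseholdRecord",
    "OutcomeFlags",
    "SchemaConfig",
    "SurveyData",
    "classify_stunting",
    "classify_wasting",
    "derive_outcomes",
    "read_survey",
    "write_survey",
    "age_band",
]

#: The seven complementary-feeding food groups, in canonical order.
FOOD_GROUPS = (
    "grains_roots_tubers",
    "legumes_nuts",
    "vitamin_a_fruits_veg",
    "other_fruits_veg",
    "meats",
    "eggs",
    "dairy",
)

STUNTING_LAZ_CUTOFF = -2.0
WASTING_WLZ_CUTOFF = -2.0
MUAC_CUTOFF_MM = 125.0

SEXES = ("female", "male")
REGIONS = ("phnom_penh", "north_eastern")
EDUCATION_LEVELS = ("none", "primary", "secondary_plus")
WATER_SOURCES = ("improved", "nonimproved")
WATER_TREATMENTS = ("adequate", "not_adequate")
SANITATION_TYPES = ("improved", "nonimproved")

_TRUE_STRINGS = {"1", "yes", "true", "y", "t"}
_FALSE_STRINGS = {"0", "no", "false", "n", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean")


def classify_stunting(laz: float) -> bool:
    """True iff the length-for-age z-score is strictly below -2 SD."""
    if not math.isfinite(laz):
        raise ValidationError(f"length-for-age z-score must be finite, got {laz!r}")
    return laz < STUNTING_LAZ_CUTOFF


def classify_wasting(wlz: float, muac_mm: float, oedema: bool) -> bool:
    """True iff any acute-undernutrition criterion is met.

    Criteria (any one suffices): weight-for-length z < -2 SD, MUAC < 125 mm,
    or presence of oedema.
    """
    if not math.isfinite(wlz) or not math.isfinite(muac_mm):
        raise ValidationError("weight-for-length z and MUAC must be finite")
    if muac_mm <= 0:
        raise ValidationError(f"MUAC must be positive millimetres, got {muac_mm!r}")
    return (wlz < WASTING_WLZ_CUTOFF) or (muac_mm < MUAC_CUTOFF_MM) or bool(oedema)


def age_band(age_months: float) -> str:
    """Half-open descriptive age band: [6,12) -> 'm6_12', [12,18) -> 'm12_18', [18,24) -> 'm18_24'."""
    if age_months < 6 or age_months >= 24:
        raise ValidationError(f"age {age_months} outside [6, 24) months")
    if age_months < 12:
        return "m6_12"
    if age_months < 18:
        return "m12_18"
    return "m18_24"


@dataclass(frozen=True)
class ChildRecord:
    """One surveyed child aged 6-23.9 months."""

    child_id: str
    household_id: str
    age_months: float
    sex: str
    laz: float
    wlz: float
    muac_mm: float
    oedema: bool
    breastfed_now: bool
    bottle_fed: bool
    food_groups: tuple  # 7 booleans in FOOD_GROUPS order
    meal_count: int
    birth_certificate: bool
    campaign_access: bool
    region: str

    def __post_init__(self):
        if not (6.0 <= self.age_months < 24.0):
            raise ValidationError(
                f"child {self.child_id}: age {self.age_months} outside [6, 24) months"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"child {self.child_id}: unknown sex {self.sex!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"child {self.child_id}: unknown region {self.region!r}")
        for name in ("laz", "wlz", "muac_mm"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"child {self.child_id}: non-finite {name}")
        if self.muac_mm <= 0:
            raise ValidationError(f"child {self.child_id}: MUAC must be > 0 mm")
        if len(self.food_groups) != len(FOOD_GROUPS):
            raise ValidationError(
                f"child {self.child_id}: expected {len(FOOD_GROUPS)} food-group flags"
            )
        if self.meal_count < 0 or int(self.meal_count) != self.meal_count:
            raise ValidationError(f"child {self.child_id}: meal_count must be a nonnegative integer")


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household: assets, WASH classification, maternal education."""

    household_id: str
    asset_flags: Mapping[str, bool]
    water_source: str
    water_treatment: str
    sanitation: str
    mother_education: str

    def __post_init__(self):
        if len(self.asset_flags) < 2:
            raise ValidationError(
                f"household {self.household_id}: need at least 2 asset indicators"
            )
        if self.water_source not in WATER_SOURCES:
            raise ValidationError(
                f"household {self.household_id}: unknown water source {self.water_source!r}"
            )
        if self.water_treatment not in WATER_TREATMENTS:
            raise ValidationError(
                f"household {self.household_id}: unknown water treatment {self.water_treatment!r}"
            )
        if self.sanitation not in SANITATION_TYPES:
            raise ValidationError(
                f"household {self.household_id}: unknown sanitation {self.sanitation!r}"
            )
        if self.mother_education not in EDUCATION_LEVELS:
            raise ValidationError(
                f"household {self.household_id}: unknown education {self.mother_education!r}"
            )


@dataclass(frozen=True)
class OutcomeFlags:
    stunted: bool
    wasted: bool


def derive_outcomes(child: ChildRecord) -> OutcomeFlags:
    """Deterministic anthropometric classification of one child."""
    return OutcomeFlags(
        stunted=classify_stunting(child.laz),
        wasted=classify_wasting(child.wlz, child.muac_mm, child.oedema),
    )


@dataclass
class SchemaConfig:
    """Column mapping and unit conventions for survey CSV files.

    ``child_columns`` / ``household_columns`` map canonical field names to the
    column names actually present in the file; unmapped fields default to the
    canonical name.  ``muac_unit`` may be ``"mm"`` or ``"cm"`` (cm values are
    converted to mm on read).
    """

    child_columns: dict = field(default_factory=dict)
    household_columns: dict = field(default_factory=dict)
    muac_unit: str = "mm"

    @classmethod
    def from_file(cls, path) -> "SchemaConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(
            child_columns=data.get("child_columns", {}),
            household_columns=data.get("household_columns", {}),
            muac_unit=data.get("muac_unit", "mm"),
        )


CHILD_FIELDS = [f.name for f in dataclasses.fields(ChildRecord) if f.name != "food_groups"]
HOUSEHOLD_SCALAR_FIELDS = [
    "household_id",
    "water_source",
    "water_treatment",
    "sanitation",
    "mother_education",
]


@dataclass
class SurveyData:
    """Validated records plus a rejects report (rows failing invariants are kept, not dropped)."""

    children: list
    households: list
    rejects: pd.DataFrame

    def children_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.children:
            d = {k: getattr(c, k) for k in CHILD_FIELDS}
            d.update({f"fg_{g}": c.food_groups[i] for i, g in enumerate(FOOD_GROUPS)})
            rows.append(d)
        cols = CHILD_FIELDS + [f"fg_{g}" for g in FOOD_GROUPS]
        return pd.DataFrame(rows, columns=cols)

    def households_frame(self) -> pd.DataFrame:
        rows = []
        asset_names = sorted({a for h in self.households for a in h.asset_flags})
        for h in self.households:
            d = {k: getattr(h, k) for k in HOUSEHOLD_SCALAR_FIELDS}
            d.update({f"asset_{a}": bool(h.asset_flags.get(a, False)) for a in asset_names})
            rows.append(d)
        cols = HOUSEHOLD_SCALAR_FIELDS + [f"asset_{a}" for a in asset_names]
        return pd.DataFrame(rows, columns=cols)


def _column(df: pd.DataFrame, canonical: str, mapping: Mapping[str, str]) -> str:
    name = mapping.get(canonical, canonical)
    if name not in df.columns:
        raise SchemaError(f"missing mandatory column {name!r} (for field {canonical!r})")
    return name


def _read_children(df: pd.DataFrame, schema: SchemaConfig):
    records, rejects = [], []
    cmap = schema.child_columns
    mandatory = CHILD_FIELDS + [f"fg_{g}" for g in FOOD_GROUPS]
    cols = {f: _column(df, f, cmap) for f in mandatory}
    scale = 10.0 if schema.muac_unit == "cm" else 1.0
    for _, row in df.iterrows():
        try:
            fg = tuple(_parse_bool(row[cols[f"fg_{g}"]]) for g in FOOD_GROUPS)
            rec = ChildRecord(
                child_id=str(row[cols["child_id"]]),
                household_id=str(row[cols["household_id"]]),
                age_months=float(row[cols["age_months"]]),
                sex=str(row[cols["sex"]]).strip().lower(),
                laz=float(row[cols["laz"]]),
                wlz=float(row[cols["wlz"]]),
                muac_mm=float(row[cols["muac_mm"]]) * scale,
                oedema=_parse_bool(row[cols["oedema"]]),
                breastfed_now=_parse_bool(row[cols["breastfed_now"]]),
                bottle_fed=_parse_bool(row[cols["bottle_fed"]]),
                food_groups=fg,
                meal_count=int(row[cols["meal_count"]]),
                birth_certificate=_parse_bool(row[cols["birth_certificate"]]),
                campaign_access=_parse_bool(row[cols["campaign_access"]]),
                region=str(row[cols["region"]]).strip().lower(),
            )
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            rejects.append({"table": "children", "row": dict(row), "reason": str(exc)})
    return records, rejects


def _read_households(df: pd.DataFrame, schema: SchemaConfig):
    records, rejects = [], []
    cmap = schema.household_columns
    cols = {f: _column(df, f, cmap) for f in HOUSEHOLD_SCALAR_FIELDS}
    asset_cols = [c for c in df.columns if c.startswith("asset_")]
    for _, row in df.iterrows():
        try:
            assets = {c[len("asset_"):]: _parse_bool(row[c]) for c in asset_cols}
            rec = HouseholdRecord(
                household_id=str(row[cols["household_id"]]),
                asset_flags=assets,
                water_source=str(row[cols["water_source"]]).strip().lower(),
                water_treatment=str(row[cols["water_treatment"]]).strip().lower(),
                sanitation=str(row[cols["sanitation"]]).strip().lower(),
                mother_education=str(row[cols["mother_education"]]).strip().lower(),
            )
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            rejects.append({"table": "households", "row": dict(row), "reason": str(exc)})
    return records, rejects


def read_survey(children_path, households_path, schema: SchemaConfig | None = None) -> SurveyData:
    """Read and validate the two survey CSV files.

    Rows failing a domain invariant are collected into ``SurveyData.rejects``
    with the offending reason; they are never silently dropped.
    """
    schema = schema or SchemaConfig()
    cdf = pd.read_csv(children_path)
    hdf = pd.read_csv(households_path)
    children, crej = _read_children(cdf, schema)
    households, hrej = _read_households(hdf, schema)
    rej_rows = [
        {"table": r["table"], "reason": r["reason"], **{str(k): v for k, v in r["row"].items()}}
        for r in crej + hrej
    ]
    rejects = pd.DataFrame(rej_rows)
    return SurveyData(children=children, households=households, rejects=rejects)


def write_survey(data: SurveyData, children_path, households_path, rejects_path=None) -> None:
    """Serialize typed records back to CSV (round-trips with :func:`read_survey`)."""
    data.children_frame().to_csv(children_path, index=False)
    data.households_frame().to_csv(households_path, index=False)
    if rejects_path is not None and len(data.rejects):
        data.rejects.to_csv(rejects_path, index=False)
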