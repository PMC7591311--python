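"""Synthetic survey generator with a latent socioeconomic factor.

One household per child.  A latent living standard ``z ~ Normal(0, sd)``
drives everything socioeconomic: asset ownership (logit links), maternal
education (ordinal cutpoints on a noisy latent score), WASH indicators
(probit links), birth registration and health-campaign access, and - mildly -
feeding behaviours.  Child outcomes (stunting, wasting) follow a logistic
model on the binary determinant matrix, with the household's *true*
wealth quintile taken as the quintile of ``z``.  Anthropometric measurements
(length-for-age z, weight-for-length z, MUAC, oedema) are realized from
truncated normals consistent with the simulated outcome flags, so the
classification rules recover the flags exactly.

Because every determinant's link intercept is solved from its target
marginal (closed form for probit, Gauss-Hermite quadrature for logit), the
presets reproduce the survey marginals they are calibrated to as n grows.
The two outcome-model intercepts per preset are frozen constants produced
by ``scripts/calibrate_presets.py`` (large-n root-finding at a fixed
internal seed).

Ground truth ships with every draw: true coefficients, determinant means and
concentration indices against the *latent* ranking, and the implied
contribution shares - the quantities a downstream decomposition should
recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .exceptions import ConfigError
from .feeding import cfi_score_frame
from .inequality import concentration_index, fractional_rank
from .survey import FOOD_GROUPS

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticSurvey", "generate", "preset",
           "calibrate_outcome_intercept", "DETERMINANTS"]

#: Canonical determinant columns of the outcome design matrix (reference
#: categories omitted: 18-23.9 months, male, no education, poorest quintile,
#: low CFI, and the "risk present" WASH levels).
DETERMINANTS = (
    "age_6_12",
    "age_12_18",
    "female",
    "edu_primary",
    "edu_secondary",
    "wealth_poor",
    "wealth_middle",
    "wealth_rich",
    "wealth_richest",
    "cfi_medium",
    "cfi_high",
    "birth_certificate",
    "campaign_access",
    "sanitation_improved",
    "water_treatment_adequate",
    "water_source_improved",
)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _logit_marginal(a: float, loading: float, sd: float) -> float:
    # E[sigmoid(a + loading*z)], z ~ N(0, sd), by Gauss-Hermite quadrature
    vals = _logistic(a + loading * sd * np.sqrt(2.0) * _GH_NODES)
    return float(np.sum(_GH_WEIGHTS * vals) / np.sqrt(np.pi))


def _solve_logit_intercept(target: float, loading: float, sd: float) -> float:
    if not (0.0 < target < 1.0):
        raise ConfigError(f"marginal probability {target} outside (0, 1)")
    return brentq(lambda a: _logit_marginal(a, loading, sd) - target, -30.0, 30.0)


def _solve_probit_intercept(target: float, loading: float, sd: float) -> float:
    if not (0.0 < target < 1.0):
        raise ConfigError(f"marginal probability {target} outside (0, 1)")
    # P(a + loading*z + eps > 0) = Phi(a / sqrt(1 + loading^2 sd^2))
    return norm.ppf(target) * float(np.sqrt(1.0 + (loading * sd) ** 2))


@dataclass
class SyntheticConfig:
    """All knobs of the generator; presets fill them from survey marginals."""

    n_children: int = 5000
    seed: int = 0
    latent_sd: float = 1.0
    region: str = "north_eastern"
    region_mix: float = 1.0  # proportion assigned to north_eastern

    # assets: name -> (target marginal, latent loading)
    asset_params: dict = field(default_factory=dict)

    # education: ordinal cutpoints on e = loading*z + N(0,1)
    education_loading: float = 0.8
    education_thresholds: tuple = (-0.5, 0.8)

    # WASH + registration/campaign: name -> (target marginal, probit loading)
    wash_params: dict = field(default_factory=dict)
    cert_rate: float = 0.65
    cert_loading: float = 0.5
    campaign_rate: float = 0.73
    campaign_loading: float = 0.4

    # feeding behaviours
    feeding_params: dict = field(default_factory=dict)

    # demographics
    age_band_probs: tuple = (0.293, 0.381, 0.326)
    female_rate: float = 0.513

    # outcome logistic models on DETERMINANTS
    outcome_betas: dict = field(default_factory=dict)       # outcome -> {determinant: beta}
    outcome_intercepts: dict = field(default_factory=dict)  # outcome -> b0

    def __post_init__(self):
        if self.n_children < 10:
            raise ConfigError("n_children must be >= 10")
        for p in (self.cert_rate, self.campaign_rate, self.female_rate, *self.age_band_probs):
            if not (0.0 < p < 1.0):
                raise ConfigError(f"probability {p} outside (0, 1)")
        for name, (rate, _) in {**self.asset_params, **self.wash_params}.items():
            if not (0.0 < rate < 1.0):
                raise ConfigError(f"marginal for {name!r} outside (0, 1)")


@dataclass
class GroundTruth:
    """Designed decomposition quantities, evaluated on the drawn sample against the latent rank."""

    tables: dict          # outcome -> DataFrame(name, beta, mean, determinant_ci, contribution, share_percent)
    lnodds_means: dict    # outcome -> mean true linear predictor
    outcome_cis: dict     # outcome -> CI of the true linear predictor
    prevalences: dict     # outcome -> designed large-n prevalence realized in-sample

    def family_shares(self, outcome: str) -> pd.Series:
        df = self.tables[outcome]
        return df.groupby("family", sort=False)["share_percent"].sum()

    def to_json(self) -> str:
        payload = {
            "lnodds_means": self.lnodds_means,
            "outcome_cis": self.outcome_cis,
            "prevalences": self.prevalences,
            "tables": {k: v.to_dict(orient="records") for k, v in self.tables.items()},
        }
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticSurvey:
    children: pd.DataFrame
    households: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig


_FAMILY_OF = {
    "age_6_12": "age", "age_12_18": "age", "female": "gender",
    "edu_primary": "education", "edu_secondary": "education",
    "wealth_poor": "wealth", "wealth_middle": "wealth", "wealth_rich": "wealth",
    "wealth_richest": "wealth", "cfi_medium": "cfi", "cfi_high": "cfi",
    "birth_certificate": "birth_certificate", "campaign_access": "campaign",
    "sanitation_improved": "sanitation", "water_treatment_adequate": "water_treatment",
    "water_source_improved": "water_source",
}


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator):
    n = cfg.n_children
    sd = cfg.latent_sd
    z = rng.normal(0.0, sd, size=n)

    region = np.where(rng.random(n) < cfg.region_mix, "north_eastern", "phnom_penh")

    assets = {}
    for name, (rate, loading) in cfg.asset_params.items():
        a = _solve_logit_intercept(rate, loading, sd)
        assets[name] = rng.random(n) < _logistic(a + loading * z)

    e = cfg.education_loading * z + rng.normal(0.0, 1.0, size=n)
    c1, c2 = cfg.education_thresholds
    education = np.select([e < c1, e < c2], ["none", "primary"], default="secondary_plus")

    wash = {}
    for name, (rate, loading) in cfg.wash_params.items():
        a = _solve_probit_intercept(rate, loading, sd)
        wash[name] = (a + loading * z + rng.normal(0.0, 1.0, size=n)) > 0

    a_cert = _solve_probit_intercept(cfg.cert_rate, cfg.cert_loading, sd)
    cert = (a_cert + cfg.cert_loading * z + rng.normal(0.0, 1.0, size=n)) > 0
    a_cam = _solve_probit_intercept(cfg.campaign_rate, cfg.campaign_loading, sd)
    campaign = (a_cam + cfg.campaign_loading * z + rng.normal(0.0, 1.0, size=n)) > 0

    band = rng.choice(3, size=n, p=np.asarray(cfg.age_band_probs) / sum(cfg.age_band_probs))
    lo = np.array([6.0, 12.0, 18.0])[band]
    hi = np.array([12.0, 18.0, 23.9])[band]
    age = lo + rng.random(n) * (hi - lo)
    female = rng.random(n) < cfg.female_rate

    fp = cfg.feeding_params
    a_bf = _solve_logit_intercept(fp["breastfed_rate"], fp["breastfed_z_loading"], sd)
    breastfed = rng.random(n) < _logistic(a_bf + fp["breastfed_z_loading"] * z)
    a_bot = _solve_logit_intercept(fp["bottle_rate"], fp["bottle_z_loading"], sd)
    bottle = rng.random(n) < _logistic(a_bot + fp["bottle_z_loading"] * z)
    food = {}
    for g in FOOD_GROUPS:
        rate = fp["food_group_rates"][g]
        loading = fp["food_group_z_loading"] if g != "grains_roots_tubers" else 0.1
        ag = _solve_logit_intercept(rate, loading, sd)
        food[g] = rng.random(n) < _logistic(ag + loading * z)
    lam = fp["meal_lambda"] * np.exp(fp["meal_z_loading"] * z)
    meals = np.minimum(rng.poisson(lam), 9)

    # true wealth quintile = quintile of the latent factor itself
    cuts = np.percentile(z, [20, 40, 60, 80])
    quint = np.searchsorted(cuts, z, side="left")

    feeding_df = pd.DataFrame({
        "age_months": age,
        "breastfed_now": breastfed,
        "bottle_fed": bottle,
        "meal_count": meals,
        **{f"fg_{g}": food[g] for g in FOOD_GROUPS},
    })
    cfi = cfi_score_frame(feeding_df)

    X = pd.DataFrame({
        "age_6_12": (age < 12).astype(float),
        "age_12_18": ((age >= 12) & (age < 18)).astype(float),
        "female": female.astype(float),
        "edu_primary": (education == "primary").astype(float),
        "edu_secondary": (education == "secondary_plus").astype(float),
        "wealth_poor": (quint == 1).astype(float),
        "wealth_middle": (quint == 2).astype(float),
        "wealth_rich": (quint == 3).astype(float),
        "wealth_richest": (quint == 4).astype(float),
        "cfi_medium": (cfi["cfi_class"] == "medium").astype(float),
        "cfi_high": (cfi["cfi_class"] == "high").astype(float),
        "birth_certificate": cert.astype(float),
        "campaign_access": campaign.astype(float),
        "sanitation_improved": wash["sanitation"].astype(float),
        "water_treatment_adequate": wash["water_treatment"].astype(float),
        "water_source_improved": wash["water_source"].astype(float),
    })
    cov = {
        "z": z, "region": region, "assets": assets, "education": education,
        "wash": wash, "cert": cert, "campaign": campaign, "age": age,
        "female": female, "feeding": feeding_df, "cfi": cfi, "quintile": quint,
    }
    return cov, X


def _linear_predictor(cfg: SyntheticConfig, outcome: str, X: pd.DataFrame) -> np.ndarray:
    betas = cfg.outcome_betas[outcome]
    b0 = cfg.outcome_intercepts[outcome]
    lp = np.full(len(X), float(b0))
    for name, beta in betas.items():
        lp += beta * X[name].to_numpy()
    return lp


def calibrate_outcome_intercept(cfg: SyntheticConfig, outcome: str, target_prevalence: float,
                                n: int = 200_000, seed: int = 987_654) -> float:
    """Solve the outcome intercept so the large-n prevalence hits the target.

    Used by ``scripts/calibrate_presets.py``; the presets ship the frozen
    results so generation itself involves no root-finding over outcomes.
    """
    big = dataclasses.replace(cfg, n_children=n, seed=seed)
    _, X = _draw_covariates(big, np.random.default_rng(seed))
    betas = cfg.outcome_betas[outcome]
    xb = np.zeros(len(X))
    for name, beta in betas.items():
        xb += beta * X[name].to_numpy()

    def prev(b0):
        return float(_logistic(b0 + xb).mean()) - target_prevalence

    return float(brentq(prev, -30.0, 30.0))


def _truncn(rng, lower, upper, loc, scale, size):
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _realize_anthropometry(rng, stunted: np.ndarray, wasted: np.ndarray):
    n = len(stunted)
    laz = np.where(
        stunted,
        _truncn(rng, -6.0, -2.0 - 1e-9, -2.9, 0.7, n),
        _truncn(rng, -2.0 + 1e-9, 6.0, -0.9, 0.9, n),
    )
    wlz = _truncn(rng, -2.0 + 1e-9, 6.0, -0.5, 0.9, n)
    muac = _truncn(rng, 125.0 + 1e-6, 200.0, 145.0, 10.0, n)
    oedema = np.zeros(n, dtype=bool)
    mech = rng.choice(3, size=n, p=[0.75, 0.20, 0.05])  # wlz / muac / oedema pathway
    w = wasted.astype(bool)
    m0, m1, m2 = w & (mech == 0), w & (mech == 1), w & (mech == 2)
    if m0.any():
        wlz[m0] = _truncn(rng, -6.0, -2.0 - 1e-9, -2.6, 0.5, int(m0.sum()))
    if m1.any():
        muac[m1] = _truncn(rng, 100.0, 125.0 - 1e-6, 118.0, 5.0, int(m1.sum()))
    oedema[m2] = True
    return laz, wlz, muac, oedema


def generate(cfg: SyntheticConfig, out_dir=None) -> SyntheticSurvey:
    """Draw a full synthetic survey; fixed seed gives byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    cov, X = _draw_covariates(cfg, rng)
    n = cfg.n_children

    flags, truths, mus, cis, prevs = {}, {}, {}, {}, {}
    ranked = fractional_rank(cov["z"])
    for outcome in cfg.outcome_betas:
        lp = _linear_predictor(cfg, outcome, X)
        flags[outcome] = rng.random(n) < _logistic(lp)
        mu = float(lp.mean())
        try:
            out_ci = concentration_index(lp, ranked).value
        except Exception:
            out_ci = np.nan
        rows = []
        for name in DETERMINANTS:
            beta = cfg.outcome_betas[outcome].get(name, 0.0)
            x = X[name].to_numpy()
            xbar = float(x.mean())
            if np.ptp(x) == 0.0:
                ck, contrib, share = np.nan, np.nan, np.nan
            else:
                ck = concentration_index(x, ranked).value
                contrib = (beta * xbar / mu) * ck if mu != 0 else np.nan
                share = contrib / out_ci * 100.0 if out_ci not in (0.0, np.nan) and np.isfinite(out_ci) else np.nan
            rows.append({"name": name, "family": _FAMILY_OF[name], "beta": beta,
                         "mean": xbar, "determinant_ci": ck, "contribution": contrib,
                         "share_percent": share})
        truths[outcome] = pd.DataFrame(rows)
        mus[outcome] = mu
        cis[outcome] = out_ci
        prevs[outcome] = float(flags[outcome].mean())

    stunted = flags.get("stunted", np.zeros(n, dtype=bool))
    wasted = flags.get("wasted", np.zeros(n, dtype=bool))
    laz, wlz, muac, oedema = _realize_anthropometry(rng, stunted, wasted)

    ids = [f"c{i:06d}" for i in range(n)]
    hids = [f"h{i:06d}" for i in range(n)]
    fd = cov["feeding"]
    children = pd.DataFrame({
        "child_id": ids,
        "household_id": hids,
        "age_months": np.round(cov["age"], 2),
        "sex": np.where(cov["female"], "female", "male"),
        "laz": np.round(laz, 3),
        "wlz": np.round(wlz, 3),
        "muac_mm": np.round(muac, 1),
        "oedema": oedema,
        "breastfed_now": fd["breastfed_now"].to_numpy(),
        "bottle_fed": fd["bottle_fed"].to_numpy(),
        **{f"fg_{g}": fd[f"fg_{g}"].to_numpy() for g in FOOD_GROUPS},
        "meal_count": fd["meal_count"].to_numpy(),
        "birth_certificate": cov["cert"],
        "campaign_access": cov["campaign"],
        "region": cov["region"],
    })
    households = pd.DataFrame({
        "household_id": hids,
        **{f"asset_{a}": v for a, v in cov["assets"].items()},
        "water_source": np.where(cov["wash"]["water_source"], "improved", "nonimproved"),
        "water_treatment": np.where(cov["wash"]["water_treatment"], "adequate", "not_adequate"),
        "sanitation": np.where(cov["wash"]["sanitation"], "improved", "nonimproved"),
        "mother_education": np.select(
            [cov["education"] == "none", cov["education"] == "primary"],
            ["none", "primary"], default="secondary_plus"),
    })

    truth = GroundTruth(tables=truths, lnodds_means=mus, outcome_cis=cis, prevalences=prevs)
    survey = SyntheticSurvey(children=children, households=households, truth=truth, config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        children.to_csv(out / "children.csv", index=False)
        households.to_csv(out / "households.csv", index=False)
        (out / "ground_truth.json").write_text(truth.to_json())
    return survey


# ---------------------------------------------------------------------------
# Presets.  Marginal targets follow the two study regions' survey columns;
# loadings and outcome coefficients are the generator's design (see
# docs/methods.md).  Outcome intercepts are frozen from
# scripts/calibrate_presets.py.

_NE_FOOD_RATES = {"grains_roots_tubers": 0.92, "legumes_nuts": 0.20,
                  "vitamin_a_fruits_veg": 0.45, "other_fruits_veg": 0.40,
                  "meats": 0.60, "eggs": 0.30, "dairy": 0.25}
_PP_FOOD_RATES = {"grains_roots_tubers": 0.95, "legumes_nuts": 0.25,
                  "vitamin_a_fruits_veg": 0.50, "other_fruits_veg": 0.50,
                  "meats": 0.70, "eggs": 0.40, "dairy": 0.45}

_NE_STUNTING_BETAS = {
    "age_6_12": -0.8, "age_12_18": -0.3, "female": -0.2,
    "edu_primary": -0.35, "edu_secondary": -0.6,
    "wealth_poor": -0.3, "wealth_middle": -0.5, "wealth_rich": -0.8, "wealth_richest": -1.2,
    "cfi_medium": -0.15, "cfi_high": -0.3,
    "birth_certificate": 0.0, "campaign_access": -0.25,
    "sanitation_improved": -0.2, "water_treatment_adequate": 0.05,
    "water_source_improved": -0.4,
}
_NE_WASTING_BETAS = {
    "age_6_12": 0.1, "age_12_18": 0.08, "female": 0.2,
    "edu_primary": -0.15, "edu_secondary": -0.3,
    "wealth_poor": -0.25, "wealth_middle": -0.35, "wealth_rich": -0.2, "wealth_richest": -0.5,
    "cfi_medium": -0.15, "cfi_high": -0.25,
    "birth_certificate": -0.05, "campaign_access": -0.2,
    "sanitation_improved": -0.45, "water_treatment_adequate": 0.1,
    "water_source_improved": -0.35,
}

# frozen by scripts/calibrate_presets.py
_CALIBRATED_INTERCEPTS = {
    "ne_like": {"stunted": 0.7562, "wasted": -0.9629},
    "pp_like": {"stunted": 0.3102, "wasted": -1.1573},
}


def _edu_thresholds(p_none: float, p_primary: float, loading: float, sd: float) -> tuple:
    s = float(np.sqrt((loading * sd) ** 2 + 1.0))
    return (s * norm.ppf(p_none), s * norm.ppf(p_none + p_primary))


def preset(name: str, n_children: int = 5000, seed: int = 1) -> SyntheticConfig:
    """Named generator configurations.

    ``ne_like`` and ``pp_like`` target the north-eastern / capital survey
    marginals; ``null`` removes every latent loading and outcome effect
    (determinants independent of living standard, outcomes pure noise).
    """
    if name == "ne_like":
        cfg = SyntheticConfig(
            n_children=n_children, seed=seed, latent_sd=1.0,
            region="north_eastern", region_mix=1.0,
            asset_params={
                "radio": (0.35, 0.6), "television": (0.55, 1.2),
                "refrigerator": (0.12, 1.5), "motorbike": (0.60, 0.9),
                "finished_floor": (0.35, 1.0), "finished_roof": (0.50, 0.8),
                "clean_cooking_fuel": (0.15, 1.3), "electricity": (0.45, 1.1),
            },
            education_loading=0.8,
            education_thresholds=_edu_thresholds(0.309, 0.400, 0.8, 1.0),
            wash_params={"sanitation": (0.325, 0.9), "water_treatment": (0.677, 0.5),
                         "water_source": (0.585, 0.7)},
            cert_rate=0.650, cert_loading=0.5,
            campaign_rate=0.730, campaign_loading=0.4,
            feeding_params={"breastfed_rate": 0.60, "breastfed_z_loading": -0.1,
                            "bottle_rate": 0.20, "bottle_z_loading": 0.6,
                            "food_group_rates": _NE_FOOD_RATES,
                            "food_group_z_loading": 0.3,
                            "meal_lambda": 3.0, "meal_z_loading": 0.1},
            age_band_probs=(0.293, 0.381, 0.326), female_rate=0.513,
            outcome_betas={"stunted": dict(_NE_STUNTING_BETAS),
                           "wasted": dict(_NE_WASTING_BETAS)},
            outcome_intercepts=dict(_CALIBRATED_INTERCEPTS["ne_like"]),
        )
        return cfg
    if name == "pp_like":
        cfg = SyntheticConfig(
            n_children=n_children, seed=seed, latent_sd=1.0,
            region="phnom_penh", region_mix=0.0,
            asset_params={
                "radio": (0.40, 0.6), "television": (0.90, 1.0),
                "refrigerator": (0.45, 1.4), "motorbike": (0.80, 0.8),
                "finished_floor": (0.70, 1.0), "finished_roof": (0.80, 0.8),
                "clean_cooking_fuel": (0.55, 1.2), "electricity": (0.95, 1.0),
            },
            education_loading=0.8,
            education_thresholds=_edu_thresholds(0.148, 0.355, 0.8, 1.0),
            wash_params={"sanitation": (0.674, 0.9), "water_treatment": (0.908, 0.5),
                         "water_source": (0.993, 0.7)},
            cert_rate=0.819, cert_loading=0.5,
            campaign_rate=0.808, campaign_loading=0.4,
            feeding_params={"breastfed_rate": 0.55, "breastfed_z_loading": -0.1,
                            "bottle_rate": 0.35, "bottle_z_loading": 0.6,
                            "food_group_rates": _PP_FOOD_RATES,
                            "food_group_z_loading": 0.3,
                            "meal_lambda": 3.3, "meal_z_loading": 0.1},
            age_band_probs=(0.253, 0.402, 0.345), female_rate=0.496,
            outcome_betas={"stunted": dict(_NE_STUNTING_BETAS),
                           "wasted": dict(_NE_WASTING_BETAS)},
            outcome_intercepts=dict(_CALIBRATED_INTERCEPTS["pp_like"]),
        )
        return cfg
    if name == "null":
        zero = {k: 0.0 for k in DETERMINANTS}
        return SyntheticConfig(
            n_children=n_children, seed=seed, latent_sd=1.0,
            region="north_eastern", region_mix=1.0,
            asset_params={"radio": (0.35, 0.0), "television": (0.55, 0.0),
                          "refrigerator": (0.12, 0.0), "motorbike": (0.60, 0.0),
                          "finished_floor": (0.35, 0.0), "finished_roof": (0.50, 0.0),
                          "clean_cooking_fuel": (0.15, 0.0), "electricity": (0.45, 0.0)},
            education_loading=0.0,
            education_thresholds=_edu_thresholds(0.309, 0.400, 0.0, 1.0),
            wash_params={"sanitation": (0.325, 0.0), "water_treatment": (0.677, 0.0),
                         "water_source": (0.585, 0.0)},
            cert_rate=0.650, cert_loading=0.0,
            campaign_rate=0.730, campaign_loading=0.0,
            feeding_params={"breastfed_rate": 0.60, "breastfed_z_loading": 0.0,
                            "bottle_rate": 0.20, "bottle_z_loading": 0.0,
                            "food_group_rates": _NE_FOOD_RATES,
                            "food_group_z_loading": 0.0,
                            "meal_lambda": 3.0, "meal_z_loading": 0.0},
            age_band_probs=(0.293, 0.381, 0.326), female_rate=0.513,
            outcome_betas={"stunted": dict(zero), "wasted": dict(zero)},
            outcome_intercepts={"stunted": float(np.log(0.265 / 0.735)),
                                "wasted": float(np.log(0.152 / 0.848))},
        )
    raise ConfigError(f"unknown preset {name!r}")
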