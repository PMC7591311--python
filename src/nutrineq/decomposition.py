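"""Decomposition of socioeconomic inequality in a binary outcome.

Five-step recipe (Wagstaff-style, on the log-odds scale):

1. fit a logistic model of the outcome on the binary determinants,
   giving coefficients :math:`\\beta_k` (log-odds per unit);
2. take each determinant's sample mean :math:`\\bar x_k`;
3. take each determinant's own concentration index :math:`C_k` against the
   living-standard ranking;
4. form the elasticity :math:`\\eta_k = \\beta_k \\bar x_k / \\mu`, where
   :math:`\\mu` is the mean fitted log-odds of the outcome; the absolute
   contribution of determinant *k* to the outcome's concentration index is
   :math:`\\eta_k C_k`;
5. divide by the outcome concentration index to obtain the percentage share.

The outcome concentration index is the CI of the fitted linear predictor
(the "ln odds" of the outcome), so the identity

    sum of contributions + residual = outcome CI

holds by construction, with the residual absorbing the part of the log-odds
inequality not explained by the modelled determinants.

Two entry points:

* :class:`InequalityDecomposition` — a model object over data; ``fit()``
  runs the logistic regression and all five steps.
* :func:`decompose_from_printed` — "fixture mode": re-runs steps 4-5 from an
  already-printed table of (coefficient, mean, CI) rows plus the printed
  mean log-odds and outcome CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateDataError, SeparationError, UndefinedIndexError, ValidationError
from .inequality import concentration_index, fractional_rank

__all__ = [
    "LogitFit",
    "DecompositionRow",
    "DecompositionTable",
    "DecompositionResults",
    "InequalityDecomposition",
    "fit_logit",
    "decompose_row",
    "decompose",
    "decompose_from_printed",
    "group_percent",
]

IRLS_TOL = 1e-8
IRLS_MAXITER = 100


@dataclass
class LogitFit:
    """Maximum-likelihood logistic fit and its mean linear predictor."""

    coefficients: dict
    intercept: float
    linear_predictor_mean: float
    converged: bool
    n: int
    linear_predictor: np.ndarray = field(repr=False, default=None)


def _scan_separation(y: np.ndarray, X: pd.DataFrame) -> str | None:
    # quasi-complete separation on a single column: the column's support under
    # y=0 and y=1 does not overlap
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) == 0 or len(x1) == 0:
            continue
        if x0.max() <= x1.min() and x0.min() < x1.max():
            return col
        if x1.max() <= x0.min() and x1.min() < x0.max():
            return col
    return None


def fit_logit(outcome, design: pd.DataFrame) -> LogitFit:
    """Logistic MLE (Newton/IRLS) of a binary outcome on a determinant matrix.

    Raises
    ------
    ValidationError
        If the outcome has a single class or n <= number of determinants.
    SeparationError
        If the MLE does not exist because a column separates the outcome;
        the error names the column.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("outcome has a single class; logistic fit undefined")
    if design.shape[0] <= design.shape[1]:
        raise ValidationError("need more observations than determinants")
    X = sm.add_constant(design.astype(float), prepend=True, has_constant="add")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=IRLS_MAXITER, tol=IRLS_TOL, method="newton")
    except Exception as exc:
        col = _scan_separation(y, design)
        if col is not None:
            raise SeparationError(col) from exc
        raise
    params = res.params
    if not np.all(np.isfinite(params)) or not res.mle_retvals.get("converged", False):
        col = _scan_separation(y, design)
        if col is not None:
            raise SeparationError(col)
        raise ValidationError("logistic fit did not converge")
    lp = np.asarray(X @ params)
    return LogitFit(
        coefficients={c: float(params[c]) for c in design.columns},
        intercept=float(params["const"]),
        linear_predictor_mean=float(lp.mean()),
        converged=True,
        n=len(y),
        linear_predictor=lp,
    )


@dataclass
class DecompositionRow:
    """One determinant's line: coefficient, mean, own CI, elasticity, contribution, share."""

    name: str
    coefficient: float
    mean: float
    determinant_ci: float
    elasticity: float
    contribution: float
    percent: float
    family: str | None = None
    is_na: bool = False


def decompose_row(beta: float, mean: float, lnodds_mean: float, determinant_ci: float,
                  outcome_ci: float, name: str = "", family: str | None = None) -> DecompositionRow:
    """Steps 4-5 for a single determinant from its summary numbers.

    elasticity = beta * mean / lnodds_mean; contribution = elasticity * determinant CI;
    percent = contribution / outcome CI * 100.
    """
    if lnodds_mean == 0.0:
        raise UndefinedIndexError("mean log-odds is zero; elasticity undefined")
    if outcome_ci == 0.0:
        raise UndefinedIndexError("outcome concentration index is zero; shares undefined")
    eta = beta * mean / lnodds_mean
    contribution = eta * determinant_ci
    return DecompositionRow(
        name=name,
        coefficient=beta,
        mean=mean,
        determinant_ci=determinant_ci,
        elasticity=eta,
        contribution=contribution,
        percent=contribution / outcome_ci * 100.0,
        family=family,
    )


@dataclass
class DecompositionTable:
    """All determinant rows plus the outcome's own CI and the unexplained residual."""

    rows: list
    outcome_ci: float
    outcome_lnodds_mean: float
    residual: float

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "name": r.name,
                    "family": r.family,
                    "coefficient": r.coefficient,
                    "mean": r.mean,
                    "determinant_ci": r.determinant_ci,
                    "elasticity": r.elasticity,
                    "contribution": r.contribution,
                    "percent": r.percent,
                    "na": r.is_na,
                }
                for r in self.rows
            ]
        )
        return df

    def family_percents(self) -> pd.Series:
        df = self.frame()
        df = df[~df["na"]]
        return df.groupby("family", sort=False)["percent"].sum()


def group_percent(rows) -> float:
    """Summed percentage share of a categorical family (e.g. the four wealth-quintile rows)."""
    rows = [r for r in rows if not r.is_na]
    if not rows:
        raise ValidationError("empty determinant family")
    return float(sum(r.percent for r in rows))


def decompose(fit: LogitFit, design: pd.DataFrame, living_standard,
              families: dict | None = None, rank_method: str = "i_over_n") -> DecompositionTable:
    """Steps 2-5 over a fitted model and the sample it was fitted on.

    ``living_standard`` ranks the sample (continuous wealth score by default
    upstream).  Zero-variance determinants yield an NA row excluded from the
    sum, mirroring survey cells with no variation.
    """
    if not fit.converged:
        raise ValidationError("decompose requires a converged fit")
    ranked = fractional_rank(np.asarray(living_standard, dtype=float), method=rank_method)
    outcome_ci = concentration_index(fit.linear_predictor, ranked).value
    mu = fit.linear_predictor_mean
    families = families or {}
    rows = []
    for col in design.columns:
        x = design[col].to_numpy(dtype=float)
        beta = fit.coefficients[col]
        if np.ptp(x) == 0.0 or x.mean() == 0.0:
            rows.append(
                DecompositionRow(col, beta, float(x.mean()), np.nan, np.nan, np.nan, np.nan,
                                 family=families.get(col), is_na=True)
            )
            continue
        ck = concentration_index(x, ranked).value
        rows.append(
            decompose_row(beta, float(x.mean()), mu, ck, outcome_ci, name=col,
                          family=families.get(col))
        )
    explained = sum(r.contribution for r in rows if not r.is_na)
    return DecompositionTable(
        rows=rows,
        outcome_ci=outcome_ci,
        outcome_lnodds_mean=mu,
        residual=outcome_ci - explained,
    )


def decompose_from_printed(rows: pd.DataFrame, lnodds_mean: float,
                           outcome_ci: float) -> DecompositionTable:
    """Fixture mode: recompute elasticity/contribution/percent from printed inputs.

    ``rows`` needs columns name, coefficient, mean, ci (and optionally family);
    rows with any missing input become NA rows.  The outcome CI is taken as
    printed rather than recomputed (the underlying microdata are not ours).
    """
    out = []
    for _, r in rows.iterrows():
        family = r.get("family")
        if pd.isna(r["coefficient"]) or pd.isna(r["mean"]) or pd.isna(r["ci"]):
            out.append(DecompositionRow(r["name"], np.nan, np.nan, np.nan, np.nan, np.nan,
                                        np.nan, family=family, is_na=True))
            continue
        out.append(
            decompose_row(float(r["coefficient"]), float(r["mean"]), lnodds_mean,
                          float(r["ci"]), outcome_ci, name=r["name"], family=family)
        )
    explained = sum(r.contribution for r in out if not r.is_na)
    return DecompositionTable(rows=out, outcome_ci=outcome_ci,
                              outcome_lnodds_mean=lnodds_mean,
                              residual=outcome_ci - explained)


class DecompositionResults:
    """Results wrapper: the fit, the table, and a text summary."""

    def __init__(self, model: "InequalityDecomposition", fit: LogitFit, table: DecompositionTable):
        self.model = model
        self.logit_fit = fit
        self.table = table

    @property
    def outcome_ci(self) -> float:
        return self.table.outcome_ci

    @property
    def residual(self) -> float:
        return self.table.residual

    def frame(self) -> pd.DataFrame:
        return self.table.frame()

    def family_percents(self) -> pd.Series:
        return self.table.family_percents()

    def summary(self) -> str:
        t = self.table
        lines = [
            "Decomposition of socioeconomic inequality (log-odds scale)",
            f"  n = {self.logit_fit.n}, mean ln-odds = {t.outcome_lnodds_mean:.4f}, "
            f"outcome CI = {t.outcome_ci:.4f}",
            f"  {'determinant':<28s}{'coef':>9s}{'mean':>8s}{'CI_k':>8s}{'contrib':>10s}{'%':>8s}",
        ]
        for r in t.rows:
            if r.is_na:
                lines.append(f"  {r.name:<28s}{r.coefficient:>9.3f}{r.mean:>8.3f}{'NA':>8s}{'NA':>10s}{'NA':>8s}")
            else:
                lines.append(
                    f"  {r.name:<28s}{r.coefficient:>9.3f}{r.mean:>8.3f}{r.determinant_ci:>8.3f}"
                    f"{r.contribution:>10.4f}{r.percent:>8.2f}"
                )
        lines.append(f"  residual (unexplained): {t.residual:+.4f}")
        fams = t.family_percents()
        if fams.notna().any():
            lines.append("  family shares (%): " + ", ".join(
                f"{k}={v:.2f}" for k, v in fams.items() if k is not None))
        return "\n".join(lines)


class InequalityDecomposition:
    """Model object: binary outcome, binary determinant matrix, living-standard ranking.

    Parameters
    ----------
    endog : array-like of 0/1
        The outcome (e.g. stunted).
    exog : DataFrame
        Binary determinant columns (reference categories omitted).
    living_standard : array-like
        Continuous ranking variable (e.g. the wealth-index score).
    families : dict, optional
        determinant name -> family label, for grouped percentage shares.
    """

    def __init__(self, endog, exog: pd.DataFrame, living_standard,
                 families: dict | None = None, rank_method: str = "i_over_n"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.living_standard = np.asarray(living_standard, dtype=float)
        if len(self.endog) != len(self.exog) or len(self.endog) != len(self.living_standard):
            raise ValidationError("endog, exog and living_standard must share length")
        self.families = families or {}
        self.rank_method = rank_method

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, determinants,
                       rank_by: str, families: dict | None = None) -> "InequalityDecomposition":
        missing = [c for c in [outcome, rank_by, *determinants] if c not in data.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        return cls(data[outcome].astype(float), data[list(determinants)].astype(float),
                   data[rank_by], families=families)

    def fit(self) -> DecompositionResults:
        # zero-variance determinants cannot enter the MLE; they come back as NA rows
        varying = [c for c in self.exog.columns if self.exog[c].nunique() > 1]
        dropped = [c for c in self.exog.columns if c not in varying]
        if not varying:
            raise DegenerateDataError("all determinants are constant")
        lfit = fit_logit(self.endog, self.exog[varying])
        for c in dropped:
            lfit.coefficients[c] = np.nan
        table = decompose(lfit, self.exog[varying + dropped] if dropped else self.exog,
                          self.living_standard, families=self.families,
                          rank_method=self.rank_method)
        return DecompositionResults(self, lfit, table)
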