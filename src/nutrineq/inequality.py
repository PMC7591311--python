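"""Fractional socioeconomic ranks and the concentration index.

The concentration index (CI) of a variable :math:`h` over a population ranked
by living standard is

.. math:: CI = \\frac{2\\,\\mathrm{cov}(h, r)}{\\bar h},

where :math:`r_i = i/N` is the fractional rank of unit :math:`i` in the
living-standard ordering (poorest first) and the covariance is the population
(1/N) covariance.  Negative values mean the variable is concentrated among
the poor; zero means no socioeconomic gradient.

The population covariance is deliberate: it is what makes the "convenient
regression" identity hold exactly (regressing :math:`2\\sigma_r^2 h/\\bar h`
on :math:`r` returns CI as the slope) and keeps :math:`|CI| \\le 1` for
nonnegative bounded variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedIndexError, ValidationError

__all__ = ["RankedSample", "CIResult", "fractional_rank", "concentration_index", "convenient_regression_ci"]


@dataclass(frozen=True)
class RankedSample:
    """Living standards with their fractional ranks (poorest first, ranks in (0, 1])."""

    living_standard: np.ndarray
    fractional_rank: np.ndarray

    def __len__(self) -> int:
        return len(self.fractional_rank)


@dataclass(frozen=True)
class CIResult:
    value: float
    variable_mean: float
    covariance: float
    n: int


def fractional_rank(standards, method: str = "i_over_n") -> RankedSample:
    """Fractional ranks r_i = i/N in the living-standard ordering.

    Ties receive the mean of their positions' i/N values.  ``method`` may be
    ``"i_over_n"`` (default) or ``"midpoint"`` for the (2i-1)/(2N) variant;
    the two differ by O(1/N).
    """
    x = np.asarray(standards, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need a one-dimensional sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("living standards must be finite")
    n = len(x)
    r = rankdata(x, method="average")
    if method == "i_over_n":
        ranks = r / n
    elif method == "midpoint":
        ranks = (2.0 * r - 1.0) / (2.0 * n)
    else:
        raise ValidationError(f"unknown rank method {method!r}")
    return RankedSample(living_standard=x, fractional_rank=ranks)


def concentration_index(values, ranks: RankedSample | np.ndarray) -> CIResult:
    """CI = 2 cov_pop(value, rank) / mean(value).

    Raises :class:`UndefinedIndexError` when the variable mean is zero.
    """
    h = np.asarray(values, dtype=float)
    r = ranks.fractional_rank if isinstance(ranks, RankedSample) else np.asarray(ranks, dtype=float)
    if h.shape != r.shape:
        raise ValidationError("values and ranks must have the same length")
    if not np.all(np.isfinite(h)):
        raise ValidationError("values must be finite")
    mean = float(h.mean())
    if mean == 0.0:
        raise UndefinedIndexError("concentration index undefined for a zero-mean variable")
    cov = float(np.mean((h - mean) * (r - r.mean())))
    return CIResult(value=2.0 * cov / mean, variable_mean=mean, covariance=cov, n=len(h))


def convenient_regression_ci(values, ranks: RankedSample | np.ndarray) -> float:
    """CI via the convenient-regression identity (OLS slope); cross-check route.

    Regress :math:`2\\sigma_r^2\\, h_i/\\bar h` on :math:`r_i`; the slope equals
    the covariance-formula CI exactly under the population covariance.
    """
    h = np.asarray(values, dtype=float)
    r = ranks.fractional_rank if isinstance(ranks, RankedSample) else np.asarray(ranks, dtype=float)
    mean = h.mean()
    if mean == 0.0:
        raise UndefinedIndexError("concentration index undefined for a zero-mean variable")
    var_r = np.mean((r - r.mean()) ** 2)
    y = 2.0 * var_r * h / mean
    slope = np.polyfit(r, y, 1)[0]
    return float(slope)
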