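"""Asset-based household wealth index (Filmer-Pritchett first principal component).

Each asset indicator is standardized to mean 0 / variance 1 and the household
score is the projection onto the first eigenvector of the asset correlation
matrix.  WASH indicators are deliberately *not* part of the asset set (they
are analysed as determinants in their own right, so including them in the
ranking variable would build the answer into the question).

The principal-component sign is arbitrary; it is oriented so that households
owning a configurable "luxury anchor" asset (default: refrigerator) score
higher on average.  Scores are divided into quintiles (poorest, poor, middle,
rich, richest) at the empirical 20/40/60/80 percentiles, tied scores sharing
the lower quintile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError

__all__ = ["QUINTILE_LABELS", "WealthScores", "WealthIndex", "fit_wealth_index", "assign_quintiles"]

QUINTILE_LABELS = ("poorest", "poor", "middle", "rich", "richest")

#: Asset-name prefixes that must never enter the index (WASH family).
_EXCLUDED_PREFIXES = ("water", "sanitation")


@dataclass
class WealthScores:
    """First-PC asset index: per-household score, loadings, and quintile labels."""

    scores: pd.Series  # household_id -> score
    loadings: dict
    explained_variance_fraction: float
    quintiles: pd.Series | None = None
    dropped_assets: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Asset-based wealth index (first principal component)"]
        lines.append(f"  households: {len(self.scores)}")
        lines.append(f"  explained variance fraction: {self.explained_variance_fraction:.3f}")
        lines.append("  loadings:")
        for k, v in sorted(self.loadings.items(), key=lambda kv: -abs(kv[1])):
            lines.append(f"    {k:<28s} {v:+.4f}")
        if self.dropped_assets:
            lines.append(f"  dropped (zero variance): {', '.join(self.dropped_assets)}")
        if self.quintiles is not None:
            counts = self.quintiles.value_counts().reindex(QUINTILE_LABELS, fill_value=0)
            lines.append("  quintile sizes: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        return "\n".join(lines)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        if self.quintiles is not None:
            df["quintile"] = self.quintiles
        df.index.name = "household_id"
        return df


class WealthIndex:
    """Model object: build from an asset-indicator matrix, ``fit`` returns :class:`WealthScores`.

    Parameters
    ----------
    assets : DataFrame
        One row per household (index = household_id), one 0/1 column per
        asset indicator.  WASH-named columns are refused.
    anchor : str
        Asset used to orient the component sign (owners score higher).  If
        absent from the columns, the sign is chosen so the sum of loadings
        is positive.
    """

    def __init__(self, assets: pd.DataFrame, anchor: str = "refrigerator"):
        if assets.shape[0] < 2:
            raise ValidationError("need at least 2 households")
        if assets.shape[1] < 2:
            raise ValidationError("need at least 2 asset indicators")
        bad = [c for c in assets.columns if str(c).startswith(_EXCLUDED_PREFIXES)]
        if bad:
            raise ValidationError(f"WASH indicators may not enter the wealth index: {bad}")
        self.assets = assets.astype(float)
        self.anchor = anchor

    def fit(self) -> WealthScores:
        X = self.assets
        sd = X.std(axis=0, ddof=0)
        keep = sd[sd > 0].index.tolist()
        dropped = [c for c in X.columns if c not in keep]
        if dropped:
            warnings.warn(f"dropping zero-variance assets: {dropped}", stacklevel=2)
        if len(keep) == 0:
            raise DegenerateDataError("all asset indicators are constant")
        Xk = X[keep]
        Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=0)
        corr = np.asarray(Z.T @ Z) / len(Z)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        v1 = eigvec[:, 0]
        scores = pd.Series(np.asarray(Z) @ v1, index=X.index, name="score")
        # orient: anchor owners score higher on average
        if self.anchor in keep:
            owners = Xk[self.anchor] > 0
            if owners.any() and scores[owners].mean() < scores.mean():
                v1, scores = -v1, -scores
        elif v1.sum() < 0:
            v1, scores = -v1, -scores
        loadings = dict(zip(keep, v1))
        evf = float(eigval[0] / eigval.sum()) if eigval.sum() > 0 else 0.0
        return WealthScores(
            scores=scores,
            loadings=loadings,
            explained_variance_fraction=evf,
            dropped_assets=dropped,
        )


def fit_wealth_index(assets: pd.DataFrame, anchor: str = "refrigerator") -> WealthScores:
    """Functional wrapper over :class:`WealthIndex`."""
    return WealthIndex(assets, anchor=anchor).fit()


def assign_quintiles(ws: WealthScores) -> WealthScores:
    """Partition households into quintiles at the 20/40/60/80 empirical percentiles.

    Tied scores share a quintile (assigned to the lower cut side), so the
    five groups differ in size by at most the tie-block size.
    """
    scores = ws.scores
    if len(scores) < 5:
        raise ValidationError("need at least 5 households for quintiles")
    cuts = np.percentile(scores.to_numpy(), [20, 40, 60, 80])
    idx = np.searchsorted(cuts, scores.to_numpy(), side="left")
    ws.quintiles = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(QUINTILE_LABELS)),
        index=scores.index,
        name="quintile",
    )
    return ws
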