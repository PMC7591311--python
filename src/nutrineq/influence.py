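"""Gradient-boosted regression trees (Bernoulli loss) with Friedman relative influence.

The ensemble is built from scratch: depth-limited CART regression trees are
fitted by least squares to the working response (the negative gradient of the
Bernoulli deviance, ``y - p``), terminal-node values take a single Newton
step, and trees are added with shrinkage.  Rows are subsampled without
replacement per tree (bagging) under a single integer seed, so a fitted
model is a deterministic function of (data, config).

Variable importance follows Friedman: each split's squared-error improvement
on the working response is credited to the split variable; per-variable
totals over all splits and trees are scaled to percentages summing to 100.

:func:`rank_risk_factors` applies the machinery to the eight binary risk
indicators used for child stunting/wasting screening (low wealth quintile,
no maternal education, low child feeding index, no health-campaign access,
no birth certificate, nonimproved sanitation, inadequate water treatment,
nonimproved water source), reporting zero-variance indicators as NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "BoostConfig",
    "GradientBoostedTrees",
    "BoostResults",
    "InfluenceReport",
    "fit_brt",
    "relative_influence",
    "select_n_trees",
    "rank_risk_factors",
    "RISK_INDICATORS",
]


@dataclass(frozen=True)
class BoostConfig:
    n_trees: int = 1000
    learning_rate: float = 0.01
    max_depth: int = 3
    bag_fraction: float = 0.75
    min_node: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 0 or self.max_depth < 1 or self.min_node < 1:
            raise ValidationError("n_trees, max_depth, min_node must be positive")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if not (0 < self.bag_fraction <= 1):
            raise ValidationError("bag_fraction must lie in (0, 1]")


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    value: float = 0.0
    left: "_Node" = None
    right: "_Node" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def _best_split(x: np.ndarray, z: np.ndarray, min_node: int):
    """Best squared-error split of z along x; returns (improvement, threshold) or None."""
    order = np.argsort(x, kind="stable")
    xs, zs = x[order], z[order]
    m = len(zs)
    if m < 2 * min_node:
        return None
    cz = np.cumsum(zs)
    total = cz[-1]
    k = np.arange(1, m)  # left-child sizes
    valid = (xs[1:] != xs[:-1]) & (k >= min_node) & (m - k >= min_node)
    if not valid.any():
        return None
    left = cz[:-1]
    imp = left**2 / k + (total - left) ** 2 / (m - k) - total**2 / m
    imp = np.where(valid, imp, -np.inf)
    best = int(np.argmax(imp))
    if imp[best] <= 1e-12:
        return None
    thr = 0.5 * (xs[best] + xs[best + 1])
    return float(imp[best]), thr


def _build_tree(X: np.ndarray, z: np.ndarray, w: np.ndarray, idx: np.ndarray,
                depth: int, cfg: BoostConfig, improvements: np.ndarray) -> _Node:
    node = _Node()
    zw = z[idx]
    # Newton terminal estimate for Bernoulli loss: sum(z)/sum(p(1-p))
    denom = w[idx].sum()
    node.value = float(zw.sum() / denom) if denom > 1e-12 else 0.0
    if depth >= cfg.max_depth or len(idx) < 2 * cfg.min_node:
        return node
    best_imp, best_feat, best_thr = 0.0, -1, 0.0
    for j in range(X.shape[1]):
        res = _best_split(X[idx, j], zw, cfg.min_node)
        if res is not None and res[0] > best_imp:
            best_imp, best_feat, best_thr = res[0], j, res[1]
    if best_feat < 0:
        return node
    improvements[best_feat] += best_imp
    node.feature, node.threshold = best_feat, best_thr
    mask = X[idx, best_feat] <= best_thr
    node.left = _build_tree(X, z, w, idx[mask], depth + 1, cfg, improvements)
    node.right = _build_tree(X, z, w, idx[~mask], depth + 1, cfg, improvements)
    return node


def _predict_tree(node: _Node, X: np.ndarray, out: np.ndarray, idx: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.value
        return
    mask = X[idx, node.feature] <= node.threshold
    _predict_tree(node.left, X, out, idx[mask])
    _predict_tree(node.right, X, out, idx[~mask])


def _sigmoid(f: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(f, -500, 500)))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    return float(-2.0 * np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


@dataclass
class InfluenceReport:
    """Per-variable relative influence (percent, summing to 100) with NA support."""

    influence: pd.Series  # variable -> percent (NaN = indicator had no variation)

    @property
    def ordering(self) -> list:
        return list(self.influence.dropna().sort_values(ascending=False).index)

    def frame(self) -> pd.DataFrame:
        df = self.influence.rename("influence_percent").to_frame()
        df.index.name = "variable"
        return df


class BoostResults:
    """Fitted ensemble: trees, deviance path, predictions, relative influence."""

    def __init__(self, model: "GradientBoostedTrees", trees: list, f0: float,
                 improvements: np.ndarray, deviance_path: np.ndarray):
        self.model = model
        self.trees = trees
        self.f0 = f0
        self._improvements = improvements
        self.deviance_path = deviance_path

    @property
    def n_splits(self) -> int:
        def count(node):
            return 0 if node.is_leaf else 1 + count(node.left) + count(node.right)

        return sum(count(t) for t in self.trees)

    def decision_function(self, X, n_trees: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        f = np.full(len(X), self.f0)
        trees = self.trees if n_trees is None else self.trees[:n_trees]
        out = np.empty(len(X))
        idx = np.arange(len(X))
        for tree in trees:
            _predict_tree(tree, X, out, idx)
            f += self.model.config.learning_rate * out
        return f

    def predict_proba(self, X, n_trees: int | None = None) -> np.ndarray:
        return _sigmoid(self.decision_function(X, n_trees))

    def relative_influence(self) -> InfluenceReport:
        """Friedman influence: squared-error split improvements, scaled to sum 100."""
        total = self._improvements.sum()
        if total <= 0:
            raise DegenerateDataError("no structure learned: the ensemble made no splits")
        pct = 100.0 * self._improvements / total
        return InfluenceReport(pd.Series(pct, index=list(self.model.feature_names)))

    def summary(self) -> str:
        rep = self.relative_influence()
        lines = [
            "Gradient-boosted trees (Bernoulli deviance)",
            f"  n = {self.model.n}, trees = {len(self.trees)}, "
            f"depth <= {self.model.config.max_depth}, shrinkage = {self.model.config.learning_rate}",
            f"  training deviance: {self.deviance_path[0]:.4f} -> {self.deviance_path[-1]:.4f}"
            if len(self.deviance_path)
            else "  training deviance: (no trees)",
            "  relative influence (%):",
        ]
        for name in rep.ordering:
            lines.append(f"    {name:<36s} {rep.influence[name]:6.2f}")
        return "\n".join(lines)


class GradientBoostedTrees:
    """Model object: binary outcome boosted on a numeric predictor matrix."""

    def __init__(self, endog, exog, config: BoostConfig = BoostConfig()):
        if isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(endog, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValidationError("need a 2-D predictor matrix with >= 2 columns")
        if len(y) != len(X):
            raise ValidationError("endog and exog must share length")
        if y.min() == y.max():
            raise ValidationError("outcome has a single class")
        if all(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
            raise DegenerateDataError("all predictors are constant")
        self.X, self.y = X, y
        self.n = len(y)
        self.config = config

    def fit(self) -> BoostResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        p_base = self.y.mean()
        f0 = math.log(p_base / (1.0 - p_base))
        f = np.full(self.n, f0)
        trees, devs = [], []
        improvements = np.zeros(self.X.shape[1])
        bag_size = max(2 * cfg.min_node, math.ceil(cfg.bag_fraction * self.n))
        bag_size = min(bag_size, self.n)
        out = np.empty(self.n)
        all_idx = np.arange(self.n)
        for _ in range(cfg.n_trees):
            p = _sigmoid(f)
            z = self.y - p
            w = p * (1.0 - p)
            bag = np.sort(rng.choice(self.n, size=bag_size, replace=False))
            tree = _build_tree(self.X, z, w, bag, 0, cfg, improvements)
            trees.append(tree)
            _predict_tree(tree, self.X, out, all_idx)
            f = f + cfg.learning_rate * out
            devs.append(_deviance(self.y, _sigmoid(f)))
        return BoostResults(self, trees, f0, improvements, np.asarray(devs))


def fit_brt(outcome, risk_factors, config: BoostConfig = BoostConfig()) -> BoostResults:
    """Functional wrapper over :class:`GradientBoostedTrees`."""
    return GradientBoostedTrees(outcome, risk_factors, config).fit()


def relative_influence(results: BoostResults) -> InfluenceReport:
    return results.relative_influence()


def select_n_trees(outcome, risk_factors, config: BoostConfig, n_folds: int = 5) -> int:
    """Effective tree count by k-fold cross-validated Bernoulli deviance."""
    X = risk_factors.to_numpy(dtype=float) if isinstance(risk_factors, pd.DataFrame) else np.asarray(risk_factors, float)
    y = np.asarray(outcome, dtype=float)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(y))
    folds = np.array_split(perm, n_folds)
    dev = np.zeros(config.n_trees)
    for k in range(n_folds):
        val = folds[k]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        res = GradientBoostedTrees(y[train], X[train], replace(config, seed=config.seed + k + 1)).fit()
        f = np.full(len(val), res.f0)
        out = np.empty(len(val))
        idx = np.arange(len(val))
        for m, tree in enumerate(res.trees):
            _predict_tree(tree, X[val], out, idx)
            f += config.learning_rate * out
            dev[m] += _deviance(y[val], _sigmoid(f)) * len(val)
    return int(np.argmin(dev)) + 1


#: The eight binary risk indicators (1 = risk present), keyed by the columns
#: of the analysis frame they derive from.
RISK_INDICATORS = {
    "low_wealth_quintile": lambda df: (df["wealth_quintile"] == "poorest"),
    "no_mother_education": lambda df: (df["mother_education"] == "none"),
    "low_cfi_score": lambda df: (df["cfi_class"] == "low"),
    "no_campaign_access": lambda df: ~df["campaign_access"].astype(bool),
    "no_birth_certificate": lambda df: ~df["birth_certificate"].astype(bool),
    "nonimproved_sanitation": lambda df: (df["sanitation"] == "nonimproved"),
    "no_adequate_water_treatment": lambda df: (df["water_treatment"] == "not_adequate"),
    "nonimproved_water_source": lambda df: (df["water_source"] == "nonimproved"),
}


def rank_risk_factors(data: pd.DataFrame, outcome: str, region: str | None = None,
                      config: BoostConfig = BoostConfig()) -> InfluenceReport:
    """Influence ranking of the eight risk indicators for one outcome and region.

    ``data`` is the per-child analysis frame (one row per child with its
    household variables merged in).  Indicators with no variation in the
    region are reported NA; the remaining influences still sum to 100.
    """
    df = data if region is None else data[data["region"] == region]
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError(f"outcome {outcome!r} has a single class in region {region!r}")
    indicators = pd.DataFrame({name: fn(df).astype(float).to_numpy()
                               for name, fn in RISK_INDICATORS.items()})
    # canonicalize row order so the report is invariant to input shuffling
    # (bagging draws row indices, so the fit depends on row order otherwise)
    order = np.lexsort([y] + [indicators[c].to_numpy() for c in indicators.columns])
    y = y[order]
    indicators = indicators.iloc[order].reset_index(drop=True)
    varying = [c for c in indicators.columns if indicators[c].nunique() > 1]
    degenerate = [c for c in indicators.columns if c not in varying]
    res = GradientBoostedTrees(y, indicators[varying], config).fit()
    rep = res.relative_influence()
    full = rep.influence.reindex(list(RISK_INDICATORS))
    full[degenerate] = np.nan
    return InfluenceReport(full)
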