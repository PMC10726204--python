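"""Integrated feature selection: PC filter + RF importance + patience-limited RFE.

The PCRF-RFE procedure combines the three classical families of feature
selection:

1. **Filter** — rank every vegetation index by the absolute Pearson
   correlation with observed yield, |r(X, y)| with
   r = Cov(X, Y)/sqrt(Var(X) Var(Y)), and keep indices whose score
   strictly exceeds a threshold (default 0.53).
2. **Embedded** — rank indices by random-forest permutation importance
   (percent increase in out-of-bag MSE when the feature is permuted,
   averaged over trees) and keep those strictly above a second
   threshold (default 1.9, on the percent-increase scale).
3. The **union** of the two retained sets seeds a **wrapper**:
   recursive feature elimination over a pluggable base regressor.  At
   each iteration the base model is fitted on the current subset, the
   subset is scored by inner cross-validated RMSE, and the least
   important feature (base-model importance) is removed.  The best
   subset seen is tracked; elimination stops after ``patience``
   consecutive non-improving removals (default 10) or when one feature
   remains.

|r| (not signed r) is used because strongly *negatively* correlated
indices are just as informative for prediction.  All tie-breaks use the
canonical index-table order, and every stochastic step takes an
explicit seed, so the pipeline is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .evaluate import DegenerateTargetError, kfold_cv
from .feature_sets import FeatureRanking, FeatureSubset
from .models import ModelSpec, fit, model_importance
from .vegindex import index_order

__all__ = [
    "ForestConfig",
    "RFEConfig",
    "EmptySubsetError",
    "pearson_ranking",
    "rf_ranking",
    "apply_threshold",
    "combine_subsets",
    "rfe_select",
    "pcrf_rfe",
]


class EmptySubsetError(ValueError):
    """No feature survived; relax the thresholds."""


def _feature_frame(vitable) -> pd.DataFrame:
    return vitable.data if hasattr(vitable, "data") else vitable


def _order_key(name: str):
    try:
        return (0, index_order(name))
    except KeyError:
        return (1, name)


# ---------------------------------------------------------------------------
# Filter ranking: Pearson correlation
# ---------------------------------------------------------------------------


def pearson_ranking(vitable, y: Sequence[float]) -> FeatureRanking:
    """Rank features by |Pearson r| with the target.

    Missing feature values are dropped pairwise; features with zero
    variance (or fewer than 3 valid pairs) score 0 with a warning.  A
    constant target raises :class:`~yieldvi.evaluate.DegenerateTargetError`.
    """
    X = _feature_frame(vitable)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y length must match the feature table")
    if len(y) < 3:
        raise ValueError("need at least 3 plots")
    if np.var(y) == 0:
        raise DegenerateTargetError("target is constant; correlation undefined")
    scores: dict[str, float] = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xi, yi = x[ok], y[ok]
        if len(xi) < 3 or np.var(xi) == 0 or np.var(yi) == 0:
            warnings.warn(
                f"feature {col!r} has no usable variance; score set to 0",
                UserWarning,
                stacklevel=2,
            )
            scores[col] = 0.0
            continue
        cov = np.mean((xi - xi.mean()) * (yi - yi.mean()))
        r = cov / np.sqrt(np.var(xi) * np.var(yi))
        scores[col] = float(abs(r))
    return FeatureRanking.from_scores("PC", scores)


# ---------------------------------------------------------------------------
# Embedded ranking: random-forest OOB permutation importance
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ForestConfig:
    """Regression-forest hyperparameters (R randomForest-style defaults)."""

    n_trees: int = 500
    mtry: int | None = None  # None -> max(1, p // 3)
    min_samples_leaf: int = 5


def rf_ranking(
    vitable,
    y: Sequence[float],
    forest_config: ForestConfig | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by random-forest OOB permutation importance.

    A bagged ensemble of regression trees is grown on bootstrap samples;
    for each tree the out-of-bag MSE is compared with the OOB MSE after
    permuting one feature at a time, and the per-tree increases are
    averaged and expressed as a percent increase over the baseline OOB
    MSE.  Deterministic given the seed.  Rows with any missing feature
    are dropped.
    """
    cfg = forest_config or ForestConfig()
    X = _feature_frame(vitable)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y length must match the feature table")
    keep = ~X.isna().any(axis=1).to_numpy()
    Xv = X.to_numpy(dtype=float)[keep]
    yv = y[keep]
    n, p = Xv.shape
    if n < 10:
        raise ValueError(f"need at least 10 complete rows for the forest, got {n}")
    mtry = cfg.mtry if cfg.mtry is not None else max(1, p // 3)
    rng = np.random.default_rng(seed)

    base_mses: list[float] = []
    perm_increase = np.zeros(p)
    n_used = 0
    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        m = int(oob_mask.sum())
        tree_seed = int(rng.integers(2**31 - 1))
        perms = [rng.permutation(m) for _ in range(p)]
        if m < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=tree_seed,
        )
        tree.fit(Xv[boot], yv[boot])
        Xo, yo = Xv[oob_mask], yv[oob_mask]
        # stack the baseline block and one permuted block per feature into a
        # single predict call per tree
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perms[j], j]
            blocks.append(Xp)
        preds = tree.predict(np.vstack(blocks))
        mses = ((preds.reshape(p + 1, m) - yo) ** 2).mean(axis=1)
        base_mses.append(mses[0])
        perm_increase += mses[1:] - mses[0]
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    base = float(np.mean(base_mses))
    scores = {
        col: float(100.0 * (perm_increase[j] / n_used) / base)
        for j, col in enumerate(X.columns)
    }
    return FeatureRanking.from_scores("RF", scores)


# ---------------------------------------------------------------------------
# Thresholding and set combination
# ---------------------------------------------------------------------------


def apply_threshold(
    ranking: FeatureRanking, tau: float, mode: str = "absolute"
) -> FeatureSubset:
    """Retain the features whose score strictly exceeds the threshold.

    ``mode="absolute"`` compares scores to ``tau`` directly.  Because
    importance scales are data-dependent, ``mode="quantile"`` instead
    retains scores strictly above the ``(1 - tau)`` empirical quantile
    of all scores (i.e. roughly the top fraction ``tau``).
    """
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    if mode == "absolute":
        cut = float(tau)
    elif mode == "quantile":
        if not 0.0 <= tau <= 1.0:
            raise ValueError("quantile-mode threshold must be in [0, 1]")
        cut = float(np.quantile([s for _, s in ranking.scores], 1.0 - tau))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    retained = [n for n, s in ranking.scores if s > cut]
    return FeatureSubset.create(
        retained,
        [
            {
                "step": "threshold",
                "method": ranking.method,
                "mode": mode,
                "threshold": float(tau),
                "scores": [[n, s] for n, s in ranking.scores],
            }
        ],
    )


def combine_subsets(a: FeatureSubset, b: FeatureSubset, mode: str = "union") -> FeatureSubset:
    """Union or intersection of two subsets; provenance is concatenated."""
    if mode == "union":
        names = set(a.names) | set(b.names)
    elif mode == "intersection":
        names = set(a.names) & set(b.names)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    prov = list(a.provenance) + list(b.provenance) + [{"step": "combine", "mode": mode}]
    return FeatureSubset.create(names, prov)


# ---------------------------------------------------------------------------
# Wrapper: recursive feature elimination with patience
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RFEConfig:
    """Recursive-feature-elimination settings.

    ``patience`` counts consecutive eliminations without improvement of
    the best inner-CV RMSE (strict improvement by more than ``tol``);
    when it is exhausted the best subset seen so far is returned.
    """

    model_spec: ModelSpec
    patience: int = 10
    step: int = 1
    cv_folds: int = 10
    seed: int = 0
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _inner_score(vitable, y, names: Sequence[str], config: RFEConfig) -> float:
    res = kfold_cv(
        vitable, y, names, config.model_spec, k=config.cv_folds, seed=config.seed
    )
    return res.mean_rmse


def rfe_select(
    vitable, y: Sequence[float], start_subset: FeatureSubset, config: RFEConfig
) -> FeatureSubset:
    """Patience-limited recursive feature elimination from a start subset.

    Returns the best-seen subset (by inner-CV RMSE) with the full score
    trace in its provenance.  Deterministic given the config seed.
    """
    if len(start_subset) == 0:
        raise EmptySubsetError("start subset is empty")
    X = _feature_frame(vitable)
    y = np.asarray(y, dtype=float)
    current = list(start_subset.names)

    best_names = list(current)
    best_rmse = _inner_score(vitable, y, current, config)
    trace = [{"n_features": len(current), "cv_rmse": best_rmse, "dropped": None}]
    stale = 0
    iteration = 0
    while len(current) > 1 and stale < config.patience:
        iteration += 1
        try:
            model = fit(X[current], y, config.model_spec)
            imp = model_importance(
                model, X[current], y, seed=config.seed + iteration
            )
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(
                f"base model failed at RFE iteration {iteration} "
                f"({len(current)} features)"
            ) from exc
        # drop the `step` least important; ties drop the later table entry
        by_importance = sorted(
            current, key=lambda f: (imp.score_of(f), -_order_key(f)[1])
        )
        n_drop = min(config.step, len(current) - 1)
        dropped = by_importance[:n_drop]
        current = [f for f in current if f not in dropped]
        score = _inner_score(vitable, y, current, config)
        trace.append(
            {"n_features": len(current), "cv_rmse": score, "dropped": list(dropped)}
        )
        if score < best_rmse - config.tol:
            best_rmse = score
            best_names = list(current)
            stale = 0
        else:
            stale += 1
    prov = list(start_subset.provenance) + [
        {
            "step": "rfe",
            "model": config.model_spec.to_dict(),
            "patience": config.patience,
            "elimination_step": config.step,
            "cv_folds": config.cv_folds,
            "seed": config.seed,
            "best_cv_rmse": best_rmse,
            "trace": trace,
        }
    ]
    return FeatureSubset.create(best_names, prov)


# ---------------------------------------------------------------------------
# The integrated pipeline
# ---------------------------------------------------------------------------


def pcrf_rfe(
    vitable,
    y: Sequence[float],
    rfe_config: RFEConfig,
    pc_tau: float = 0.53,
    rf_tau: float = 1.9,
    forest_config: ForestConfig | None = None,
    forest_seed: int = 0,
) -> FeatureSubset:
    """PC ranking + RF ranking -> thresholds -> union -> patience-limited RFE.

    This is the full integrated selector; the returned subset's
    provenance records every stage.  Raises :class:`EmptySubsetError`
    (suggesting threshold relaxation) when no feature survives the
    union.
    """
    pc = pearson_ranking(vitable, y)
    rf = rf_ranking(vitable, y, forest_config=forest_config, seed=forest_seed)
    sub_pc = apply_threshold(pc, pc_tau)
    sub_rf = apply_threshold(rf, rf_tau)
    union = combine_subsets(sub_pc, sub_rf, "union")
    if len(union) == 0:
        raise EmptySubsetError(
            "no feature exceeded either threshold; relax pc_tau/rf_tau "
            "or use quantile mode"
        )
    return rfe_select(vitable, y, union, rfe_config)
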