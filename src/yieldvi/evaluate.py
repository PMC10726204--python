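"""Cross-validated accuracy metrics, yield descriptives and treatment t-tests.

Model accuracy is measured by the coefficient of determination

    R² = 1 − Σ(ŷᵢ − yᵢ)² / Σ(yᵢ − ȳ)²

and the root-mean-square error

    RMSE = sqrt( Σ(ŷᵢ − yᵢ)² / N )          [t·ha⁻¹]

assessed by k-fold cross-validation: the plots are randomly partitioned
into k folds, each fold serves once as the validation set while the
model is trained on the remaining k−1 folds, and the per-fold metrics
are averaged into the final accuracy.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .models import ModelSpec, fit, predict

__all__ = [
    "CVResult",
    "YieldSummary",
    "DegenerateTargetError",
    "r_squared",
    "rmse",
    "kfold_cv",
    "describe_yield",
    "treatment_ttest",
]


class DegenerateTargetError(ValueError):
    """The observed target is constant, so the statistic is undefined."""


def r_squared(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot.

    At most 1; negative when the predictions are worse than the mean of
    the observations. Raises :class:`DegenerateTargetError` on a
    constant observed vector (SS_tot = 0).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    if y_obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTargetError("observed values are constant; R² undefined")
    ss_res = float(np.sum((y_pred - y_obs) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Root-mean-square error in the units of the target (t·ha⁻¹ for yield)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    if y_obs.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))


@dataclasses.dataclass
class CVResult:
    """Per-fold and mean accuracy for one model × feature subset."""

    k: int
    fold_r2: list[float]
    fold_rmse: list[float]
    fold_sizes: list[int]
    mean_r2: float
    mean_rmse: float
    seed: int
    model: dict
    subset: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def kfold_cv(
    vitable,
    y: Sequence[float],
    subset: Sequence[str],
    model_spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    stratify_labels: Sequence | None = None,
) -> CVResult:
    """k-fold cross-validated accuracy of one model on one feature subset.

    The partition is simple random (seeded); pass ``stratify_labels``
    (e.g. water-treatment labels) for a stratified partition instead.
    Each plot lands in exactly one validation fold.  Rows with a missing
    value in any selected feature are dropped with a warning before
    partitioning.
    """
    X = _feature_frame(vitable, subset)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y length must match the feature table")
    keep = ~X.isna().any(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} row(s) with undefined feature values",
            UserWarning,
            stacklevel=2,
        )
        X, y = X.loc[keep], y[keep]
        if stratify_labels is not None:
            stratify_labels = np.asarray(stratify_labels)[keep]
    n = len(X)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} plots into {k} folds")

    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X)

    fold_r2, fold_rmse, fold_sizes = [], [], []
    for i, (tr, va) in enumerate(split):
        model = fit(X.iloc[tr], y[tr], model_spec)
        pred = predict(model, X.iloc[va])
        # R² is undefined on a degenerate validation fold (size 1 or
        # constant observations, e.g. leave-one-out); record NaN there
        if len(va) < 2 or np.ptp(y[va]) == 0:
            fold_r2.append(float("nan"))
        else:
            fold_r2.append(r_squared(y[va], pred))
        fold_rmse.append(rmse(y[va], pred))
        fold_sizes.append(len(va))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN folds
        mean_r2 = float(np.nanmean(fold_r2))
    return CVResult(
        k=k,
        fold_r2=fold_r2,
        fold_rmse=fold_rmse,
        fold_sizes=fold_sizes,
        mean_r2=mean_r2,
        mean_rmse=float(np.mean(fold_rmse)),
        seed=seed,
        model=model_spec.to_dict(),
        subset=list(subset),
    )


def _feature_frame(vitable, subset: Sequence[str]) -> pd.DataFrame:
    """Select subset columns from a VITable or plain DataFrame."""
    data = vitable.data if hasattr(vitable, "data") else vitable
    missing = [s for s in subset if s not in data.columns]
    if missing:
        raise KeyError(f"subset names absent from feature table: {missing}")
    return data[list(subset)]


@dataclasses.dataclass
class YieldSummary:
    """Descriptive yield statistics per group (and overall)."""

    table: pd.DataFrame  # rows: groups; columns: n, min, max, sd, q25, q50, q75, mean, cv_pct


def describe_yield(
    yields: Sequence[float], groups: Sequence | None = None
) -> YieldSummary:
    """Group-wise descriptive statistics of observed yield.

    SD is the sample standard deviation (n−1 denominator); quartiles use
    linear interpolation between order statistics; CV is SD/mean as a
    percentage.  An "All" row summarises every plot.  Empty groups are
    omitted with a warning.
    """
    y = np.asarray(yields, dtype=float)
    if np.any(y <= 0):
        warnings.warn("non-positive yields present", UserWarning, stacklevel=2)
    frames: dict[str, np.ndarray] = {"All": y}
    if groups is not None:
        if isinstance(groups, pd.Series) and isinstance(groups.dtype, pd.CategoricalDtype):
            labels = list(groups.cat.categories)
        elif isinstance(groups, pd.Categorical):
            labels = list(groups.categories)
        else:
            labels = list(pd.unique(np.asarray(groups)))
        groups = np.asarray(groups)
        if len(groups) != len(y):
            raise ValueError("groups must label every plot")
        for g in labels:
            sel = y[groups == g]
            if sel.size == 0:
                warnings.warn(f"group {g!r} is empty; omitted", UserWarning, stacklevel=2)
                continue
            frames[str(g)] = sel
    rows = {}
    for name, v in frames.items():
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        mean = float(np.mean(v))
        rows[name] = {
            "n": int(v.size),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "sd": sd,
            "q25": float(np.quantile(v, 0.25)),
            "q50": float(np.quantile(v, 0.50)),
            "q75": float(np.quantile(v, 0.75)),
            "mean": mean,
            "cv_pct": float(sd / mean * 100.0) if mean > 0 else np.nan,
        }
    return YieldSummary(table=pd.DataFrame(rows).T)


class UndefinedTestError(ValueError):
    """Both groups have zero variance; the t statistic is undefined."""


def treatment_ttest(values: Sequence[float], treatment_labels: Sequence) -> pd.DataFrame:
    """Welch two-sample t-test for every unordered pair of treatments.

    Returns a table with columns ``pair, t, df, p``: the Welch statistic,
    Welch–Satterthwaite degrees of freedom, and the two-sided p-value.
    p-values are reported raw (no multiple-testing correction by
    default); pass the result through :func:`holm_adjust` if desired.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(treatment_labels)
    if len(values) != len(labels):
        raise ValueError("labels must match values")
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two treatments")
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        va, vb = values[labels == a], values[labels == b]
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"treatments {a!r}/{b!r} need at least 2 plots each")
        if np.var(va, ddof=1) == 0 and np.var(vb, ddof=1) == 0:
            raise UndefinedTestError(f"zero variance in both groups for {a} vs {b}")
        res = stats.ttest_ind(va, vb, equal_var=False)
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def holm_adjust(ttable: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjustment of the p column (optional, off by default)."""
    out = ttable.copy()
    p = out["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    out["p_holm"] = adj
    return out
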