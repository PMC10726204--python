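"""Rule-based model tree regressor in the Cubist / M5 family.

The feature space is recursively partitioned by axis-parallel splits
chosen to maximise standard-deviation reduction, and an ordinary
least-squares linear model is fitted in every node.  Subtrees whose
penalised error exceeds that of their node's own linear model are
pruned back, and predictions are smoothed along the root-to-leaf path
(M5 smoothing), which is what gives model trees their characteristic
piecewise-linear-with-soft-edges response.

Each root-to-leaf path is equivalently a rule

    if  [conjunction of split conditions]  then  [linear regression]

which is the representation the ``rules()`` accessor exposes.

Defaults: one committee (no boosting), no instance-based correction,
minimum 4 rows to attempt a split, smoothing constant k=15.  Fitting is
fully deterministic; raw (unscaled) features are consumed directly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CubistConfig", "CubistModel", "fit_cubist"]

_SD_STOP_FRACTION = 0.05  # stop splitting once node SD < 5% of root SD
_PRUNE_NU = 1.0  # penalty weight per model parameter


@dataclasses.dataclass(frozen=True)
class CubistConfig:
    """Hyperparameters of the rule model tree."""

    min_split: int = 4  # minimum rows in a node to attempt a split
    min_leaf: int = 2  # minimum rows on each side of a split
    smoothing_k: float = 15.0  # M5 smoothing constant (0 disables)
    prune: bool = True

    @classmethod
    def from_params(cls, params: dict) -> "CubistConfig":
        return cls(**params)


@dataclasses.dataclass
class _LinearModel:
    """OLS model on a subset of features; empty feature list = node mean."""

    features: list[str]
    coef: list[float]
    intercept: float
    n_params: int

    def bind(self, feature_names: list[str]) -> None:
        """Cache a dense coefficient vector aligned to the model's columns."""
        w = np.zeros(len(feature_names))
        col = {f: j for j, f in enumerate(feature_names)}
        for f, c in zip(self.features, self.coef):
            w[col[f]] = c
        self._w = w

    def predict_rows(self, Xv: np.ndarray) -> np.ndarray:
        return Xv @ self._w + self.intercept

    def to_json(self) -> dict:
        return {
            "features": self.features,
            "coef": self.coef,
            "intercept": self.intercept,
            "n_params": self.n_params,
        }

    @classmethod
    def from_json(cls, d: dict) -> "_LinearModel":
        return cls(**d)


@dataclasses.dataclass
class _Node:
    n: int
    model: Optional[_LinearModel]
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_json(self) -> dict:
        d = {"n": self.n, "model": self.model.to_json()}
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                left=self.left.to_json(),
                right=self.right.to_json(),
            )
        return d

    @classmethod
    def from_json(cls, d: dict) -> "_Node":
        node = cls(n=int(d["n"]), model=_LinearModel.from_json(d["model"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = float(d["threshold"])
            node.left = cls.from_json(d["left"])
            node.right = cls.from_json(d["right"])
        return node


def _fit_linear(
    Xv: np.ndarray, y: np.ndarray, cols: list[int], names: list[str]
) -> tuple[Optional[_LinearModel], bool]:
    """OLS via lstsq; (None, deficient?) when too small or rank-deficient."""
    p = len(cols)
    n = len(y)
    if n < p + 2:
        return None, False
    A = np.column_stack([np.ones(n), Xv[:, cols]])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        return None, True
    model = _LinearModel(
        features=[names[c] for c in cols],
        coef=[float(c) for c in coef[1:]],
        intercept=float(coef[0]),
        n_params=p + 1,
    )
    return model, False


def _node_model(
    Xv: np.ndarray,
    y: np.ndarray,
    names: list[str],
    subtree_cols: list[int],
    try_all: bool = True,
) -> tuple[_LinearModel, int]:
    """Best feasible linear model for a node, plus a rank-deficiency count.

    Tries all features first (so a tree with no admissible split reduces
    exactly to the global OLS fit), then the features used by splits in
    the node's subtree, then the node mean.  Rank-deficient designs
    (e.g. exactly collinear index pairs) fall through to the next
    smaller model.  ``try_all=False`` skips the all-features attempt —
    used when the full design is already rank-deficient at the root,
    which implies it is rank-deficient in every row subset.
    """
    deficient = 0
    m = None
    if try_all:
        m, bad = _fit_linear(Xv, y, list(range(Xv.shape[1])), names)
        deficient += bad
    if m is None and subtree_cols:
        m, bad = _fit_linear(Xv, y, subtree_cols, names)
        deficient += bad
    if m is None:
        m = _LinearModel(features=[], coef=[], intercept=float(np.mean(y)), n_params=1)
    return m, deficient


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """(feature_idx, threshold) maximising SD reduction, or None.

    Ties broken by lower feature index, then lower threshold, so fitting
    is deterministic.
    """
    n = len(y)
    best = None
    best_gain = 0.0
    sd_full = y.std()
    lo, hi = min_leaf - 1, n - min_leaf  # candidate cut after position i in [lo, hi)
    if lo >= hi:
        return None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys**2)
        total, total2 = csum[-1], csum2[-1]
        i = np.arange(lo, hi)
        valid = xs[i] != xs[i + 1]
        if not valid.any():
            continue
        nl = (i + 1).astype(float)
        nr = n - nl
        var_l = np.maximum(csum2[i] / nl - (csum[i] / nl) ** 2, 0.0)
        var_r = np.maximum((total2 - csum2[i]) / nr - ((total - csum[i]) / nr) ** 2, 0.0)
        gain = sd_full - (nl * np.sqrt(var_l) + nr * np.sqrt(var_r)) / n
        gain[~valid] = -np.inf
        k = int(np.argmax(gain))  # first max -> lowest threshold on ties
        if gain[k] > best_gain + 1e-12:
            best_gain = float(gain[k])
            pos = lo + k
            best = (j, 0.5 * (xs[pos] + xs[pos + 1]))
    return best


class CubistModel:
    """A fitted rule model tree."""

    family = "cubist"

    def __init__(
        self,
        root: _Node,
        feature_names: list[str],
        config: CubistConfig,
        y_range: tuple[float, float] | None = None,
    ):
        self.root = root
        self.feature_names = list(feature_names)
        self.config = config
        self.y_range = y_range  # training-target clamp bounds for predictions
        self._col = {f: j for j, f in enumerate(self.feature_names)}
        self._bind(self.root)

    def _bind(self, node: _Node) -> None:
        node.model.bind(self.feature_names)
        if not node.is_leaf:
            self._bind(node.left)
            self._bind(node.right)

    # -- fitting ----------------------------------------------------------

    @classmethod
    def fit(cls, X: pd.DataFrame, y: np.ndarray, config: CubistConfig) -> "CubistModel":
        if len(X) < 5:
            raise ValueError("need at least 5 rows to fit a model tree")
        if X.isna().any().any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed in model fitting")
        feature_names = list(X.columns)
        y = np.asarray(y, dtype=float)
        root_sd = y.std()
        Xv = np.ascontiguousarray(X.to_numpy(dtype=float))

        def grow(idx: np.ndarray) -> _Node:
            yi = y[idx]
            node = _Node(n=len(idx), model=None)  # models fitted after pruning
            if (
                len(idx) >= config.min_split
                and yi.std() >= _SD_STOP_FRACTION * root_sd
            ):
                split = _best_split(Xv[idx], yi, config.min_leaf)
                if split is not None:
                    j, thr = split
                    mask = Xv[idx, j] <= thr
                    node.feature = feature_names[j]
                    node.threshold = float(thr)
                    node.left = grow(idx[mask])
                    node.right = grow(idx[~mask])
            return node

        root = grow(np.arange(len(y)))
        deficient = [0]
        col = {f: j for j, f in enumerate(feature_names)}
        # column collinearity is inherited by every row subset: check once
        p = Xv.shape[1]
        full_rank = (
            len(y) >= p + 2
            and np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xv])) == p + 1
        )
        root_deficient = len(y) >= p + 2 and not full_rank
        if root_deficient:
            deficient[0] += 1

        def finalise(node: _Node, idx: np.ndarray) -> float:
            """Fit node models bottom-up and prune; returns penalised error."""
            sub_cols = sorted({col[f] for f in cls._subtree_split_features(node)})
            node.model, bad = _node_model(
                Xv[idx], y[idx], feature_names, sub_cols, try_all=full_rank
            )
            deficient[0] += bad
            node.model.bind(feature_names)
            own_err = _penalised_error(
                y[idx], node.model.predict_rows(Xv[idx]), node.model.n_params
            )
            if node.is_leaf:
                return own_err
            mask = Xv[idx, col[node.feature]] <= node.threshold
            err_l = finalise(node.left, idx[mask])
            err_r = finalise(node.right, idx[~mask])
            sub_err = (node.left.n * err_l + node.right.n * err_r) / node.n
            if config.prune and own_err <= sub_err:
                node.feature = node.threshold = node.left = node.right = None
                return own_err
            return sub_err

        finalise(root, np.arange(len(y)))
        # cap extrapolation at the training-target range extended by 5%,
        # as rule-based model trees conventionally do
        span = float(y.max() - y.min())
        y_range = (float(y.min()) - 0.05 * span, float(y.max()) + 0.05 * span)
        if deficient[0]:
            warnings.warn(
                f"{deficient[0]} node regression(s) were rank-deficient; "
                "smaller models or node means were used instead",
                UserWarning,
                stacklevel=2,
            )
        return cls(root, feature_names, config, y_range)

    @staticmethod
    def _subtree_split_features(node: _Node) -> list[str]:
        if node.is_leaf:
            return []
        return (
            [node.feature]
            + CubistModel._subtree_split_features(node.left)
            + CubistModel._subtree_split_features(node.right)
        )

    # -- prediction -------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.feature_names].to_numpy(dtype=float)
        out = np.empty(len(Xv), dtype=float)
        self._predict_into(self.root, Xv, np.arange(len(Xv)), out)
        if self.y_range is not None:
            out = np.clip(out, self.y_range[0], self.y_range[1])
        return out

    def _predict_into(self, node: _Node, Xv: np.ndarray, idx: np.ndarray, out) -> None:
        if node.is_leaf:
            out[idx] = node.model.predict_rows(Xv[idx])
            return
        mask = Xv[idx, self._col[node.feature]] <= node.threshold
        for child, sel in ((node.left, mask), (node.right, ~mask)):
            sub = idx[sel]
            if len(sub):
                self._predict_into(child, Xv, sub, out)
                k = self.config.smoothing_k
                if k > 0:
                    parent_pred = node.model.predict_rows(Xv[sub])
                    out[sub] = (child.n * out[sub] + k * parent_pred) / (child.n + k)

    # -- structure accessors ----------------------------------------------

    def leaves(self) -> list[_Node]:
        acc: list[_Node] = []

        def walk(node):
            if node.is_leaf:
                acc.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return acc

    def rules(self) -> list[dict]:
        """Root-to-leaf paths as if/then rules."""
        rules = []

        def walk(node, conds):
            if node.is_leaf:
                rules.append(
                    {"conditions": list(conds), "model": node.model.to_json(), "n": node.n}
                )
                return
            walk(node.left, conds + [(node.feature, "<=", node.threshold)])
            walk(node.right, conds + [(node.feature, ">", node.threshold)])

        walk(self.root, [])
        return rules

    def attribute_usage(self) -> dict[str, float]:
        """Cubist-style usage: % of cases whose rule conditions test the
        feature, averaged with % of cases whose path models use it."""
        n_total = self.root.n
        cond = {f: 0.0 for f in self.feature_names}
        modl = {f: 0.0 for f in self.feature_names}

        def walk(node, path_conds: set, path_model_feats: set):
            path_model_feats = path_model_feats | set(node.model.features)
            if node.is_leaf:
                for f in path_conds:
                    cond[f] += node.n
                for f in path_model_feats:
                    modl[f] += node.n
                return
            walk(node.left, path_conds | {node.feature}, path_model_feats)
            walk(node.right, path_conds | {node.feature}, path_model_feats)

        walk(self.root, set(), set())
        return {
            f: 50.0 * cond[f] / n_total + 50.0 * modl[f] / n_total
            for f in self.feature_names
        }

    # -- serialization ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "feature_names": self.feature_names,
            "config": dataclasses.asdict(self.config),
            "y_range": list(self.y_range) if self.y_range is not None else None,
            "tree": self.root.to_json(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "CubistModel":
        y_range = d.get("y_range")
        return cls(
            root=_Node.from_json(d["tree"]),
            feature_names=list(d["feature_names"]),
            config=CubistConfig(**d["config"]),
            y_range=tuple(y_range) if y_range is not None else None,
        )


def _penalised_error(y: np.ndarray, pred: np.ndarray, n_params: int) -> float:
    """Mean absolute error inflated by the M5 (n+νp)/(n−νp) factor."""
    n = len(y)
    mae = float(np.mean(np.abs(y - pred)))
    nu_p = _PRUNE_NU * n_params
    if n <= nu_p:
        return np.inf
    return mae * (n + nu_p) / (n - nu_p)


def fit_cubist(X: pd.DataFrame, y, config: CubistConfig | None = None) -> CubistModel:
    """Fit a rule model tree; see :class:`CubistModel`."""
    return CubistModel.fit(X, np.asarray(y, dtype=float), config or CubistConfig())
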