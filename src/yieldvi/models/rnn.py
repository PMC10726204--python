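"""Recurrent-network regressor for tabular feature vectors.

The d selected features of a plot are presented as a length-d sequence
of scalars (canonical table order) to a single Elman recurrent hidden
layer; the hidden state after the last step is mapped linearly to the
yield prediction:

    h_t = tanh(w_x · x_t + W_h · h_{t−1} + b_h),   ŷ = w_o · h_d + b_o

Training minimises mean-squared error by full-batch backpropagation
through time with an Adam optimiser, a fixed epoch budget, and early
stopping on a seeded held-out split (best-checkpoint restore).  Inputs
and target are z-scored internally from the training data; predictions
are returned on the original scale.  Everything is seeded, so two fits
with the same spec and seed produce identical predictions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["RNNConfig", "RNNModel", "fit_rnn", "TrainingFailureError"]


class TrainingFailureError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclasses.dataclass(frozen=True)
class RNNConfig:
    hidden_size: int = 32
    epochs: int = 500
    learning_rate: float = 0.01
    early_stop_patience: int = 25
    val_fraction: float = 0.2
    init_scale: float = 0.2
    seed: int = 0

    @classmethod
    def from_params(cls, params: dict) -> "RNNConfig":
        return cls(**params)


class RNNModel:
    """A fitted Elman recurrent regressor."""

    family = "rnn"

    def __init__(self, weights, scaler, feature_names, config):
        self.weights = weights  # dict of ndarrays: wx, Wh, bh, wo, bo
        self.scaler = scaler  # dict: x_mean, x_sd, y_mean, y_sd
        self.feature_names = list(feature_names)
        self.config = config

    # -- forward pass -----------------------------------------------------

    @staticmethod
    def _forward(Xs: np.ndarray, w) -> tuple[np.ndarray, np.ndarray]:
        """Return (per-step hidden states (n, d+1, h), predictions (n,))."""
        n, d = Xs.shape
        h = len(w["bh"])
        H = np.zeros((n, d + 1, h))
        for t in range(d):
            H[:, t + 1] = np.tanh(
                Xs[:, t, None] * w["wx"] + H[:, t] @ w["Wh"].T + w["bh"]
            )
        pred = H[:, d] @ w["wo"] + w["bo"]
        return H, pred

    @classmethod
    def fit(cls, X: pd.DataFrame, y: np.ndarray, config: RNNConfig) -> "RNNModel":
        n, d = X.shape
        if n < 10:
            raise ValueError("need at least 10 rows to train the recurrent regressor")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(config.seed)

        x_mean = X.to_numpy(dtype=float).mean(axis=0)
        x_sd = X.to_numpy(dtype=float).std(axis=0)
        x_sd[x_sd == 0] = 1.0
        y_mean, y_sd = float(y.mean()), float(y.std())
        if y_sd == 0:
            y_sd = 1.0
        Xs = (X.to_numpy(dtype=float) - x_mean) / x_sd
        ys = (y - y_mean) / y_sd

        # seeded held-out split for early stopping
        perm = rng.permutation(n)
        n_val = max(1, int(round(config.val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("training split is empty")

        h = config.hidden_size
        s = config.init_scale
        w = {
            "wx": rng.normal(0, s, h),
            "Wh": rng.normal(0, s / np.sqrt(h), (h, h)),
            "bh": np.zeros(h),
            "wo": rng.normal(0, s / np.sqrt(h), h),
            "bo": 0.0,
        }
        m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in w.items()}
        v_ = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in w.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8

        Xtr, ytr = Xs[tr_idx], ys[tr_idx]
        Xva, yva = Xs[val_idx], ys[val_idx]
        best = {k: np.copy(v) for k, v in w.items()}
        best_val = np.inf
        stale = 0
        for epoch in range(1, config.epochs + 1):
            H, pred = cls._forward(Xtr, w)
            err = pred - ytr
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingFailureError(f"non-finite training loss at epoch {epoch}")
            g = cls._gradients(Xtr, H, err, w)
            for k in w:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v_[k] = b2 * v_[k] + (1 - b2) * g[k] ** 2
                mhat = m[k] / (1 - b1**epoch)
                vhat = v_[k] / (1 - b2**epoch)
                w[k] = w[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)

            _, vpred = cls._forward(Xva, w)
            val_loss = float(np.mean((vpred - yva) ** 2))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best = {k: np.copy(v) for k, v in w.items()}
                stale = 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    break

        scaler = {
            "x_mean": x_mean,
            "x_sd": x_sd,
            "y_mean": y_mean,
            "y_sd": y_sd,
        }
        return cls(best, scaler, list(X.columns), config)

    @staticmethod
    def _gradients(Xs, H, err, w) -> dict:
        """Backpropagation through time for the mean-squared-error loss."""
        n, d = Xs.shape
        dyhat = 2.0 * err / n  # (n,)
        g = {
            "wo": H[:, d].T @ dyhat,
            "bo": float(np.sum(dyhat)),
            "wx": np.zeros_like(w["wx"]),
            "Wh": np.zeros_like(w["Wh"]),
            "bh": np.zeros_like(w["bh"]),
        }
        dh = np.outer(dyhat, w["wo"])  # (n, h)
        for t in range(d - 1, -1, -1):
            a = H[:, t + 1]
            da = dh * (1.0 - a**2)
            g["wx"] += da.T @ Xs[:, t]
            g["Wh"] += da.T @ H[:, t]
            g["bh"] += da.sum(axis=0)
            dh = da @ w["Wh"]
        return g

    # -- prediction -------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = (X.to_numpy(dtype=float) - self.scaler["x_mean"]) / self.scaler["x_sd"]
        _, pred = self._forward(Xs, self.weights)
        return pred * self.scaler["y_sd"] + self.scaler["y_mean"]

    # -- serialization ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "feature_names": self.feature_names,
            "config": dataclasses.asdict(self.config),
            "weights": {k: np.asarray(v).tolist() for k, v in self.weights.items()},
            "scaler": {k: np.asarray(v).tolist() for k, v in self.scaler.items()},
        }

    @classmethod
    def from_json(cls, d: dict) -> "RNNModel":
        weights = {
            "wx": np.asarray(d["weights"]["wx"], dtype=float),
            "Wh": np.asarray(d["weights"]["Wh"], dtype=float),
            "bh": np.asarray(d["weights"]["bh"], dtype=float),
            "wo": np.asarray(d["weights"]["wo"], dtype=float),
            "bo": float(np.asarray(d["weights"]["bo"])),
        }
        scaler = {
            "x_mean": np.asarray(d["scaler"]["x_mean"], dtype=float),
            "x_sd": np.asarray(d["scaler"]["x_sd"], dtype=float),
            "y_mean": float(np.asarray(d["scaler"]["y_mean"])),
            "y_sd": float(np.asarray(d["scaler"]["y_sd"])),
        }
        return cls(weights, scaler, list(d["feature_names"]), RNNConfig(**d["config"]))


def fit_rnn(X: pd.DataFrame, y, config: RNNConfig | None = None) -> RNNModel:
    """Train the recurrent regressor; see :class:`RNNModel`."""
    return RNNModel.fit(X, np.asarray(y, dtype=float), config or RNNConfig())
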