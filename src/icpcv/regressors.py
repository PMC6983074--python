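"""Screen-coordinate regressors: MLP, RBFN and DNN.

One scalar-output network is trained per screen coordinate (x and y),
on feature vectors standardized per feature and targets normalized to
[0, 1] by the screen width / height:

* ``mlp`` — one hidden layer, sigmoid hidden and output activations,
  full-batch gradient descent, learning rate 0.4, 10,000 iterations.
* ``dnn`` — exactly five hidden layers, ReLU hidden / sigmoid output,
  Adam (lr 0.01, beta1 0.9, beta2 0.999, eps 1e-8), 100 iterations,
  MSE loss.
* ``rbfn`` — a single layer of Gaussian units with centers from k-means
  on the training features, a shared width equal to the mean distance
  between a center and its nearest neighbor, and linear output weights from
  ridge-regularized least squares; predictions clamped to [0, 1].

All training is deterministic for a fixed seed.  Models serialize to
JSON (architecture, normalization record and weights as nested lists).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

DEFAULTS = {
    "mlp": dict(hidden_sizes=(10,), learning_rate=0.4, iterations=10_000),
    "dnn": dict(hidden_sizes=(5, 10, 10, 10, 5), learning_rate=0.01, iterations=100),
    "rbfn": dict(hidden_sizes=(10,), learning_rate=0.0, iterations=0),
}

ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 0.9, 0.999, 1e-8
RBFN_RIDGE = 1e-6


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class RegressorConfig:
    family: str = "dnn"
    hidden_sizes: tuple = None
    learning_rate: float = None
    iterations: int = None
    seed: int = 0
    screen_size: tuple[float, float] = (1920.0, 1080.0)

    def __post_init__(self):
        if self.family not in DEFAULTS:
            raise ValueError(f"unknown family {self.family!r}")
        d = DEFAULTS[self.family]
        if self.hidden_sizes is None:
            self.hidden_sizes = d["hidden_sizes"]
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.learning_rate is None:
            self.learning_rate = d["learning_rate"]
        if self.iterations is None:
            self.iterations = d["iterations"]
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.family == "dnn" and len(self.hidden_sizes) != 5:
            raise ValueError("dnn requires exactly 5 hidden layers")
        if self.family in ("mlp", "rbfn") and len(self.hidden_sizes) != 1:
            raise ValueError(f"{self.family} takes a single hidden layer")
        if self.family != "rbfn" and self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class GazeRegressor:
    """A trained scalar-output gaze mapping for one screen coordinate."""

    family: str
    weights: dict  # layer matrices / rbf parameters, as arrays
    x_mean: np.ndarray
    x_std: np.ndarray
    feature_variant: str | None = None
    coordinate: str | None = None  # "x" or "y"
    screen_scale: float = 1.0  # denormalization factor (screen w or h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "weights": {k: np.asarray(v).tolist() for k, v in self.weights.items()},
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "feature_variant": self.feature_variant,
            "coordinate": self.coordinate,
            "screen_scale": self.screen_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GazeRegressor":
        return cls(
            family=d["family"],
            weights={k: np.asarray(v, dtype=float) for k, v in d["weights"].items()},
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_std=np.asarray(d["x_std"], dtype=float),
            feature_variant=d.get("feature_variant"),
            coordinate=d.get("coordinate"),
            screen_scale=float(d.get("screen_scale", 1.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GazeRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ErrorReport:
    """Per-coordinate mean absolute errors and mean Euclidean error
    distance, in screen pixels."""

    avg_error_x: float
    avg_error_y: float
    mean_error_distance: float

    def to_dict(self) -> dict:
        return {
            "avg_error_x": self.avg_error_x,
            "avg_error_y": self.avg_error_y,
            "mean_error_distance": self.mean_error_distance,
        }


# ---------------------------------------------------------------------------
# internals


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _coerce_xy(samples):
    """Accept a list of (features, scalar target) pairs or an (X, y) tuple."""
    if isinstance(samples, tuple) and len(samples) == 2:
        X, y = samples
    else:
        X = [f for f, _ in samples]
        y = [t for _, t in samples]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError(f"inconsistent sample shapes {X.shape} vs {y.shape}")
    return X, y


def _init_layers(sizes, rng):
    """Glorot-uniform weight matrices and zero biases, seeded."""
    Ws, bs = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        Ws.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


def _forward(Ws, bs, X, hidden_activation):
    """Return per-layer activations; output layer is always sigmoid."""
    acts = [X]
    a = X
    n = len(Ws)
    for i, (W, b) in enumerate(zip(Ws, bs)):
        z = a @ W + b
        if i == n - 1:
            a = _sigmoid(z)
        elif hidden_activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            a = _sigmoid(z)
        acts.append(a)
    return acts


def _backward(Ws, acts, Y, hidden_activation):
    """Gradients of the MSE loss wrt weights and biases; Y is (m, k)."""
    n = len(Ws)
    m, k = Y.shape
    # d(MSE)/d(out) * d(sigmoid)
    delta = (2.0 / (m * k)) * (acts[-1] - Y) * (acts[-1] * (1.0 - acts[-1]))
    gWs, gbs = [None] * n, [None] * n
    for i in range(n - 1, -1, -1):
        gWs[i] = acts[i].T @ delta
        gbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ Ws[i].T
            a = acts[i]
            if hidden_activation == "relu":
                delta = delta * (a > 0.0)
            else:
                delta = delta * a * (1.0 - a)
    return gWs, gbs


def _train_net(cfg: RegressorConfig, X, Y):
    rng = np.random.default_rng(cfg.seed)
    sizes = [X.shape[1], *cfg.hidden_sizes, Y.shape[1]]
    Ws, bs = _init_layers(sizes, rng)
    act = "relu" if cfg.family == "dnn" else "sigmoid"
    if cfg.family == "dnn":  # Adam state
        mW = [np.zeros_like(W) for W in Ws]
        vW = [np.zeros_like(W) for W in Ws]
        mb = [np.zeros_like(b) for b in bs]
        vb = [np.zeros_like(b) for b in bs]
    for it in range(1, cfg.iterations + 1):
        acts = _forward(Ws, bs, X, act)
        loss = np.mean((acts[-1] - Y) ** 2)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at iteration {it}")
        gWs, gbs = _backward(Ws, acts, Y, act)
        if cfg.family == "dnn":
            b1c = 1.0 - ADAM_BETA1**it
            b2c = 1.0 - ADAM_BETA2**it
            for i in range(len(Ws)):
                for g, W, mo, vo in ((gWs[i], Ws, mW, vW), (gbs[i], bs, mb, vb)):
                    mo[i] = ADAM_BETA1 * mo[i] + (1 - ADAM_BETA1) * g
                    vo[i] = ADAM_BETA2 * vo[i] + (1 - ADAM_BETA2) * g * g
                    W[i] = W[i] - cfg.learning_rate * (mo[i] / b1c) / (
                        np.sqrt(vo[i] / b2c) + ADAM_EPS
                    )
        else:  # full-batch gradient descent
            for i in range(len(Ws)):
                Ws[i] -= cfg.learning_rate * gWs[i]
                bs[i] -= cfg.learning_rate * gbs[i]
    weights = {}
    for i, (W, b) in enumerate(zip(Ws, bs)):
        weights[f"W{i}"] = W
        weights[f"b{i}"] = b
    weights["n_layers"] = np.array([len(Ws)])
    return weights


def _train_rbfn(cfg: RegressorConfig, X, y):
    k = min(cfg.hidden_sizes[0], X.shape[0])
    km = KMeans(n_clusters=k, random_state=cfg.seed, n_init=10)
    with warnings.catch_warnings():
        # sessions revisit identical targets, so duplicated feature rows can
        # leave fewer distinct points than requested centers
        warnings.simplefilter("ignore")
        km.fit(X)
    centers = km.cluster_centers_
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    if k > 1:  # mean nearest-center spacing; robust to duplicated inputs
        dc = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(dc, np.inf)
        sigma = float(dc.min(axis=1).mean())
    else:
        sigma = float(d.mean())
    if sigma <= 0:
        sigma = 1.0
    Phi = np.exp(-(d**2) / (2.0 * sigma**2))
    Phi = np.hstack([Phi, np.ones((Phi.shape[0], 1))])  # bias unit
    A = Phi.T @ Phi + RBFN_RIDGE * np.eye(Phi.shape[1])
    w = np.linalg.solve(A, Phi.T @ y)
    return {"centers": centers, "sigma": np.array([sigma]), "w": w}


# ---------------------------------------------------------------------------
# public API


def train(cfg: RegressorConfig, samples, feature_variant=None, coordinate=None,
          screen_scale: float = 1.0) -> GazeRegressor:
    """Train one regressor on (feature vector, normalized-target) samples.

    Targets must already be in [0, 1] (screen coordinate divided by the
    screen width or height); features are standardized internally and
    the standardization is stored with the model.
    """
    X, y = _coerce_xy(samples)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)  # constant features pass through as 0
    Xs = (X - x_mean) / x_std
    if cfg.family == "rbfn":
        weights = _train_rbfn(cfg, Xs, y)
    else:
        weights = _train_net(cfg, Xs, y.reshape(-1, 1))
    return GazeRegressor(
        family=cfg.family,
        weights=weights,
        x_mean=x_mean,
        x_std=x_std,
        feature_variant=feature_variant,
        coordinate=coordinate,
        screen_scale=screen_scale,
    )


def predict(model: GazeRegressor, features) -> np.ndarray:
    """Normalized predictions in [0, 1] for one feature vector or a batch."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature mismatch: model expects {model.x_mean.shape[0]} features, "
            f"got {X.shape[1]}"
        )
    Xs = (X - model.x_mean) / model.x_std
    if model.family == "rbfn":
        centers = model.weights["centers"]
        sigma = float(model.weights["sigma"][0])
        d = np.linalg.norm(Xs[:, None, :] - centers[None, :, :], axis=2)
        Phi = np.exp(-(d**2) / (2.0 * sigma**2))
        Phi = np.hstack([Phi, np.ones((Phi.shape[0], 1))])
        out = Phi @ model.weights["w"]
        return np.clip(out, 0.0, 1.0)
    n = int(model.weights["n_layers"][0])
    Ws = [model.weights[f"W{i}"] for i in range(n)]
    bs = [model.weights[f"b{i}"] for i in range(n)]
    act = "relu" if model.family == "dnn" else "sigmoid"
    out = _forward(Ws, bs, Xs, act)[-1]
    return out[:, 0] if out.shape[1] == 1 else out


def predict_point(model_x: GazeRegressor, model_y: GazeRegressor, features) -> np.ndarray:
    """Denormalized screen point(s) (px) from the per-coordinate pair."""
    if (
        model_x.feature_variant is not None
        and model_y.feature_variant is not None
        and model_x.feature_variant != model_y.feature_variant
    ):
        raise ValueError(
            f"feature variant mismatch: {model_x.feature_variant} vs "
            f"{model_y.feature_variant}"
        )
    px = predict(model_x, features) * model_x.screen_scale
    py = predict(model_y, features) * model_y.screen_scale
    pts = np.stack([px, py], axis=-1)
    return pts[0] if pts.shape[0] == 1 and np.asarray(features).ndim == 1 else pts


def train_pair(cfg: RegressorConfig, features_df, feature_variant=None):
    """Train the (x, y) regressor pair from a featurized session table
    (feature columns + target_x, target_y)."""
    names = [c for c in features_df.columns if c not in ("target_x", "target_y")]
    X = features_df[names].to_numpy(dtype=float)
    w, h = cfg.screen_size
    variant = feature_variant or features_df.attrs.get("variant")
    mx = train(
        cfg, (X, features_df["target_x"].to_numpy() / w),
        feature_variant=variant, coordinate="x", screen_scale=w,
    )
    my = train(
        cfg, (X, features_df["target_y"].to_numpy() / h),
        feature_variant=variant, coordinate="y", screen_scale=h,
    )
    return mx, my


def error_report(predictions, targets) -> ErrorReport:
    """Per-coordinate mean absolute error and mean Euclidean error
    distance (px) between (n, 2) prediction and target arrays."""
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if P.shape != T.shape or P.shape[0] == 0:
        raise ValueError(f"empty or mismatched arrays: {P.shape} vs {T.shape}")
    err = P - T
    return ErrorReport(
        avg_error_x=float(np.abs(err[:, 0]).mean()),
        avg_error_y=float(np.abs(err[:, 1]).mean()),
        mean_error_distance=float(np.linalg.norm(err, axis=1).mean()),
    )


def train_joint(cfg: RegressorConfig, features_df, feature_variant=None) -> GazeRegressor:
    """Train a single two-output network predicting (x, y) jointly
    (non-default alternative to the per-coordinate pair)."""
    names = [c for c in features_df.columns if c not in ("target_x", "target_y")]
    X = features_df[names].to_numpy(dtype=float)
    wh = np.asarray(cfg.screen_size, dtype=float)
    Y = features_df[["target_x", "target_y"]].to_numpy(dtype=float) / wh
    x_mean = X.mean(axis=0)
    x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - x_mean) / x_std
    if cfg.family == "rbfn":
        weights = _train_rbfn(cfg, Xs, Y)
    else:
        weights = _train_net(cfg, Xs, Y)
    weights["screen_wh"] = wh
    return GazeRegressor(
        family=cfg.family,
        weights=weights,
        x_mean=x_mean,
        x_std=x_std,
        feature_variant=feature_variant or features_df.attrs.get("variant"),
        coordinate="xy",
        screen_scale=1.0,
    )


def predict_point_joint(model: GazeRegressor, features) -> np.ndarray:
    """Denormalized screen point(s) from a jointly trained model."""
    if model.coordinate != "xy":
        raise ValueError("model was not trained jointly")
    out = np.atleast_2d(predict(model, features)) * model.weights["screen_wh"]
    return out[0] if np.asarray(features).ndim == 1 else out


def evaluate(model_x: GazeRegressor, model_y: GazeRegressor, samples) -> ErrorReport:
    """Evaluate a model pair: per-coordinate mean absolute error (px) and
    mean Euclidean error distance (px).

    ``samples`` is a featurized session DataFrame (feature columns plus
    target_x / target_y) or a list of (feature vector, target point)."""
    if hasattr(samples, "columns"):
        names = [c for c in samples.columns if c not in ("target_x", "target_y")]
        X = samples[names].to_numpy(dtype=float)
        T = samples[["target_x", "target_y"]].to_numpy(dtype=float)
    else:
        X = np.asarray([np.asarray(f, dtype=float) for f, _ in samples])
        T = np.asarray([np.asarray(t, dtype=float) for _, t in samples])
    if X.shape[0] == 0:
        raise ValueError("empty sample list")
    P = np.atleast_2d(predict_point(model_x, model_y, X))
    return error_report(P, T)
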