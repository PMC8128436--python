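"""Regressors mapping encoded stem-loop tensors to basal gene-regulatory activity.

The headline model is a small 3-D convolutional network: a 2x2x2 convolution
with stride 1 scans every group of eight adjacent nucleotide cells (two rows x
two strand sides x both stem-loops), followed by 25% dropout, flatten, a dense
rectilinear layer, 50% dropout, and a final dense unit producing one value
(predicted log10(GFP/mCherry)).  It is trained with Adam on mean squared
error.  The network is implemented directly in numpy (im2col convolution,
manual backpropagation, inverted dropout) so training is exactly reproducible
from a single integer seed on any machine.

Baselines — lasso (with internally cross-validated penalty), an RBF support
vector machine and a random forest — operate on the flattened tensor through
scikit-learn.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig
from .errors import LabelError, MetadataError, ShapeError

BASELINE_KINDS = ("lasso", "svm", "random_forest")


@dataclass(frozen=True)
class RegressorConfig:
    conv_kernel: tuple[int, int, int] = (2, 2, 2)
    conv_stride: int = 1
    n_filters: int = 32
    dropout_after_conv: float = 0.25
    dense_units: int = 128
    dense_activation: str = "relu"
    dropout_after_dense: float = 0.50
    epochs: int = 100
    learning_rate: float = 1e-3
    loss: str = "mse"
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout_after_conv < 1 and 0 <= self.dropout_after_dense < 1):
            raise ValueError("dropout fractions must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedRegressor:
    kind: str                       # "cnn" | "lasso" | "svm" | "random_forest"
    params: dict | object           # numpy weight dict (cnn) or sklearn estimator
    metadata: dict = field(default_factory=dict)

    @property
    def loss_trace(self) -> list[float]:
        return self.metadata.get("loss_trace", [])


# ---------------------------------------------------------------------------
# CNN internals
# ---------------------------------------------------------------------------

def _check_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32).reshape(-1)
    if X.ndim != 5 or X.shape[2:] != (2, 2, 8):
        raise ShapeError(f"expected (N, L, 2, 2, 8) tensor batch, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"{X.shape[0]} tensors vs {y.shape[0]} labels")
    if not np.all(np.isfinite(y)):
        raise LabelError("non-finite training label")
    return X, y


def _im2col(X: np.ndarray) -> np.ndarray:
    """(N, L, 2, 2, 8) -> (N, L-1, 64): each row-window of 2x2x2x8 cells flattened.

    The 2x2x2 valid convolution collapses the side and stem-loop axes (both of
    extent 2), so the only scanned axis is the row axis.
    """
    N, L = X.shape[:2]
    windows = np.concatenate([X[:, :-1], X[:, 1:]], axis=-1)  # (N, L-1, 2, 2, 16)
    return windows.reshape(N, L - 1, 64)


def _col2im(dXc: np.ndarray, L: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    N = dXc.shape[0]
    w = dXc.reshape(N, L - 1, 2, 2, 16)
    dX = np.zeros((N, L, 2, 2, 8), dtype=dXc.dtype)
    dX[:, :-1] += w[..., :8]
    dX[:, 1:] += w[..., 8:]
    return dX


def _init_params(l_rows: int, cfg: RegressorConfig, rng: np.random.Generator) -> dict:
    f, h = cfg.n_filters, cfg.dense_units
    flat = (l_rows - 1) * f
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
    return {
        "W1": he((64, f), 64), "b1": np.zeros(f, dtype=np.float32),
        "W2": he((flat, h), flat), "b2": np.zeros(h, dtype=np.float32),
        "W3": he((h, 1), h), "b3": np.zeros(1, dtype=np.float32),
    }


def _forward(params: dict, Xc: np.ndarray, *, rng=None, p_conv=0.0, p_dense=0.0):
    """Forward pass on im2col'd input; dropout only when an rng is given."""
    Z1 = Xc @ params["W1"] + params["b1"]          # (N, L-1, F)
    A1 = np.maximum(Z1, 0.0)
    M1 = None
    if rng is not None and p_conv > 0:
        M1 = (rng.random(A1.shape) >= p_conv).astype(np.float32) / (1.0 - p_conv)
        A1 = A1 * M1
    F1 = A1.reshape(A1.shape[0], -1)               # flatten
    Z2 = F1 @ params["W2"] + params["b2"]
    A2 = np.maximum(Z2, 0.0)
    M2 = None
    if rng is not None and p_dense > 0:
        M2 = (rng.random(A2.shape) >= p_dense).astype(np.float32) / (1.0 - p_dense)
        A2 = A2 * M2
    out = (A2 @ params["W3"] + params["b3"]).reshape(-1)
    cache = (Xc, Z1, A1, M1, F1, Z2, A2, M2)
    return out, cache


def _backward(params: dict, cache, dout: np.ndarray) -> dict:
    Xc, Z1, A1, M1, F1, Z2, A2, M2 = cache
    g = {}
    dA2 = dout[:, None] @ params["W3"].T.astype(np.float32)    # (N, H)
    g["W3"] = A2.T @ dout[:, None]
    g["b3"] = np.array([dout.sum()], dtype=np.float32)
    if M2 is not None:
        dA2 = dA2 * M2
    dZ2 = dA2 * (Z2 > 0)
    g["W2"] = F1.T @ dZ2
    g["b2"] = dZ2.sum(axis=0)
    dF1 = dZ2 @ params["W2"].T
    dA1 = dF1.reshape(A1.shape)
    if M1 is not None:
        dA1 = dA1 * M1
    dZ1 = dA1 * (Z1 > 0)
    g["W1"] = np.tensordot(Xc, dZ1, axes=([0, 1], [0, 1]))
    g["b1"] = dZ1.sum(axis=(0, 1))
    return g


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k in params:
            gk = grads[k].astype(np.float32).reshape(params[k].shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def train_cnn(X: np.ndarray, y, config: RegressorConfig = RegressorConfig(),
              encoder_config: EncoderConfig | None = None,
              structure_keys: list | None = None) -> TrainedRegressor:
    """Fit the convolutional regressor; fully reproducible from ``config.seed``."""
    X, y = _check_xy(X, np.asarray(y))
    if X.shape[0] < 2:
        raise ShapeError("need at least 2 training records")
    if config.conv_kernel != (2, 2, 2) or config.conv_stride != 1:
        raise ShapeError("only the 2x2x2 stride-1 convolution is implemented")
    rng = np.random.default_rng(config.seed)
    L = X.shape[1]
    params = _init_params(L, config, rng)
    opt = _Adam(params, config.learning_rate)
    Xc = _im2col(X)
    n = X.shape[0]
    trace = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, yb = Xc[idx], y[idx]
            out, cache = _forward(params, xb, rng=rng,
                                  p_conv=config.dropout_after_conv,
                                  p_dense=config.dropout_after_dense)
            err = out - yb
            losses.append(float(np.mean(err ** 2)))
            weights.append(len(idx))
            dout = (2.0 / len(idx)) * err.astype(np.float32)
            grads = _backward(params, cache, dout)
            opt.step(params, grads)
        trace.append(float(np.average(losses, weights=weights)))
    meta = {
        "config": {**asdict(config), "conv_kernel": list(config.conv_kernel)},
        "seed": config.seed,
        "l_rows": L,
        "loss_trace": trace,
        "encoder": (encoder_config or EncoderConfig(l_max=L)).as_dict(),
        "structure_keys": sorted({"|".join(map(str, k)) for k in structure_keys})
        if structure_keys else [],
    }
    return TrainedRegressor("cnn", params, meta)


def _check_encoder(model: TrainedRegressor, encoder_config: EncoderConfig | None):
    if encoder_config is None:
        return
    want = model.metadata.get("encoder")
    if want and want != encoder_config.as_dict():
        raise MetadataError(
            f"encoder settings {encoder_config.as_dict()} do not match the "
            f"model's training settings {want}")


def predict(model: TrainedRegressor, X: np.ndarray,
            encoder_config: EncoderConfig | None = None) -> np.ndarray:
    """Deterministic inference (dropout disabled)."""
    _check_encoder(model, encoder_config)
    X = np.asarray(X, dtype=np.float32)
    if model.kind == "cnn":
        if X.ndim != 5:
            raise ShapeError(f"expected 5-D tensor batch, got {X.shape}")
        if X.shape[1] != model.metadata.get("l_rows", X.shape[1]):
            raise MetadataError("tensor row count differs from training")
        out, _ = _forward(model.params, _im2col(X))
        return out.astype(np.float64)
    flat = X.reshape(X.shape[0], -1)
    return np.asarray(model.params.predict(flat), dtype=np.float64)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def train_baseline(kind: str, X, y, seed: int = 0,
                   encoder_config: EncoderConfig | None = None) -> TrainedRegressor:
    """Lasso / SVM / random-forest regressor on the flattened encoding."""
    if kind not in BASELINE_KINDS:
        raise ValueError(f"kind must be one of {BASELINE_KINDS}")
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    if not np.all(np.isfinite(y)):
        raise LabelError("non-finite training label")
    flat = X.reshape(X.shape[0], -1)
    if kind == "lasso":
        from sklearn.linear_model import LassoCV
        est = LassoCV(cv=5, random_state=seed, alphas=40, max_iter=5000)
    elif kind == "svm":
        from sklearn.svm import SVR
        est = SVR(kernel="rbf")
    else:
        from sklearn.ensemble import RandomForestRegressor
        est = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    est.fit(flat, y)
    meta = {"seed": seed,
            "encoder": encoder_config.as_dict() if encoder_config else None}
    return TrainedRegressor(kind, est, meta)


# ---------------------------------------------------------------------------
# Artifact round trip
# ---------------------------------------------------------------------------

def save_model(model: TrainedRegressor, path) -> None:
    """Write weights + JSON metadata sidecar; load gives bit-identical output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if model.kind == "cnn":
        np.savez(path.with_suffix(".npz"), **model.params)
    else:
        with open(path.with_suffix(".pkl"), "wb") as fh:
            pickle.dump(model.params, fh)
    meta = {"kind": model.kind, **model.metadata}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> TrainedRegressor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    kind = meta.pop("kind")
    if kind == "cnn":
        with np.load(path.with_suffix(".npz")) as z:
            params = {k: z[k] for k in z.files}
    else:
        with open(path.with_suffix(".pkl"), "rb") as fh:
            params = pickle.load(fh)
    return TrainedRegressor(kind, params, meta)


def training_log_tsv(model: TrainedRegressor, path) -> None:
    import pandas as pd
    pd.DataFrame({"epoch": np.arange(1, len(model.loss_trace) + 1),
                  "train_loss": model.loss_trace}).to_csv(path, sep="\t", index=False)
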