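"""MLP latency regressor: architecture, training recipe, portable weights.

The network maps the 120-sample preprocessed epoch to a single latency in
ms post-stimulus.  Architecture: 120 → 30 → 30 → 1, ReLU hidden
activations, linear output (4591 trainable parameters).  Training: Adam on
mean-squared error, mini-batches of 32, a cap of 200 epochs with
patience-based early stopping on a 10 % validation split; the weights with
the best validation loss are returned.  All randomness (initialization,
validation split, batch shuffling) flows from a single integer seed, so a
fixed seed on the same platform reproduces the trained weights bit for bit.

Weights are serialized to a documented JSON container (spec + nested
arrays), portable across platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from delmep.mep_io import AnnotatedDataset
from delmep.preprocess import PreprocessedVector, preprocess

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "build_model",
    "train",
    "predict_latency",
    "predict_batch",
    "forward",
    "save_model",
    "load_model",
    "fit_on_dataset",
    "annotate_dataset",
]

INPUT_DIM = 120


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the latency regressor.

    ``max_epochs`` caps training; ``early_stop_patience`` stops it sooner
    once the validation loss has not improved for that many epochs.
    ``validation_fraction = 0`` disables early stopping (the full
    ``max_epochs`` are run on all data) — useful for memorization checks.
    """

    input_dim: int = INPUT_DIM
    hidden: Tuple[int, ...] = (30, 30)
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    validation_fraction: float = 0.1
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if not self.hidden or any(h <= 0 for h in self.hidden):
            raise ValueError(f"hidden sizes must be positive, got {self.hidden}")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

    @property
    def layer_sizes(self) -> Tuple[int, ...]:
        return (self.input_dim, *self.hidden, 1)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass
class TrainedModel:
    """Network weights plus the spec and training metadata.

    ``weights[l]`` has shape (fan_in, fan_out); ``biases[l]`` has shape
    (fan_out,).  ``training_meta`` is None for a freshly initialized
    (untrained) model.
    """

    spec: ModelSpec
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    training_meta: Optional[Dict] = None

    def __post_init__(self) -> None:
        sizes = self.spec.layer_sizes
        expected = list(zip(sizes[:-1], sizes[1:]))
        got = [w.shape for w in self.weights]
        if got != expected:
            raise ValueError(f"weight shapes {got} do not match spec {expected}")
        for b, (_, fan_out) in zip(self.biases, expected):
            if b.shape != (fan_out,):
                raise ValueError(f"bias shape {b.shape} != ({fan_out},)")
        for arr in (*self.weights, *self.biases):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")

    @property
    def is_trained(self) -> bool:
        return self.training_meta is not None

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters


def build_model(spec: ModelSpec = ModelSpec()) -> TrainedModel:
    """Deterministically initialize an untrained network (Glorot uniform)."""
    rng = np.random.default_rng(spec.seed)
    weights, biases = [], []
    sizes = spec.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedModel(spec=spec, weights=weights, biases=biases)


def forward(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Raw forward pass: (n, input_dim) -> (n,) latencies in ms."""
    A = np.atleast_2d(np.asarray(X, dtype=float))
    if A.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input has {A.shape[1]} features, model expects {model.spec.input_dim}"
        )
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        A = A @ W + b
        if i < n_layers - 1:
            np.maximum(A, 0.0, out=A)
    return A[:, 0]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.atleast_2d(np.asarray(X, dtype=float))
    rows = [v.values if isinstance(v, PreprocessedVector) else np.asarray(v, float)
            for v in X]
    return np.vstack(rows)


def train(
    model: TrainedModel,
    X,
    y: Sequence[float],
    spec: Optional[ModelSpec] = None,
) -> TrainedModel:
    """Train with Adam on MSE; return the best-validation-loss weights.

    ``X`` is a (n, input_dim) array or a sequence of
    :class:`PreprocessedVector`; ``y`` the target latencies in ms.
    The input model is not modified.
    """
    spec = spec or model.spec
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != yv.size:
        raise ValueError(f"|X| = {Xm.shape[0]} but |y| = {yv.size}")
    if not np.all(np.isfinite(yv)):
        raise ValueError("target latencies must be finite")
    if not np.all(np.isfinite(Xm)):
        raise ValueError("inputs must be finite")
    n = Xm.shape[0]
    if n < spec.batch_size:
        raise ValueError(f"need at least batch_size={spec.batch_size} samples, got {n}")

    rng = np.random.default_rng(spec.seed)
    n_val = int(round(spec.validation_fraction * n))
    if spec.validation_fraction > 0 and (n_val < 1 or n - n_val < 1):
        raise ValueError(
            f"validation_fraction={spec.validation_fraction} leaves an empty "
            f"split for n={n}"
        )
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = Xm[tr_idx], yv[tr_idx]
    Xval, yval = Xm[val_idx], yv[val_idx]

    W = [w.copy() for w in model.weights]
    B = [b.copy() for b in model.biases]
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mB = [np.zeros_like(b) for b in B]
    vB = [np.zeros_like(b) for b in B]
    t_step = 0
    lr, b1, b2, eps = spec.learning_rate, spec.beta1, spec.beta2, spec.adam_eps
    n_layers = len(W)

    def val_loss() -> float:
        if n_val == 0:
            return float("nan")
        A = Xval
        for i in range(n_layers):
            A = A @ W[i] + B[i]
            if i < n_layers - 1:
                A = np.maximum(A, 0.0)
        return float(np.mean((A[:, 0] - yval) ** 2))

    best = (np.inf, [w.copy() for w in W], [b.copy() for b in B])
    stall = 0
    epochs_run = 0
    last_train_loss = np.nan
    n_tr = Xtr.shape[0]
    for epoch in range(spec.max_epochs):
        epochs_run = epoch + 1
        order = rng.permutation(n_tr)
        sse = 0.0
        for start in range(0, n_tr, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            # forward, caching pre-activations
            acts = [xb]
            A = xb
            for i in range(n_layers):
                Z = A @ W[i] + B[i]
                A = np.maximum(Z, 0.0) if i < n_layers - 1 else Z
                acts.append(A)
            resid = acts[-1][:, 0] - yb
            sse += float(resid @ resid)
            # backprop of mean-squared error
            delta = (2.0 / idx.size) * resid[:, None]
            t_step += 1
            corr1 = 1.0 - b1 ** t_step
            corr2 = 1.0 - b2 ** t_step
            for i in range(n_layers - 1, -1, -1):
                gW = acts[i].T @ delta
                gB = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ W[i].T) * (acts[i] > 0.0)
                mW[i] = b1 * mW[i] + (1 - b1) * gW
                vW[i] = b2 * vW[i] + (1 - b2) * gW ** 2
                mB[i] = b1 * mB[i] + (1 - b1) * gB
                vB[i] = b2 * vB[i] + (1 - b2) * gB ** 2
                W[i] -= lr * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
                B[i] -= lr * (mB[i] / corr1) / (np.sqrt(vB[i] / corr2) + eps)
        last_train_loss = sse / n_tr
        if n_val > 0:
            vl = val_loss()
            if vl < best[0] - 1e-12:
                best = (vl, [w.copy() for w in W], [b.copy() for b in B])
                stall = 0
            else:
                stall += 1
                if stall >= spec.early_stop_patience:
                    break

    if n_val > 0 and np.isfinite(best[0]):
        best_val, W, B = best
    else:
        best_val = float("nan")

    fingerprint = hashlib.sha256(Xm.tobytes() + yv.tobytes()).hexdigest()[:12]
    meta = {
        "epochs_run": epochs_run,
        "final_train_loss": last_train_loss,
        "best_val_loss": best_val,
        "n_train": int(n - n_val),
        "n_val": int(n_val),
        "seed": spec.seed,
        "dataset_fingerprint": fingerprint,
    }
    return TrainedModel(spec=spec, weights=W, biases=B, training_meta=meta)


def predict_batch(model: TrainedModel, X) -> np.ndarray:
    """Latencies (ms) for a batch of preprocessed vectors."""
    if not model.is_trained:
        raise ValueError("model is untrained; call train() first")
    return forward(model, _as_matrix(X))


def predict_latency(model: TrainedModel, v) -> float:
    """Latency in ms post-stimulus for one preprocessed vector (no clipping)."""
    x = v.values if isinstance(v, PreprocessedVector) else np.asarray(v, float)
    if x.ndim != 1:
        raise ValueError("predict_latency takes a single vector; use predict_batch")
    return float(predict_batch(model, x[None, :])[0])


def save_model(model: TrainedModel, path) -> None:
    """Write the model as a portable JSON container."""
    payload = {
        "format": "delmep-mlp",
        "format_version": 1,
        "spec": asdict(model.spec),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "training_meta": model.training_meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    """Read a JSON model container; validates layout and weight shapes."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupted model container {path}: {e}") from e
    for key in ("format", "spec", "weights", "biases"):
        if key not in payload:
            raise ValueError(f"model container missing field {key!r}")
    if payload["format"] != "delmep-mlp":
        raise ValueError(f"unknown container format {payload['format']!r}")
    spec_d = dict(payload["spec"])
    spec_d["hidden"] = tuple(spec_d["hidden"])
    spec = ModelSpec(**spec_d)
    weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
    biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
    return TrainedModel(
        spec=spec, weights=weights, biases=biases,
        training_meta=payload.get("training_meta"),
    )


def fit_on_dataset(ds: AnnotatedDataset, spec: ModelSpec = ModelSpec()) -> TrainedModel:
    """Preprocess every annotated trace of ``ds`` and train a fresh model."""
    ids = sorted(ds.annotations)
    X = np.vstack([preprocess(ds.traces[i]).values for i in ids])
    y = np.array([ds.annotations[i].latency_ms for i in ids])
    return train(build_model(spec), X, y, spec)


def annotate_dataset(model: TrainedModel, ds: AnnotatedDataset) -> Dict[str, float]:
    """Predicted latency (ms) for every trace in ``ds``, keyed by trace_id."""
    ids = sorted(ds.traces)
    X = np.vstack([preprocess(ds.traces[i]).values for i in ids])
    pred = predict_batch(model, X)
    return dict(zip(ids, pred.tolist()))
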