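"""Extreme learning machine: random hidden layer, analytic output weights.

A single-hidden-layer feed-forward classifier. The input-side parameters
(weights and biases for sigmoid nodes; centers and widths for RBF nodes)
are drawn at random and never trained. The output weights are the
least-squares solution ``W = Y_encoded @ pinv(Y_h)`` where ``Y_h`` is the
hidden-layer response on the training data. Prediction takes the argmax
over class outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .dataset import ValidationError

ACTIVATIONS = ("sigmoid", "rbf")

#: relative singular-value cutoff for the pseudoinverse, robust to the
#: rank deficiency that appears whenever n_hidden exceeds n_train
PINV_RCOND = 1e-10


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LabelEncoding:
    """One-of-C target encoding with symmetric hi/lo values."""

    classes: tuple
    target_hi: float = 1.0
    target_lo: float = -1.0

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("encoding classes must be unique")
        if not self.target_hi > self.target_lo:
            raise ValidationError("target_hi must exceed target_lo")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: Sequence) -> np.ndarray:
        """Encode labels into an (n_classes, n_samples) target matrix."""
        index = {c: k for k, c in enumerate(self.classes)}
        try:
            cols = [index[l] for l in labels]
        except KeyError as exc:
            raise ValidationError(f"unknown class label {exc.args[0]!r}") from None
        out = np.full((self.n_classes, len(cols)), self.target_lo, dtype=float)
        out[cols, np.arange(len(cols))] = self.target_hi
        return out

    def decode(self, outputs: np.ndarray) -> list:
        """Map an (n_classes, n_samples) output matrix to labels by argmax.

        Ties resolve to the lowest class index.
        """
        winners = np.argmax(outputs, axis=0)
        return [self.classes[k] for k in winners]


@dataclass
class FeatureScaler:
    """Per-feature z-scoring learned on training data.

    Features with zero training variance get scale 1 so they pass through
    centred but unscaled.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class HiddenLayerParams:
    """Random input-side parameters of the hidden layer.

    For ``sigmoid`` nodes, ``input_weights`` holds the weight vectors and
    ``bias`` the additive biases. For ``rbf`` nodes, ``input_weights`` rows
    are the centers and ``bias`` entries the (positive) widths.
    """

    n_hidden: int
    input_weights: np.ndarray
    bias: np.ndarray
    activation: str = "rbf"

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.n_hidden < 1:
            raise ValidationError("n_hidden must be >= 1")
        if self.input_weights.shape[0] != self.n_hidden or self.bias.shape != (self.n_hidden,):
            raise ValidationError(
                f"hidden-layer shapes inconsistent: weights {self.input_weights.shape}, "
                f"bias {self.bias.shape}, n_hidden {self.n_hidden}"
            )
        if not (np.all(np.isfinite(self.input_weights)) and np.all(np.isfinite(self.bias))):
            raise ValidationError("hidden-layer parameters must be finite")
        if self.activation == "rbf" and not np.all(self.bias > 0):
            raise ValidationError("rbf widths must be positive")

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


@dataclass
class ELMModel:
    hidden: HiddenLayerParams
    output_weights: np.ndarray  # (n_classes, n_hidden)
    encoding: LabelEncoding
    scaler: FeatureScaler

    def __post_init__(self) -> None:
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        if not np.all(np.isfinite(self.output_weights)):
            raise ValidationError("output weights must be finite")
        if self.output_weights.shape != (self.encoding.n_classes, self.hidden.n_hidden):
            raise ValidationError(
                f"output weights shape {self.output_weights.shape} does not match "
                f"({self.encoding.n_classes}, {self.hidden.n_hidden})"
            )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "activation": self.hidden.activation,
            "n_hidden": self.hidden.n_hidden,
            "input_weights": self.hidden.input_weights.tolist(),
            "bias": self.hidden.bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "classes": list(self.encoding.classes),
            "target_hi": self.encoding.target_hi,
            "target_lo": self.encoding.target_lo,
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_scale": self.scaler.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ELMModel":
        hidden = HiddenLayerParams(
            n_hidden=int(d["n_hidden"]),
            input_weights=np.asarray(d["input_weights"], dtype=float),
            bias=np.asarray(d["bias"], dtype=float),
            activation=d["activation"],
        )
        encoding = LabelEncoding(
            classes=tuple(d["classes"]),
            target_hi=float(d["target_hi"]),
            target_lo=float(d["target_lo"]),
        )
        scaler = FeatureScaler(
            mean=np.asarray(d["scaler_mean"], dtype=float),
            scale=np.asarray(d["scaler_scale"], dtype=float),
        )
        return cls(
            hidden=hidden,
            output_weights=np.asarray(d["output_weights"], dtype=float),
            encoding=encoding,
            scaler=scaler,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ELMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def hidden_response(X: np.ndarray, hidden: HiddenLayerParams) -> np.ndarray:
    """Hidden-layer response matrix, shape (n_hidden, n_samples).

    ``sigmoid``: entry (j, i) = 1 / (1 + exp(-(v_j . x_i + b_j))).
    ``rbf``: entry (j, i) = exp(-||x_i - mu_j||^2 / (2 sigma_j^2)).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D (samples x features), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    if X.shape[1] != hidden.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features but hidden layer expects {hidden.n_features}"
        )
    if hidden.activation == "sigmoid":
        z = hidden.input_weights @ X.T + hidden.bias[:, None]
        # clip keeps exp from overflowing; sigmoid saturates well before +-500
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    # rbf
    sq = (
        np.sum(hidden.input_weights**2, axis=1)[:, None]
        - 2.0 * hidden.input_weights @ X.T
        + np.sum(X**2, axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * hidden.bias[:, None] ** 2))


def _random_hidden(
    X_scaled: np.ndarray, n_hidden: int, activation: str, rng: np.random.Generator
) -> HiddenLayerParams:
    n_train, n_features = X_scaled.shape
    if activation == "sigmoid":
        V = rng.uniform(-1.0, 1.0, size=(n_hidden, n_features))
        b = rng.uniform(-1.0, 1.0, size=n_hidden)
    elif activation == "rbf":
        centers = X_scaled[rng.integers(0, n_train, size=n_hidden)]
        if n_train > 1:
            sigma = float(np.median(pdist(X_scaled)))
        else:
            sigma = 0.0
        if sigma <= 0:
            sigma = 1.0
        V = centers.copy()
        b = np.full(n_hidden, sigma)
    else:
        raise ValidationError(f"unknown activation {activation!r}")
    return HiddenLayerParams(n_hidden=n_hidden, input_weights=V, bias=b, activation=activation)


def train_elm(
    X_train: np.ndarray,
    y_train: Sequence,
    n_hidden: int | None = None,
    activation: str = "rbf",
    seed=None,
) -> ELMModel:
    """Train an ELM: draw the hidden layer at random, solve the output weights.

    Parameters
    ----------
    X_train
        Training features, shape (n_train, n_features).
    y_train
        Class labels, one per training sample; at least two distinct classes.
    n_hidden
        Hidden-neuron count; defaults to ``max(100, min(4 * n_train, 1000))``.
        The default deliberately overshoots ``n_train``: at
        ``n_hidden == n_train`` the least-squares fit interpolates the
        training data with near-singular hidden responses and
        generalization collapses, whereas the overparameterized minimum-norm
        solution degrades gracefully with irrelevant features.
    activation
        ``"rbf"`` (default) or ``"sigmoid"``.
    seed
        Integer seed or ``numpy.random.Generator``; identical seeds yield
        bit-identical models.
    """
    rng = _as_rng(seed)
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2:
        raise ValidationError(f"X_train must be 2-D, got shape {X_train.shape}")
    y_train = list(y_train)
    if len(y_train) != X_train.shape[0]:
        raise ValidationError(
            f"{len(y_train)} labels for {X_train.shape[0]} training samples"
        )
    classes = tuple(dict.fromkeys(y_train))
    if len(classes) < 2:
        raise ValidationError(
            "training set contains a single class; the decision rule is undefined"
        )
    if n_hidden is None:
        n_hidden = max(100, min(4 * X_train.shape[0], 1000))

    scaler = FeatureScaler.fit(X_train)
    Xs = scaler.transform(X_train)
    hidden = _random_hidden(Xs, n_hidden, activation, rng)
    Yh = hidden_response(Xs, hidden)
    encoding = LabelEncoding(classes=classes)
    Y = encoding.encode(y_train)
    W = Y @ np.linalg.pinv(Yh, rcond=PINV_RCOND)
    return ELMModel(hidden=hidden, output_weights=W, encoding=encoding, scaler=scaler)


def class_outputs(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw class outputs W @ hidden_response(scaled X), shape (n_classes, n_samples)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.hidden.n_features:
        raise ValidationError(
            f"X shape {X.shape} does not match model feature count {model.hidden.n_features}"
        )
    return model.output_weights @ hidden_response(model.scaler.transform(X), model.hidden)


def predict_elm(model: ELMModel, X: np.ndarray) -> list:
    """Predicted class labels: argmax over class outputs, ties to lowest index."""
    return model.encoding.decode(class_outputs(model, X))


def tune_elm(
    X_train: np.ndarray,
    y_train: Sequence,
    X_val: np.ndarray,
    y_val: Sequence,
    candidate_hidden_counts: Sequence[int],
    n_restarts: int = 1,
    activation: str = "rbf",
    seed=None,
) -> ELMModel:
    """Random-restart search over hidden-neuron counts and random draws.

    Trains one model per (candidate count, restart) and returns the one
    minimizing validation misclassifications, breaking ties by the squared
    error between encoded targets and raw outputs. Deterministic given seed.
    """
    candidate_hidden_counts = list(candidate_hidden_counts)
    if not candidate_hidden_counts:
        raise ValidationError("candidate_hidden_counts must be nonempty")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    X_val = np.asarray(X_val, dtype=float)
    y_val = list(y_val)
    if X_val.shape[0] == 0 or not y_val:
        raise ValidationError("validation set is empty")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(candidate_hidden_counts) * n_restarts)
    best: tuple[int, float] | None = None
    best_model: ELMModel | None = None
    k = 0
    for H in candidate_hidden_counts:
        for _ in range(n_restarts):
            model = train_elm(
                X_train, y_train, n_hidden=H, activation=activation,
                seed=np.random.default_rng(children[k]),
            )
            k += 1
            outputs = class_outputs(model, X_val)
            pred = model.encoding.decode(outputs)
            n_err = sum(p != t for p, t in zip(pred, y_val))
            sq = float(np.sum((model.encoding.encode(y_val) - outputs) ** 2))
            key = (n_err, sq)
            if best is None or key < best:
                best = key
                best_model = model
    assert best_model is not None
    return best_model
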