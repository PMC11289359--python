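"""Per-metric regression heads over a fixed word-embedding space.

Each head maps a d-dimensional embedding to a rating in (0, 1):

    y = sigmoid( w2 . LayerNorm(W1 x + b1) + b2 )

i.e. one dense layer, layer normalization (with learnable gain/shift),
a scalar output layer and a sigmoid squashing onto the normalized rating
scale. One head is trained per predicted metric; all heads of a bundle
share the embedding dimension. Dropout (inverted, applied to the
layer-norm output) is active only in training mode.

Gradients are computed analytically, both with respect to the parameters
(for training) and with respect to the input embedding — the latter is what
the stimulus-matching descent moves along. Embeddings are fixed inputs here;
any encoder that produces per-word vectors can feed the heads through the
:class:`~affectnorm.lexicon.EmbeddingLexicon` interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "RegressionHead",
    "ModelBundle",
    "predict",
    "predict_batch",
    "input_gradient",
    "loss",
    "batch_loss",
    "save_bundle",
    "load_bundle",
]

LN_EPS = 1e-5  # layer-norm variance epsilon


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


@dataclass
class RegressionHead:
    """Trainable embedding -> (0, 1) mapping for one metric."""

    metric: str
    W1: np.ndarray  # (h, d)
    b1: np.ndarray  # (h,)
    ln_gamma: np.ndarray  # (h,)
    ln_beta: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    dropout_p: float = 0.1

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.ln_gamma = np.asarray(self.ln_gamma, dtype=float)
        self.ln_beta = np.asarray(self.ln_beta, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = float(self.b2)
        h, d = self.W1.shape
        if h < 1 or d < 1:
            raise ValueError("head needs h >= 1 and d >= 1")
        for name in ("b1", "ln_gamma", "ln_beta", "w2"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        for name in ("W1", "b1", "ln_gamma", "ln_beta", "w2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite parameter {name}")

    @property
    def dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    @classmethod
    def initialize(
        cls,
        metric: str,
        dim: int,
        hidden: int | None = None,
        dropout_p: float = 0.1,
        rng: np.random.Generator | int | None = None,
    ) -> "RegressionHead":
        """Glorot-uniform weights, zero biases, unit layer-norm gain."""
        h = dim if hidden is None else int(hidden)
        rng = np.random.default_rng(rng)
        lim1 = np.sqrt(6.0 / (dim + h))
        lim2 = np.sqrt(6.0 / (h + 1))
        return cls(
            metric=metric,
            W1=rng.uniform(-lim1, lim1, size=(h, dim)),
            b1=np.zeros(h),
            ln_gamma=np.ones(h),
            ln_beta=np.zeros(h),
            w2=rng.uniform(-lim2, lim2, size=h),
            b2=0.0,
            dropout_p=dropout_p,
        )

    def params(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1, "b1": self.b1, "ln_gamma": self.ln_gamma,
            "ln_beta": self.ln_beta, "w2": self.w2,
            "b2": np.array([self.b2]),
        }

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        self.W1 = np.asarray(params["W1"], dtype=float)
        self.b1 = np.asarray(params["b1"], dtype=float)
        self.ln_gamma = np.asarray(params["ln_gamma"], dtype=float)
        self.ln_beta = np.asarray(params["ln_beta"], dtype=float)
        self.w2 = np.asarray(params["w2"], dtype=float)
        self.b2 = float(np.asarray(params["b2"]).reshape(()))

    def copy(self) -> "RegressionHead":
        return RegressionHead(
            metric=self.metric, W1=self.W1.copy(), b1=self.b1.copy(),
            ln_gamma=self.ln_gamma.copy(), ln_beta=self.ln_beta.copy(),
            w2=self.w2.copy(), b2=self.b2, dropout_p=self.dropout_p,
        )


def _forward(
    head: RegressionHead,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Batched forward pass; returns (predictions, cache for backward)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != head.dim:
        raise ValueError(f"input dim {X.shape[1]} != head dim {head.dim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input embedding")
    Z = X @ head.W1.T + head.b1  # (n, h)
    mu = Z.mean(axis=1, keepdims=True)
    var = Z.var(axis=1, keepdims=True)  # population variance
    inv = 1.0 / np.sqrt(var + LN_EPS)
    Zhat = (Z - mu) * inv
    A = head.ln_gamma * Zhat + head.ln_beta
    if training and head.dropout_p > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - head.dropout_p
        mask = (rng.random(A.shape) < keep) / keep
    else:
        mask = np.ones_like(A)
    Ad = A * mask
    S = Ad @ head.w2 + head.b2  # (n,)
    Y = sigmoid(S)
    cache = {"X": X, "Zhat": Zhat, "inv": inv, "mask": mask, "Ad": Ad, "Y": Y}
    return Y, cache


def _backward(head: RegressionHead, cache: dict, dY: np.ndarray):
    """Backprop ``dY`` (grad wrt predictions) through the head.

    Returns (param_grads, input_grads) where input_grads is (n, d).
    """
    X, Zhat, inv, mask, Ad, Y = (
        cache["X"], cache["Zhat"], cache["inv"], cache["mask"],
        cache["Ad"], cache["Y"],
    )
    dS = np.asarray(dY, dtype=float) * Y * (1.0 - Y)  # (n,)
    grads: dict[str, np.ndarray] = {}
    grads["w2"] = dS @ Ad
    grads["b2"] = np.array([dS.sum()])
    dAd = np.outer(dS, head.w2)  # (n, h)
    dA = dAd * mask
    grads["ln_gamma"] = (dA * Zhat).sum(axis=0)
    grads["ln_beta"] = dA.sum(axis=0)
    dZhat = dA * head.ln_gamma
    # layer-norm backward (population variance)
    m1 = dZhat.mean(axis=1, keepdims=True)
    m2 = (dZhat * Zhat).mean(axis=1, keepdims=True)
    dZ = inv * (dZhat - m1 - Zhat * m2)
    grads["W1"] = dZ.T @ X
    grads["b1"] = dZ.sum(axis=0)
    dX = dZ @ head.W1
    return grads, dX


def predict(
    head: RegressionHead,
    x: np.ndarray,
    training_mode: bool = False,
    rng_seed: int = 0,
) -> float:
    """Predict the normalized rating for one embedding vector.

    Inference (``training_mode=False``) is deterministic and ignores
    ``rng_seed``; in training mode dropout is applied with the seeded rng.
    """
    rng = np.random.default_rng(rng_seed) if training_mode else None
    y, _ = _forward(head, np.asarray(x, dtype=float)[None, :], training_mode, rng)
    return float(y[0])


def predict_batch(head: RegressionHead, X: np.ndarray) -> np.ndarray:
    """Deterministic inference over an (n, d) batch."""
    y, _ = _forward(head, X)
    return y


def input_gradient(head: RegressionHead, x: np.ndarray, sign: int = 1) -> np.ndarray:
    """Exact gradient of ``sign * predict(head, x)`` with respect to ``x``.

    Inference mode (no dropout). This is the direction of steepest increase
    (sign=+1) or decrease (sign=-1) of the predicted rating in embedding
    space.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    x = np.asarray(x, dtype=float)
    _, cache = _forward(head, x[None, :])
    _, dX = _backward(head, cache, np.array([float(sign)]))
    return dX[0]


def loss(pred: float, target: float) -> float:
    """Squared error between a prediction and a normalized target rating."""
    pred, target = float(pred), float(target)
    if not (np.isfinite(pred) and np.isfinite(target)):
        raise ValueError("loss inputs must be finite")
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target {target} outside [0, 1]")
    return (pred - target) ** 2


def batch_loss(preds: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error over a batch."""
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape:
        raise ValueError("preds and targets must align")
    if targets.size and (targets.min() < 0.0 or targets.max() > 1.0):
        raise ValueError("targets outside [0, 1]")
    return float(np.mean((preds - targets) ** 2))


@dataclass
class ModelBundle:
    """One regression head per predicted metric over a shared embedding space."""

    heads: dict[str, RegressionHead] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {h.dim for h in self.heads.values()}
        if len(dims) > 1:
            raise ValueError(f"heads disagree on embedding dim: {sorted(dims)}")

    @classmethod
    def initialize(
        cls,
        metrics: list[str],
        dim: int,
        hidden: int | None = None,
        dropout_p: float = 0.1,
        seed: int = 0,
    ) -> "ModelBundle":
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(metrics))
        return cls(heads={
            m: RegressionHead.initialize(
                m, dim, hidden=hidden, dropout_p=dropout_p,
                rng=np.random.default_rng(child),
            )
            for m, child in zip(metrics, children)
        })

    @property
    def metrics(self) -> list[str]:
        return list(self.heads)

    @property
    def dim(self) -> int:
        return next(iter(self.heads.values())).dim

    def __iter__(self) -> Iterator[RegressionHead]:
        return iter(self.heads.values())

    def predict_word(self, x: np.ndarray) -> dict[str, float]:
        return {m: predict(h, x) for m, h in self.heads.items()}

    def predict_all(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {m: predict_batch(h, X) for m, h in self.heads.items()}

    def copy(self) -> "ModelBundle":
        return ModelBundle(heads={m: h.copy() for m, h in self.heads.items()})


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle to a self-describing JSON file (exact doubles)."""
    doc = {
        "format": "affectnorm-model",
        "version": 1,
        "dim": bundle.dim,
        "metrics": bundle.metrics,
        "heads": {
            m: {
                "hidden": h.hidden,
                "dropout_p": h.dropout_p,
                "W1": h.W1.tolist(),
                "b1": h.b1.tolist(),
                "ln_gamma": h.ln_gamma.tolist(),
                "ln_beta": h.ln_beta.tolist(),
                "w2": h.w2.tolist(),
                "b2": h.b2,
            }
            for m, h in bundle.heads.items()
        },
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_bundle(path: str | Path) -> ModelBundle:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "affectnorm-model":
        raise ValueError(f"{path} is not an affectnorm model file")
    heads = {}
    for m, spec in doc["heads"].items():
        heads[m] = RegressionHead(
            metric=m,
            W1=np.array(spec["W1"], dtype=float),
            b1=np.array(spec["b1"], dtype=float),
            ln_gamma=np.array(spec["ln_gamma"], dtype=float),
            ln_beta=np.array(spec["ln_beta"], dtype=float),
            w2=np.array(spec["w2"], dtype=float),
            b2=spec["b2"],
            dropout_p=spec.get("dropout_p", 0.0),
        )
    return ModelBundle(heads=heads)
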