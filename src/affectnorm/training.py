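"""Optimization of model bundles: AdamW with amsgrad, linear warmup/decay,
early stopping by best mean validation correlation.

The regime: mini-batch updates ("learning steps") with a learning-rate
multiplier that ramps linearly from 0 to 1 over ``warmup_steps`` steps and
then decays linearly back to 0 at the final step; training runs up to
``epochs`` epochs while checkpointing the parameters of the epoch with the
highest mean per-metric Pearson correlation on the validation words — the
returned model is that checkpoint, which is what "early stopping" means
here (no run is aborted, the best snapshot is kept).

All heads are trained jointly on the summed per-metric squared-error loss;
a word missing a metric simply contributes no loss for that head.
Everything is deterministic for a fixed config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lexicon import EmbeddingLexicon, NormLexicon, SplitSpec
from .model import ModelBundle, _backward, _forward, predict_batch

__all__ = [
    "TrainingConfig",
    "OptimizerState",
    "TrainingHistory",
    "lr_schedule",
    "adamw_step",
    "train_model",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the training regime.

    Defaults follow the reference regime for full-size norm corpora
    (lr 5e-5, 1000 epochs, 600 warmup steps, weight decay 0.3, amsgrad,
    betas (0.9, 0.999), eps 1e-8, dropout 0.1). Small synthetic worlds
    train well with a larger learning rate and far fewer epochs; pass an
    explicit config for those.
    """

    learning_rate: float = 5e-5
    epochs: int = 1000
    warmup_steps: int = 600
    batch_size: int = 32
    weight_decay: float = 0.3
    eps: float = 1e-8
    beta1: float = 0.9
    beta2: float = 0.999
    amsgrad: bool = True
    dropout_p: float = 0.1
    hidden: int | None = None  # None -> hidden width = embedding dim
    grad_clip: float | None = None  # optional global-norm clip
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("betas must lie in (0, 1)")
        if self.warmup_steps < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("warmup_steps >= 0, epochs >= 1, batch_size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class OptimizerState:
    """Per-parameter AdamW state: first/second moments, amsgrad running max,
    and the shared step counter."""

    def __init__(self) -> None:
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.v_max: dict[str, np.ndarray] = {}
        self.t: int = 0


def lr_schedule(step: int, warmup_steps: int, total_steps: int) -> float:
    """Learning-rate multiplier in [0, 1] at ``step``.

    Linear ramp 0 -> 1 over the warmup, peak exactly 1 at ``warmup_steps``,
    then linear decay to 0 at ``total_steps``. Steps beyond ``total_steps``
    clamp to 0.
    """
    if total_steps <= warmup_steps:
        raise ValueError("total_steps must exceed warmup_steps")
    if step < 0:
        raise ValueError("step must be >= 0")
    if step <= warmup_steps:
        return 1.0 if warmup_steps == 0 else step / warmup_steps
    if step >= total_steps:
        return 0.0
    return (total_steps - step) / (total_steps - warmup_steps)


def adamw_step(
    params: dict[str, np.ndarray],
    grads: Mapping[str, np.ndarray],
    state: OptimizerState,
    cfg: TrainingConfig,
    lr_mult: float = 1.0,
) -> dict[str, np.ndarray]:
    """One AdamW update with decoupled weight decay; mutates and returns
    ``params`` (and advances ``state``).

    theta <- theta - lr * lr_mult * ( m_hat / (sqrt(v_hat) + eps)
                                      + weight_decay * theta )

    With amsgrad the denominator uses the running elementwise maximum of the
    bias-corrected second moment.
    """
    state.t += 1
    t = state.t
    bc1 = 1.0 - cfg.beta1 ** t
    bc2 = 1.0 - cfg.beta2 ** t
    lr = cfg.learning_rate * lr_mult
    for name, theta in params.items():
        g = np.asarray(grads[name], dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {name!r}")
        if name not in state.m:
            state.m[name] = np.zeros_like(theta)
            state.v[name] = np.zeros_like(theta)
            state.v_max[name] = np.zeros_like(theta)
        m = state.m[name] = cfg.beta1 * state.m[name] + (1 - cfg.beta1) * g
        v = state.v[name] = cfg.beta2 * state.v[name] + (1 - cfg.beta2) * g * g
        m_hat = m / bc1
        v_hat = v / bc2
        if cfg.amsgrad:
            state.v_max[name] = np.maximum(state.v_max[name], v_hat)
            denom = np.sqrt(state.v_max[name]) + cfg.eps
        else:
            denom = np.sqrt(v_hat) + cfg.eps
        params[name] = theta - lr * (m_hat / denom + cfg.weight_decay * theta)
    return params


@dataclass
class TrainingHistory:
    """Per-epoch training loss, validation correlations and lr multiplier."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @property
    def best_mean_val_r(self) -> float:
        return self.records[self.best_epoch - 1]["mean_val_r"]


def _safe_pearson(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Validation correlation; undefined cases are 0 with a warning, never a
    mid-training exception."""
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn(
            f"validation correlation undefined for {metric!r} "
            f"(n={x.size}); recording 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def train_model(
    bundle: ModelBundle,
    embeddings: EmbeddingLexicon,
    norms: NormLexicon,
    split: SplitSpec,
    cfg: TrainingConfig,
) -> tuple[ModelBundle, TrainingHistory]:
    """Train all heads of ``bundle`` and return the best checkpoint.

    ``norms`` must already be on the [0, 1] scale. Words listed in the split
    must be present in both lexicons. Returns a new bundle holding the
    parameters of the epoch with the highest mean validation correlation,
    plus the full history.
    """
    finite = norms.means[np.isfinite(norms.means)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("norms must be normalized to [0, 1] before training")
    if len(split.val_words) < 1:
        raise ValueError("need at least one validation word")

    metrics = bundle.metrics
    X_tr = embeddings.matrix(split.train_words)
    Y_tr = np.column_stack(
        [norms.metric_values(m)[[norms.index(w) for w in split.train_words]]
         for m in metrics]
    )
    X_va = embeddings.matrix(split.val_words)
    Y_va = np.column_stack(
        [norms.metric_values(m)[[norms.index(w) for w in split.val_words]]
         for m in metrics]
    )

    n = len(split.train_words)
    batches_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * batches_per_epoch
    # short runs: the ramp cannot outlast the run itself
    warmup = min(cfg.warmup_steps, max(total_steps - 1, 0))

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    work = bundle.copy()
    for head in work:
        head.dropout_p = cfg.dropout_p
    params = {
        f"{m}/{pname}": arr
        for m in metrics
        for pname, arr in work.heads[m].params().items()
    }
    state = OptimizerState()
    history = TrainingHistory()
    best_r = -np.inf
    best_params: dict[str, np.ndarray] | None = None
    step = 0
    lr_mult = 0.0

    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_terms = 0
        for b in range(batches_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            grads = {name: np.zeros_like(arr) for name, arr in params.items()}
            for j, m in enumerate(metrics):
                head = work.heads[m]
                mask = np.isfinite(Y_tr[idx, j])
                if not mask.any():
                    continue
                Xb = X_tr[idx][mask]
                yb = Y_tr[idx, j][mask]
                preds, cache = _forward(head, Xb, training=True, rng=dropout_rng)
                resid = preds - yb
                epoch_loss += float(np.sum(resid**2))
                n_terms += resid.size
                dY = 2.0 * resid / resid.size  # grad of mean squared error
                head_grads, _ = _backward(head, cache, dY)
                for pname, g in head_grads.items():
                    grads[f"{m}/{pname}"] = g
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            lr_mult = lr_schedule(step, warmup, total_steps)
            adamw_step(params, grads, state, cfg, lr_mult)
            for m in metrics:
                work.heads[m].set_params(
                    {p: params[f"{m}/{p}"] for p in
                     ("W1", "b1", "ln_gamma", "ln_beta", "w2", "b2")}
                )
            step += 1

        val_r = {}
        for j, m in enumerate(metrics):
            mask = np.isfinite(Y_va[:, j])
            preds = predict_batch(work.heads[m], X_va[mask]) if mask.any() else np.array([])
            val_r[m] = _safe_pearson(preds, Y_va[mask, j], m)
        mean_r = float(np.mean(list(val_r.values())))
        history.records.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_terms, 1),
                **{f"val_r_{m}": val_r[m] for m in metrics},
                "mean_val_r": mean_r,
                "lr_mult": lr_mult,
            }
        )
        if mean_r > best_r:
            best_r = mean_r
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}

    result = work.copy()
    if best_params is not None:
        for m in metrics:
            result.heads[m].set_params(
                {p: best_params[f"{m}/{p}"] for p in
                 ("W1", "b1", "ln_gamma", "ln_beta", "w2", "b2")}
            )
    return result, history


def config_to_dict(cfg: TrainingConfig) -> dict:
    return asdict(cfg)
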