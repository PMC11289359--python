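"""Stimulus matching by controlled gradient descent in embedding space.

Given a trained model bundle, a seed word and a target metric, the search
moves the seed's embedding along the gradient of the predicted rating
(ascending or descending), while

* projecting out the gradients of any *controlled* metrics so their
  predictions stay approximately level ("controlled gradients"),
* penalizing excursions away from a multivariate Gaussian fitted to the
  word-occurrence distribution (model predictions far from where words
  actually live are unconstrained extrapolation), and
* after every step scanning the vocabulary for nearby words (cosine
  similarity) whose predicted rating differs from the seed's by at least
  the requested margin.

A match must satisfy three constraints simultaneously: rating difference
``delta_r >= delta_min_r`` in the requested direction, cosine similarity to
the seed embedding at least ``cosine_floor``, and every controlled metric's
drift within ``control_tolerance``. Failures return an explicit marker
("X" in serialized match tables) with diagnostics, never a silent best
guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .lexicon import EmbeddingLexicon, NormLexicon
from .model import ModelBundle, input_gradient, predict

__all__ = [
    "GaussianPrior",
    "DescentConfig",
    "MatchResult",
    "FAILURE_MARKER",
    "fit_gaussian_prior",
    "log_density_penalty",
    "penalty_gradient",
    "controlled_projection",
    "descent_step",
    "cosine_similarity",
    "nearest_words",
    "find_match",
    "match_levels",
    "select_seed_words",
]

FAILURE_MARKER = "X"


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian approximation to the word-occurrence distribution."""

    mu: np.ndarray
    sigma: np.ndarray
    ridge: float
    _chol: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma must be d x d")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        try:
            chol = linalg.cho_factor(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("sigma is not positive definite") from exc
        object.__setattr__(self, "_chol", chol)

    def solve(self, y: np.ndarray) -> np.ndarray:
        """sigma^{-1} y via the cached Cholesky factor."""
        return linalg.cho_solve(self._chol, y)


def fit_gaussian_prior(emb: EmbeddingLexicon, ridge_frac: float = 1e-3) -> GaussianPrior:
    """Fit mean and (ridged) sample covariance of the embedding cloud.

    ``ridge = ridge_frac * trace(cov) / d`` is added to the diagonal; for a
    degenerate cloud (zero covariance) the ridge falls back to
    ``ridge_frac`` itself so the prior stays positive definite.
    """
    if len(emb) < 2:
        raise ValueError("need at least two words to fit the prior")
    X = emb.vectors
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    d = X.shape[1]
    ridge = ridge_frac * float(np.trace(cov)) / d
    if ridge <= 0.0:
        ridge = ridge_frac
    return GaussianPrior(mu=mu, sigma=cov + ridge * np.eye(d), ridge=ridge)


def log_density_penalty(x: np.ndarray, prior: GaussianPrior) -> float:
    """Half squared Mahalanobis distance from the prior mean.

    This is the negative Gaussian log density shifted so its minimum (at
    ``mu``) is 0, with the constant terms dropped.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite point")
    diff = x - prior.mu
    return float(0.5 * diff @ prior.solve(diff))


def penalty_gradient(x: np.ndarray, prior: GaussianPrior) -> np.ndarray:
    """Gradient of :func:`log_density_penalty`: ``sigma^{-1} (x - mu)``."""
    return prior.solve(np.asarray(x, dtype=float) - prior.mu)


def controlled_projection(g: np.ndarray, control_grads) -> np.ndarray:
    """Remove the components of ``g`` along every control gradient.

    The control gradients are orthonormalized by modified Gram-Schmidt
    (vectors with norm below 1e-12 after deflation are dropped); the result
    is orthogonal to each control gradient. An empty control list is the
    identity.
    """
    g = np.asarray(g, dtype=float)
    basis: list[np.ndarray] = []
    for c in control_grads:
        v = np.asarray(c, dtype=float).copy()
        if v.shape != g.shape:
            raise ValueError("control gradient dimension mismatch")
        for e in basis:
            v -= (v @ e) * e
        nrm = np.linalg.norm(v)
        if nrm > 1e-12:
            basis.append(v / nrm)
    out = g.copy()
    for e in basis:
        out -= (out @ e) * e
    return out


@dataclass(frozen=True)
class DescentConfig:
    """Knobs of the matched-stimulus search.

    ``delta_min_r`` is the minimum required rating difference on the [0, 1]
    norm scale; ``sign`` +1 increases the target metric, -1 decreases it.
    ``step_size=None`` resolves at search time to 0.1 x the mean
    per-coordinate SD of the embedding cloud.
    """

    target_metric: str
    sign: int = 1
    delta_min_r: float = 0.1
    controlled_metrics: tuple[str, ...] = ()
    step_size: float | None = None
    max_steps: int = 200
    lambda_reg: float = 0.01
    cosine_floor: float = 0.4
    control_tolerance: float = 0.05
    k_candidates: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if not (0.0 < self.delta_min_r < 1.0):
            raise ValueError("delta_min_r must lie in (0, 1)")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        object.__setattr__(self, "controlled_metrics",
                           tuple(self.controlled_metrics))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one matched-word search."""

    seed_word: str
    matched_word: str | None
    delta_r: float
    control_drifts: dict
    cosine: float
    steps: int

    @property
    def success(self) -> bool:
        return self.matched_word is not None

    @property
    def matched_label(self) -> str:
        return self.matched_word if self.success else FAILURE_MARKER


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def nearest_words(
    x: np.ndarray,
    emb: EmbeddingLexicon,
    k: int,
    exclude=frozenset(),
) -> list[tuple[str, float]]:
    """Top-k vocabulary words by cosine similarity to ``x``; ties broken
    alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(x, dtype=float)
    nx = np.linalg.norm(x)
    if nx == 0.0:
        raise ValueError("query vector is zero")
    exclude = set(exclude)
    keep = [i for i, w in enumerate(emb.words) if w not in exclude]
    if not keep:
        raise ValueError("vocabulary empty after exclusion")
    V = emb.vectors[keep]
    sims = V @ x / (np.linalg.norm(V, axis=1) * nx)
    order = sorted(range(len(keep)), key=lambda i: (-sims[i], emb.words[keep[i]]))
    return [(emb.words[keep[i]], float(sims[i])) for i in order[:k]]


def _resolve_step(cfg: DescentConfig, emb: EmbeddingLexicon) -> float:
    if cfg.step_size is not None:
        return cfg.step_size
    return 0.1 * float(np.mean(emb.vectors.std(axis=0)))


def descent_step(
    x: np.ndarray,
    bundle: ModelBundle,
    prior: GaussianPrior,
    cfg: DescentConfig,
    step_size: float | None = None,
) -> np.ndarray:
    """One controlled gradient-descent step from ``x``.

    The objective is ``L(x) = -sign * predict_target(x)
    + lambda_reg * log_density_penalty(x)``; its gradient is projected
    orthogonal to the controlled metrics' gradients and the step moves
    downhill by ``step_size`` along the *normalized* projected gradient.
    Normalizing keeps the search moving even where the sigmoid saturates
    and its raw gradient is vanishingly small; a (projected) gradient of
    zero is a stationary point and leaves ``x`` unchanged.
    """
    x = np.asarray(x, dtype=float)
    head = bundle.heads[cfg.target_metric]
    g = -cfg.sign * input_gradient(head, x) \
        + cfg.lambda_reg * penalty_gradient(x, prior)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite objective gradient")
    controls = [
        input_gradient(bundle.heads[c], x) for c in cfg.controlled_metrics
    ]
    direction = controlled_projection(g, controls)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        return x
    eta = step_size if step_size is not None else cfg.step_size
    if eta is None:
        raise ValueError("step_size unresolved; pass one explicitly")
    return x - eta * (direction / nrm)


def find_match(
    seed_word: str,
    bundle: ModelBundle,
    emb: EmbeddingLexicon,
    prior: GaussianPrior,
    cfg: DescentConfig,
    exclude=frozenset(),
) -> MatchResult:
    """Search the vocabulary for a word matched to ``seed_word``.

    Iterates :func:`descent_step` from the seed embedding for up to
    ``max_steps`` steps; after each step the ``k_candidates`` nearest words
    to the current point (excluding the seed, ``exclude`` and previously
    rejected-by-distance candidates are still rescanned) are tested against
    the three match constraints. The first word passing all of them wins.
    On failure the result carries the best rating difference seen among
    candidates that met the cosine floor, and ``matched_word=None``.
    """
    if seed_word not in emb:
        raise KeyError(f"unknown seed word {seed_word!r}")
    x0 = emb.vector(seed_word)
    head = bundle.heads[cfg.target_metric]
    base_target = predict(head, x0)
    base_controls = {
        c: predict(bundle.heads[c], x0) for c in cfg.controlled_metrics
    }
    excluded = set(exclude) | {seed_word}
    step_size = _resolve_step(cfg, emb)

    x = x0.copy()
    best_delta = -np.inf
    best_diag: tuple[float, dict] = (0.0, {})
    checked: dict[str, None] = {}
    for step in range(1, cfg.max_steps + 1):
        x = descent_step(x, bundle, prior, cfg, step_size=step_size)
        for word, _ in nearest_words(x, emb, cfg.k_candidates, exclude=excluded):
            if word in checked:
                continue
            checked[word] = None
            v = emb.vector(word)
            cos = cosine_similarity(v, x0)
            delta = cfg.sign * (predict(head, v) - base_target)
            drifts = {
                c: predict(bundle.heads[c], v) - base_controls[c]
                for c in cfg.controlled_metrics
            }
            if cos >= cfg.cosine_floor and delta > best_delta:
                best_delta = delta
                best_diag = (cos, drifts)
            if (
                delta >= cfg.delta_min_r
                and cos >= cfg.cosine_floor
                and all(abs(d) <= cfg.control_tolerance for d in drifts.values())
            ):
                return MatchResult(
                    seed_word=seed_word, matched_word=word, delta_r=delta,
                    control_drifts=drifts, cosine=cos, steps=step,
                )
    return MatchResult(
        seed_word=seed_word, matched_word=None,
        delta_r=best_delta if np.isfinite(best_delta) else 0.0,
        control_drifts=best_diag[1], cosine=best_diag[0],
        steps=cfg.max_steps,
    )


def match_levels(
    seed_word: str,
    bundle: ModelBundle,
    emb: EmbeddingLexicon,
    prior: GaussianPrior,
    cfg: DescentConfig,
    n_levels: int = 2,
) -> list[MatchResult]:
    """Sequential multi-level matching (e.g. medium and high manipulation).

    Level ``i`` (1-based) requires a rating difference of
    ``i * cfg.delta_min_r``; earlier matches are excluded cumulatively, so
    each level's word is new. A failed level still lets later levels run.
    """
    results: list[MatchResult] = []
    excluded: set[str] = set()
    for level in range(1, n_levels + 1):
        level_cfg = replace(cfg, delta_min_r=min(level * cfg.delta_min_r, 0.999))
        res = find_match(seed_word, bundle, emb, prior, level_cfg,
                         exclude=frozenset(excluded))
        results.append(res)
        if res.success:
            excluded.add(res.matched_word)
    return results


def select_seed_words(
    norms: NormLexicon,
    metric: str,
    z_offset: float,
    n_per_side: int,
) -> list[str]:
    """Pick seed words purely from ratings: the ``n_per_side`` words whose
    ratings lie nearest to mean + z_offset * SD, then the ``n_per_side``
    nearest to mean - z_offset * SD (excluding already-picked words). Ties
    break alphabetically. Typical offsets: 1.0 for valence, 1.5 for arousal.
    """
    values = norms.metric_values(metric)
    ok = np.isfinite(values)
    words = [w for w, m in zip(norms.words, ok) if m]
    vals = values[ok]
    if len(words) < 2 * n_per_side:
        raise ValueError(
            f"need >= {2 * n_per_side} rated words, have {len(words)}"
        )
    mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
    chosen: list[str] = []
    for target in (mean + z_offset * sd, mean - z_offset * sd):
        pool = sorted(
            (w for w in words if w not in chosen),
            key=lambda w: (abs(vals[words.index(w)] - target), w),
        )
        chosen.extend(pool[:n_per_side])
    return chosen
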