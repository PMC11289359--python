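"""A fully specified synthetic word-world with known ground truth.

Emulates the structure of real norm studies so every other module can be
exercised end to end without external data: a clustered embedding space
(Gaussian mixture), smooth ground-truth norm functions (sigmoid of a linear
map, hence locally linear everywhere), simulated raters on a 9-point scale
with per-word noise, optional per-participant rating records with gender
labels and repeat presentations, and covariate-dependent (logistic)
missingness for missing-not-at-random experiments.

What it deliberately does *not* emulate: real lexical frequency
distributions, heavy-tailed embedding geometry, correlated rater panels, or
multilingual vocabularies.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lexicon import EmbeddingLexicon, NormLexicon
from .model import sigmoid

__all__ = [
    "MetricSpec",
    "SyntheticWorldConfig",
    "make_embedding_space",
    "make_true_norms",
    "simulate_raters",
    "simulate_rating_records",
    "impose_mnar",
    "word_lengths",
]


@dataclass(frozen=True)
class MetricSpec:
    """Ground-truth norm function for one metric: sigmoid(w . x + b), plus
    the SD of rater noise on the raw rating scale."""

    name: str
    w: np.ndarray | None = None  # None -> drawn at world-build time
    b: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Generator settings for one synthetic word-world.

    Defaults give the reference study conditions used throughout the test
    suite: 1000 words in 16 dimensions, 5 embedding clusters, three metrics,
    25 raters per word on a 9-point scale with rater-noise SD 0.5.
    """

    vocab_size: int = 1000
    dim: int = 16
    n_clusters: int = 5
    cluster_spread: float = 0.5
    metrics: tuple[MetricSpec, ...] = (
        MetricSpec("valence"),
        MetricSpec("arousal"),
        MetricSpec("concreteness"),
    )
    n_raters: int = 25
    scale: tuple[float, float] = (1.0, 9.0)
    w_scale: float = 1.5  # norm of generated projection vectors
    min_word_len: int = 3
    max_word_len: int = 10
    missing_intercept: float = 0.0
    missing_slopes: dict = field(default_factory=dict)  # covariate -> slope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 2 or self.dim < 1:
            raise ValueError("need vocab_size >= 2 and dim >= 1")
        if self.scale[1] <= self.scale[0]:
            raise ValueError("scale max must exceed scale min")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")

    def resolved_metrics(self) -> tuple[MetricSpec, ...]:
        """Metric specs with projection vectors drawn where unset
        (deterministic per world seed)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 2]))
        out = []
        for spec in self.metrics:
            if spec.w is None:
                w = rng.standard_normal(self.dim)
                w *= self.w_scale / np.linalg.norm(w)
                out.append(replace(spec, w=w))
            else:
                w = np.asarray(spec.w, dtype=float)
                if w.shape != (self.dim,):
                    raise ValueError(
                        f"metric {spec.name!r}: w has shape {w.shape}, "
                        f"expected ({self.dim},)"
                    )
                out.append(replace(spec, w=w))
        return tuple(out)


def _rng(cfg: SyntheticWorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _pseudo_words(cfg: SyntheticWorldConfig) -> list[str]:
    rng = _rng(cfg, 0)
    letters = np.array(list(string.ascii_lowercase))
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < cfg.vocab_size:
        L = int(rng.integers(cfg.min_word_len, cfg.max_word_len + 1))
        w = "".join(rng.choice(letters, size=L))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def make_embedding_space(cfg: SyntheticWorldConfig) -> EmbeddingLexicon:
    """Draw the vocabulary and its vectors from a seeded Gaussian mixture.

    Cluster means are standard-normal; each word's vector is its cluster
    mean plus isotropic noise with SD ``cluster_spread``. Word strings are
    random lowercase pseudo-words of varying length, so word length exists
    as a covariate. Deterministic per seed.
    """
    words = _pseudo_words(cfg)
    rng = _rng(cfg, 1)
    centers = rng.standard_normal((cfg.n_clusters, cfg.dim))
    assign = rng.integers(0, cfg.n_clusters, size=cfg.vocab_size)
    vectors = centers[assign] + cfg.cluster_spread * rng.standard_normal(
        (cfg.vocab_size, cfg.dim)
    )
    return EmbeddingLexicon(words=tuple(words), vectors=vectors)


def make_true_norms(emb: EmbeddingLexicon, cfg: SyntheticWorldConfig) -> pd.DataFrame:
    """Ground-truth norms on [0, 1]: ``sigmoid(w_m . x + b_m)`` per metric.

    The link is smooth with slowly varying gradient, so the mapping is
    locally linear — the regime the matched-stimulus search assumes.
    """
    out = {"word": list(emb.words)}
    for spec in cfg.resolved_metrics():
        out[spec.name] = sigmoid(emb.vectors @ spec.w + spec.b)
    return pd.DataFrame(out).set_index("word")


def simulate_raters(
    true_norms: pd.DataFrame, cfg: SyntheticWorldConfig
) -> NormLexicon:
    """Simulate ``n_raters`` ratings per word and metric.

    Each rating is the truth mapped to the raw scale plus Gaussian noise
    (``noise_sd``, raw-scale units), clipped to the scale bounds — clipping
    rather than resampling, which slightly biases words near the endpoints
    exactly the way real ceiling effects do. The returned lexicon stores the
    per-word mean, SD (ddof=1) and rater count, already normalized back to
    [0, 1].
    """
    rng = _rng(cfg, 3)
    lo, hi = cfg.scale
    width = hi - lo
    specs = cfg.resolved_metrics()
    words = list(true_norms.index)
    n_w = len(words)
    means = np.empty((n_w, len(specs)))
    sds = np.empty_like(means)
    for j, spec in enumerate(specs):
        truth_raw = lo + true_norms[spec.name].to_numpy() * width
        ratings = truth_raw[:, None] + spec.noise_sd * rng.standard_normal(
            (n_w, cfg.n_raters)
        )
        np.clip(ratings, lo, hi, out=ratings)
        means[:, j] = ratings.mean(axis=1)
        sds[:, j] = ratings.std(axis=1, ddof=1) if cfg.n_raters > 1 else 0.0
    return NormLexicon(
        words=tuple(words),
        metrics=tuple(s.name for s in specs),
        means=(means - lo) / width,
        sds=sds / width,
        n_raters=np.full(n_w, cfg.n_raters, dtype=int),
        scale=(0.0, 1.0),
    )


def simulate_rating_records(
    true_norms: pd.DataFrame,
    cfg: SyntheticWorldConfig,
    n_participants: int = 20,
    words_per_participant: int = 30,
    n_repeats: int = 5,
    dimensions: tuple[str, ...] | None = None,
    careless: tuple = (),
) -> pd.DataFrame:
    """Per-participant rating records with gender labels and repeat
    presentations, for reliability filtering and gender-balanced means.

    Each participant rates ``words_per_participant`` words on one dimension
    (round-robin over ``dimensions``); the first ``n_repeats`` of their
    words are shown a second time (``presentation == 2``). Participants in
    ``careless`` answer uniformly at random, giving low test-retest
    reliability on purpose. Genders alternate F/M by participant index.
    """
    rng = _rng(cfg, 4)
    dims = tuple(dimensions or (cfg.metrics[0].name,))
    lo, hi = cfg.scale
    width = hi - lo
    words = list(true_norms.index)
    careless = set(careless)
    rows = []
    for p in range(n_participants):
        pid = f"p{p:03d}"
        dim = dims[p % len(dims)]
        picked = rng.choice(len(words), size=words_per_participant, replace=False)
        truth_raw = lo + true_norms[dim].to_numpy()[picked] * width
        for presentation in (1, 2):
            subset = range(len(picked)) if presentation == 1 else range(n_repeats)
            for i in subset:
                if pid in careless:
                    rating = float(rng.uniform(lo, hi))
                else:
                    rating = float(
                        np.clip(truth_raw[i] + 0.5 * rng.standard_normal(), lo, hi)
                    )
                rows.append(
                    {
                        "participant": pid,
                        "gender": "F" if p % 2 == 0 else "M",
                        "word": words[picked[i]],
                        "dimension": dim,
                        "rating": rating,
                        "presentation": presentation,
                    }
                )
    return pd.DataFrame(rows)


def impose_mnar(
    lex: NormLexicon,
    covariates: pd.DataFrame,
    cfg: SyntheticWorldConfig,
) -> tuple[NormLexicon, np.ndarray]:
    """Drop words with covariate-dependent probability.

    Each word is retained with probability
    ``logistic(intercept + sum_k slope_k * covariate_k)`` using
    ``cfg.missing_intercept`` / ``cfg.missing_slopes`` (keys are columns of
    ``covariates``, aligned with ``lex.words``). All slopes 0 with intercept
    0 is MCAR at retention probability 0.5. Returns the observed lexicon and
    the boolean keep-mask. Seeded via the world seed.
    """
    if list(covariates.index) != list(lex.words):
        raise ValueError("covariates must be indexed by the lexicon words")
    rng = _rng(cfg, 5)
    eta = np.full(len(lex), cfg.missing_intercept, dtype=float)
    for name, slope in cfg.missing_slopes.items():
        eta += slope * covariates[name].to_numpy(dtype=float)
    p_keep = sigmoid(eta)
    keep = rng.random(len(lex)) < p_keep
    kept_words = [w for w, k in zip(lex.words, keep) if k]
    return lex.subset(kept_words), keep


def word_lengths(words) -> np.ndarray:
    """Word length in characters, the standard missingness covariate."""
    return np.array([len(w) for w in words], dtype=float)
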