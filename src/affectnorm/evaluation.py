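"""Accuracy and psychometric evaluation statistics.

Covers: Pearson accuracy, the aleatoric noise ceiling (the best correlation
any predictor can reach against noisy mean ratings, given rater counts and
judgment variance), correction for attenuation, the out-of-distribution
percentage accuracy drop 1 - r2/r1, a missing-not-at-random (MNAR)
robustness harness that trains under covariate-restricted selection and
compares matched test sets, the familiarity-accuracy curve, per-participant
test-retest reliability, and gender-balanced mean ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import NormLexicon, EmbeddingLexicon, SplitSpec
from .model import ModelBundle
from .training import TrainingConfig, train_model

__all__ = [
    "CeilingEstimate",
    "RobustnessReport",
    "pearson_r",
    "accuracy_drop",
    "noise_ceiling",
    "attenuation_correct",
    "mnar_harness",
    "familiarity_curve",
    "rater_reliability",
    "filter_reliable_participants",
    "gender_balanced_means",
]


class ConstantInputError(ValueError):
    """Correlation is undefined because one input has zero variance."""


def pearson_r(x, y) -> float:
    """Sample Pearson correlation between two equal-length vectors.

    Raises :class:`ConstantInputError` when either vector is constant (or
    shorter than 2), where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 2:
        raise ConstantInputError("need at least two observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def accuracy_drop(r1: float, r2: float) -> float:
    """Percentage change 1 - r2/r1 between an original correlation ``r1``
    and an experimental correlation ``r2`` (as a fraction, 0.11 = 11%)."""
    r1, r2 = float(r1), float(r2)
    if r1 == 0.0:
        raise ZeroDivisionError("accuracy_drop undefined for r1 = 0")
    return 1.0 - r2 / r1


@dataclass(frozen=True)
class CeilingEstimate:
    """The noise ceiling for one metric.

    ``ceiling_r = sqrt(max(0, 1 - mean_se2 / observed_var))`` — the expected
    correlation between the (unobservable) true word scores and the noisy
    observed means, i.e. what a perfect estimator could attain.
    """

    metric: str
    observed_var: float
    mean_se2: float
    ceiling_r: float


def noise_ceiling(sds, n_raters, means, metric: str = "") -> CeilingEstimate:
    """Aleatoric limit on prediction performance for one metric.

    Each word's mean rating carries sampling noise with squared standard
    error ``sd_i^2 / n_i``. Disattenuating the ideal correlation gives
    ``sqrt(1 - mean(se^2) / Var(observed means))``, floored at 0.
    """
    sds = np.asarray(sds, dtype=float)
    n = np.asarray(n_raters, dtype=float)
    means = np.asarray(means, dtype=float)
    if sds.shape != means.shape or (n.shape not in (means.shape, ())):
        raise ValueError("sds, n_raters, means must align")
    if means.size < 2:
        raise ValueError("need at least two words")
    if np.any(n < 1):
        raise ValueError("rater counts must be >= 1")
    observed_var = float(np.var(means, ddof=1))
    if observed_var == 0.0:
        raise ConstantInputError("observed means are constant; ceiling undefined")
    mean_se2 = float(np.mean(sds**2 / n))
    ceiling = float(np.sqrt(max(0.0, 1.0 - mean_se2 / observed_var)))
    return CeilingEstimate(
        metric=metric, observed_var=observed_var, mean_se2=mean_se2,
        ceiling_r=ceiling,
    )


def attenuation_correct(r: float, reliability: float) -> float:
    """Classical correction for attenuation: ``r / sqrt(reliability)``.

    Values that exceed 1 in magnitude (possible when the reliability
    estimate is too low) are clamped to [-1, 1] with a warning.
    """
    r, reliability = float(r), float(reliability)
    if reliability <= 0.0:
        raise ValueError("reliability must be positive")
    out = r / np.sqrt(reliability)
    if abs(out) > 1.0:
        warnings.warn(
            f"attenuation-corrected r = {out:.4f} exceeds 1 in magnitude; "
            "clamping", stacklevel=2,
        )
        out = float(np.clip(out, -1.0, 1.0))
    return float(out)


@dataclass(frozen=True)
class RobustnessReport:
    """Result of the covariate-restricted (MNAR) robustness check."""

    covariate: str
    threshold: float
    metrics: tuple[str, ...]
    r_original: dict
    r_random_test: dict
    r_abstract_test: dict
    n_train: int
    n_random_test: int
    n_abstract_test: int


def _length_matched_sample(
    target_words: list[str],
    pool: list[str],
    rng: np.random.Generator,
) -> list[str]:
    """Greedy per-length matching: for each target word draw an unused pool
    word of the same length; lengths lacking a partner fall back to the
    nearest available length."""
    by_len: dict[int, list[str]] = {}
    for w in pool:
        by_len.setdefault(len(w), []).append(w)
    for bucket in by_len.values():
        rng.shuffle(bucket)
    out: list[str] = []
    for w in target_words:
        want = len(w)
        lengths = [L for L, b in by_len.items() if b]
        if not lengths:
            break
        pick = min(lengths, key=lambda L: (abs(L - want), L))
        out.append(by_len[pick].pop())
    return out


def mnar_harness(
    norms: NormLexicon,
    embeddings: EmbeddingLexicon,
    covariate: str,
    threshold: float,
    cfg: TrainingConfig,
    seed: int,
    metrics: list[str] | None = None,
    val_fraction: float = 0.1,
    abstract_test_fraction: float = 0.5,
) -> RobustnessReport:
    """Train under covariate-restricted selection and measure the
    out-of-distribution accuracy gap.

    The restricted model is trained only on words whose ``covariate`` rating
    exceeds ``threshold`` (e.g. the concrete half of the lexicon) and
    evaluated on (a) a seeded sample of the words below the threshold (the
    "abstract" test set, ``abstract_test_fraction`` of that side) and (b) a
    seeded random test set drawn from the above-threshold pool, matched to
    (a) on word-length distribution and size; neither test set intersects
    the training words. ``r_original`` comes from a reference model trained
    without the covariate restriction (on all rated words excluding both
    test sets, so it does see below-threshold words) and evaluated on test
    set (b).
    """
    cov = norms.metric_values(covariate)
    if np.all(np.isnan(cov)):
        raise ValueError(f"covariate {covariate!r} has no ratings")
    words = np.array(norms.words)
    rated = np.isfinite(cov)
    abstract_all = [w for w, c, ok in zip(words, cov, rated) if ok and c < threshold]
    concrete = [w for w, c, ok in zip(words, cov, rated) if ok and c > threshold]
    if not abstract_all:
        raise ValueError("no words below the covariate threshold")
    if not concrete:
        raise ValueError("no words above the covariate threshold")

    rng = np.random.default_rng(seed)
    n_abs = max(2, int(round(len(abstract_all) * abstract_test_fraction)))
    abstract = list(rng.choice(abstract_all, size=min(n_abs, len(abstract_all)),
                               replace=False))
    random_test = _length_matched_sample(abstract, concrete, rng)
    reserved = set(abstract) | set(random_test)

    metrics = metrics or [m for m in norms.metrics if m != covariate]

    def fit(train_pool: list[str]) -> ModelBundle:
        pool = list(train_pool)
        rng_split = np.random.default_rng(seed + 1)
        order = rng_split.permutation(len(pool))
        pool = [pool[i] for i in order]
        n_val = max(2, int(round(len(pool) * val_fraction)))
        split = SplitSpec(
            train_words=tuple(pool[n_val:]),
            val_words=tuple(pool[:n_val]),
            test_words=(),
            seed=seed,
        )
        bundle = ModelBundle.initialize(
            metrics, embeddings.dim, hidden=cfg.hidden,
            dropout_p=cfg.dropout_p, seed=cfg.seed,
        )
        fitted, _ = train_model(bundle, embeddings, norms, split, cfg)
        return fitted

    restricted_train = [w for w in concrete if w not in set(random_test)]
    restricted = fit(restricted_train)
    unrestricted_train = [w for w in words[rated] if w not in reserved]
    reference = fit(unrestricted_train)

    def score(bundle: ModelBundle, test_words: list[str]) -> dict:
        X = embeddings.matrix(test_words)
        out = {}
        for m in metrics:
            y = norms.metric_values(m)[[norms.index(w) for w in test_words]]
            mask = np.isfinite(y)
            preds = bundle.predict_all(X[mask])[m] if mask.any() else np.array([])
            try:
                out[m] = pearson_r(preds, y[mask])
            except ConstantInputError:
                out[m] = float("nan")
        return out

    train_set = set(restricted_train) - set(abstract)
    assert not (set(abstract) & train_set) and not (set(random_test) & train_set)
    return RobustnessReport(
        covariate=covariate,
        threshold=float(threshold),
        metrics=tuple(metrics),
        r_original=score(reference, random_test),
        r_random_test=score(restricted, random_test),
        r_abstract_test=score(restricted, abstract),
        n_train=len(restricted_train),
        n_random_test=len(random_test),
        n_abstract_test=len(abstract),
    )


def familiarity_curve(
    norms: NormLexicon,
    predictions: np.ndarray,
    thresholds,
    metric: str,
) -> pd.DataFrame:
    """Accuracy as a function of the proportion of participants who knew
    the word.

    For each threshold p, restricts to words with ``known_prop >= p`` and
    reports the word count and the Pearson correlation between
    ``predictions`` (aligned with ``norms.words``) and the observed means.
    A threshold leaving fewer than 3 words yields ``r = NaN``.
    """
    if norms.known_prop is None:
        raise ValueError("lexicon has no known_prop field")
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(norms),):
        raise ValueError("predictions must align with lexicon words")
    y = norms.metric_values(metric)
    rows = []
    for p in thresholds:
        mask = (norms.known_prop >= p) & np.isfinite(y) & np.isfinite(predictions)
        n = int(mask.sum())
        if n < 3:
            rows.append({"threshold": float(p), "n_words": n, "r": float("nan")})
            continue
        try:
            r = pearson_r(predictions[mask], y[mask])
        except ConstantInputError:
            r = float("nan")
        rows.append({"threshold": float(p), "n_words": n, "r": r})
    return pd.DataFrame(rows)


def rater_reliability(records: pd.DataFrame) -> float:
    """Test-retest reliability for one participant.

    ``records`` holds that participant's ratings with columns ``word``,
    ``dimension``, ``rating`` and ``presentation`` (1 for the first showing,
    2 for the repeat). The statistic is the Pearson correlation between
    first- and repeat-presentation ratings over the participant's repeated
    words, pooled across the dimensions they rated. Constant ratings make
    the statistic undefined (:class:`ConstantInputError`); such participants
    should be flagged for manual review, not silently kept.
    """
    first = records[records["presentation"] == 1]
    second = records[records["presentation"] == 2]
    merged = first.merge(second, on=["word", "dimension"], suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError("need at least two repeated words")
    return pearson_r(merged["rating_1"].to_numpy(), merged["rating_2"].to_numpy())


def filter_reliable_participants(
    records: pd.DataFrame, threshold: float = 0.8
) -> tuple[list, list]:
    """Split participant ids into (kept, flagged_for_review).

    Kept = reliability >= threshold (exclusion is strictly below the
    threshold; equality keeps). Participants whose reliability is undefined
    (constant ratings) are flagged rather than auto-kept.
    """
    kept, flagged = [], []
    for pid, sub in records.groupby("participant", sort=True):
        try:
            rel = rater_reliability(sub)
        except (ConstantInputError, ValueError):
            flagged.append(pid)
            continue
        (kept if rel >= threshold else flagged).append(pid)
    return kept, flagged


def gender_balanced_means(
    records: pd.DataFrame, word: str, dimension: str
) -> float:
    """Mean rating for one word/dimension, balanced over gender groups.

    Computes each gender group's mean rating and averages the group means,
    so an imbalanced participant sample does not tilt the word mean. Groups
    with no rating for the word are skipped.
    """
    mask = (records["word"] == word) & (records["dimension"] == dimension)
    if "presentation" in records.columns:
        mask &= records["presentation"] == 1
    sub = records[mask]
    if sub.empty:
        raise ValueError(f"no ratings for word {word!r} on {dimension!r}")
    group_means = sub.groupby("gender")["rating"].mean()
    return float(group_means.mean())
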