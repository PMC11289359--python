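"""Shared fixtures: small synthetic worlds and trained bundles.

Heavier fixtures are session-scoped so several test modules can share one
training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from affectnorm import (
    ModelBundle,
    SyntheticWorldConfig,
    TrainingConfig,
    fit_gaussian_prior,
    make_embedding_space,
    make_true_norms,
    simulate_raters,
    split_lexicon,
    train_model,
)
from affectnorm.synthetic import MetricSpec


def fast_config(**overrides) -> TrainingConfig:
    """Training settings sized for the small synthetic worlds used in tests."""
    base = dict(
        learning_rate=0.01,
        epochs=60,
        warmup_steps=40,
        batch_size=32,
        weight_decay=0.0,
        dropout_p=0.0,
        seed=0,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    """300-word, 8-dim world with rater noise; norms on [0, 1]."""
    cfg = SyntheticWorldConfig(vocab_size=300, dim=8, seed=3)
    emb = make_embedding_space(cfg)
    truth = make_true_norms(emb, cfg)
    norms = simulate_raters(truth, cfg)
    return cfg, emb, truth, norms


@pytest.fixture(scope="session")
def trained_small(small_world):
    cfg, emb, truth, norms = small_world
    split = split_lexicon(norms, [0.8, 0.1, 0.1], seed=1)
    tc = fast_config()
    bundle = ModelBundle.initialize(list(norms.metrics), emb.dim, seed=0)
    fitted, history = train_model(bundle, emb, norms, split, tc)
    return fitted, history, split


@pytest.fixture(scope="session")
def descent_world():
    """Noiseless two-metric world with a trained bundle and Gaussian prior,
    dense enough for the matched-stimulus search to succeed."""
    cfg = SyntheticWorldConfig(
        vocab_size=800,
        dim=8,
        n_clusters=1,
        cluster_spread=1.0,
        metrics=(
            MetricSpec("valence", noise_sd=0.0),
            MetricSpec("arousal", noise_sd=0.0),
        ),
        seed=5,
    )
    emb = make_embedding_space(cfg)
    truth = make_true_norms(emb, cfg)
    norms = simulate_raters(truth, cfg)
    split = split_lexicon(norms, [0.9, 0.1], seed=1)
    tc = fast_config(epochs=80, warmup_steps=50)
    bundle = ModelBundle.initialize(list(norms.metrics), emb.dim, seed=0)
    fitted, _ = train_model(bundle, emb, norms, split, tc)
    prior = fit_gaussian_prior(emb)
    return cfg, emb, norms, fitted, prior
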