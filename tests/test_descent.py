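"""Controlled gradient descent, the Gaussian prior, projection, matching."""

from dataclasses import replace

import numpy as np
import pytest

from affectnorm import (
    DescentConfig,
    GaussianPrior,
    ModelBundle,
    controlled_projection,
    cosine_similarity,
    descent_step,
    find_match,
    fit_gaussian_prior,
    log_density_penalty,
    match_levels,
    nearest_words,
    select_seed_words,
)
from affectnorm.descent import FAILURE_MARKER, penalty_gradient
from affectnorm.lexicon import EmbeddingLexicon, NormLexicon
from affectnorm.model import RegressionHead, predict


class TestGaussianPrior:
    def test_two_point_hand_calculation(self):
        emb = EmbeddingLexicon(words=("a", "b"),
                               vectors=np.array([[0.0, 0.0], [2.0, 0.0]]))
        prior = fit_gaussian_prior(emb, ridge_frac=1e-3)
        np.testing.assert_array_equal(prior.mu, [1.0, 0.0])
        ridge = 1e-3 * 2.0 / 2  # trace(cov)=2 (sample var of {0,2} is 2)
        np.testing.assert_allclose(
            prior.sigma, np.array([[2.0, 0.0], [0.0, 0.0]]) + ridge * np.eye(2)
        )

    def test_identical_points_fall_back_to_pure_ridge(self):
        emb = EmbeddingLexicon(words=("a", "b", "c"), vectors=np.ones((3, 4)))
        prior = fit_gaussian_prior(emb, ridge_frac=1e-3)
        np.testing.assert_allclose(prior.sigma, 1e-3 * np.eye(4))

    def test_recovers_generator_mean_on_gaussian_cloud(self):
        rng = np.random.default_rng(0)
        true_mu = np.array([1.0, -2.0, 0.5])
        X = true_mu + rng.standard_normal((5000, 3))
        emb = EmbeddingLexicon(
            words=tuple(f"w{i}" for i in range(5000)), vectors=X
        )
        prior = fit_gaussian_prior(emb)
        se = 1.0 / np.sqrt(5000)
        assert np.all(np.abs(prior.mu - true_mu) < 3 * se)

    def test_requires_two_words(self):
        emb = EmbeddingLexicon(words=("solo",), vectors=np.ones((1, 3)))
        with pytest.raises(ValueError):
            fit_gaussian_prior(emb)


class TestLogDensityPenalty:
    def unit_prior(self, d=1):
        return GaussianPrior(mu=np.zeros(d), sigma=np.eye(d), ridge=0.0)

    def test_zero_at_the_mean(self):
        assert log_density_penalty(np.zeros(3), self.unit_prior(3)) == 0.0

    def test_one_dimensional_value(self):
        assert log_density_penalty(np.array([2.0]), self.unit_prior()) == 2.0

    def test_monotone_along_any_ray(self):
        prior = GaussianPrior(
            mu=np.array([1.0, 0.0]),
            sigma=np.array([[2.0, 0.3], [0.3, 1.0]]),
            ridge=0.0,
        )
        ray = np.array([0.7, -0.7])
        vals = [log_density_penalty(prior.mu + t * ray, prior)
                for t in np.linspace(0, 3, 10)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_gradient_matches_finite_difference(self):
        prior = GaussianPrior(
            mu=np.array([0.5, -0.5]),
            sigma=np.array([[1.5, 0.2], [0.2, 0.8]]),
            ridge=0.0,
        )
        x = np.array([1.3, 0.4])
        g = penalty_gradient(x, prior)
        eps = 1e-6
        fd = np.array([
            (log_density_penalty(x + eps * e, prior)
             - log_density_penalty(x - eps * e, prior)) / (2 * eps)
            for e in np.eye(2)
        ])
        np.testing.assert_allclose(g, fd, atol=1e-6)


class TestControlledProjection:
    def test_no_controls_is_identity(self):
        g = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(controlled_projection(g, []), g)

    def test_two_dimensional_orthogonal_complement(self):
        out = controlled_projection(np.array([1.0, 1.0]), [np.array([1.0, 0.0])])
        np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)

    def test_parallel_control_annihilates(self):
        g = np.array([2.0, -4.0, 6.0])
        out = controlled_projection(g, [0.5 * g])
        np.testing.assert_allclose(out, np.zeros(3), atol=1e-12)

    def test_orthogonality_over_many_random_cases(self):
        """Projected gradient is orthogonal to every control gradient."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            d = int(rng.integers(2, 12))
            k = int(rng.integers(1, min(d, 4) + 1))
            g = rng.normal(size=d)
            controls = [rng.normal(size=d) for _ in range(k)]
            out = controlled_projection(g, controls)
            for c in controls:
                bound = 1e-8 * max(np.linalg.norm(g) * np.linalg.norm(c), 1e-12)
                assert abs(out @ c) <= bound

    def test_degenerate_near_zero_controls_dropped(self):
        g = np.array([1.0, 1.0])
        out = controlled_projection(g, [np.zeros(2), np.array([1e-15, 0.0])])
        np.testing.assert_array_equal(out, g)


class TestCosineAndNeighbors:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0], [0, 1], 0.0),
            ([1, 1], [2, 2], 1.0),
            ([1, 0], [1, 1], 0.7071),
        ],
    )
    def test_cosine_values(self, a, b, expected):
        assert cosine_similarity(np.array(a, float),
                                 np.array(b, float)) == pytest.approx(expected,
                                                                      abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(2), np.ones(2))

    @pytest.fixture()
    def toy_emb(self):
        return EmbeddingLexicon(
            words=("east", "north", "northeast", "south"),
            vectors=np.array([[1, 0], [0, 1], [1, 1], [0, -1]], dtype=float),
        )

    def test_exact_vector_ranks_first(self, toy_emb):
        out = nearest_words(np.array([1.0, 0.0]), toy_emb, k=2)
        assert out[0] == ("east", pytest.approx(1.0))

    def test_k_larger_than_vocabulary(self, toy_emb):
        assert len(nearest_words(np.array([1.0, 0.5]), toy_emb, k=99)) == 4

    def test_exclusion_promotes_runner_up(self, toy_emb):
        out = nearest_words(np.array([1.0, 0.0]), toy_emb, k=1,
                            exclude={"east"})
        assert out[0][0] == "northeast"

    def test_empty_vocabulary_after_exclusion(self, toy_emb):
        with pytest.raises(ValueError):
            nearest_words(np.ones(2), toy_emb, k=1, exclude=set(toy_emb.words))


class TestDescentStep:
    def constant_bundle(self, d=4):
        head = RegressionHead(
            metric="valence", W1=np.eye(d), b1=np.zeros(d),
            ln_gamma=np.ones(d), ln_beta=np.zeros(d), w2=np.zeros(d), b2=0.0,
        )
        return ModelBundle(heads={"valence": head})

    def test_stationary_point_does_not_move(self):
        bundle = self.constant_bundle()
        prior = GaussianPrior(mu=np.zeros(4), sigma=np.eye(4), ridge=0.0)
        cfg = DescentConfig(target_metric="valence", lambda_reg=0.0,
                            step_size=0.1)
        x = np.array([0.3, -0.2, 0.1, 0.0])
        np.testing.assert_array_equal(
            descent_step(x, bundle, prior, cfg), x
        )

    def test_unregularized_step_increases_prediction(self, descent_world):
        _, emb, _, fitted, prior = descent_world
        cfg = DescentConfig(target_metric="valence", sign=1, lambda_reg=0.0,
                            step_size=0.01)
        x = emb.vectors[17]
        x1 = descent_step(x, fitted, prior, cfg)
        assert predict(fitted.heads["valence"], x1) > \
            predict(fitted.heads["valence"], x)

    def test_controlled_metric_drift_is_second_order(self, descent_world):
        _, emb, _, fitted, prior = descent_world
        cfg = DescentConfig(
            target_metric="valence", sign=1, lambda_reg=0.0,
            controlled_metrics=("arousal",), step_size=1e-3,
        )
        head_a = fitted.heads["arousal"]
        for i in (3, 50, 200):
            x = emb.vectors[i]
            x1 = descent_step(x, fitted, prior, cfg)
            drift = abs(predict(head_a, x1) - predict(head_a, x))
            assert drift < 1e-5  # O(step^2) on a smooth head


class TestFindMatch:
    def cfg(self, **kw):
        base = dict(
            target_metric="valence", sign=1, delta_min_r=0.15,
            controlled_metrics=("arousal",), control_tolerance=0.08,
            cosine_floor=0.3, max_steps=150,
        )
        base.update(kw)
        return DescentConfig(**base)

    def test_success_satisfies_all_constraints(self, descent_world):
        _, emb, norms, fitted, prior = descent_world
        cfg = self.cfg()
        seeds = select_seed_words(norms, "valence", 1.0, 5)
        successes = 0
        for w in seeds:
            res = find_match(w, fitted, emb, prior, cfg)
            if not res.success:
                continue
            successes += 1
            # post-hoc re-verification by direct prediction
            head = fitted.heads["valence"]
            delta = predict(head, emb.vector(res.matched_word)) - \
                predict(head, emb.vector(w))
            assert delta >= cfg.delta_min_r - 1e-12
            assert res.cosine >= cfg.cosine_floor
            assert all(abs(d) <= cfg.control_tolerance
                       for d in res.control_drifts.values())
            assert res.delta_r == pytest.approx(delta)
        assert successes >= 3

    def test_unreachable_delta_returns_failure_marker(self, descent_world):
        _, emb, norms, fitted, prior = descent_world
        res = find_match(norms.words[0], fitted, emb, prior,
                         self.cfg(delta_min_r=0.99, max_steps=20))
        assert not res.success
        assert res.matched_label == FAILURE_MARKER

    def test_deterministic(self, descent_world):
        _, emb, norms, fitted, prior = descent_world
        cfg = self.cfg()
        w = select_seed_words(norms, "valence", 1.0, 1)[0]
        a = find_match(w, fitted, emb, prior, cfg)
        b = find_match(w, fitted, emb, prior, cfg)
        assert a == b

    def test_unknown_seed_word(self, descent_world):
        _, emb, _, fitted, prior = descent_world
        with pytest.raises(KeyError):
            find_match("notaword", fitted, emb, prior, self.cfg())

    def test_multi_level_matches_are_distinct(self, descent_world):
        _, emb, norms, fitted, prior = descent_world
        cfg = self.cfg(delta_min_r=0.1)
        w = select_seed_words(norms, "valence", 1.0, 2)[0]
        levels = match_levels(w, fitted, emb, prior, cfg, n_levels=2)
        assert len(levels) == 2
        found = [r.matched_word for r in levels if r.success]
        assert len(found) == len(set(found))
        if levels[1].success:
            assert levels[1].delta_r >= 2 * cfg.delta_min_r - 1e-12

    def test_trajectory_stays_in_plausible_region(self, descent_world):
        """With the Gaussian regularizer on, the descent trajectory's
        Mahalanobis distance stays bounded."""
        _, emb, norms, fitted, prior = descent_world
        cfg = self.cfg(lambda_reg=0.05, max_steps=200, delta_min_r=0.99)
        x = emb.vector(norms.words[3])
        start_pen = log_density_penalty(x, prior)
        step = 0.1 * float(np.mean(emb.vectors.std(axis=0)))
        for _ in range(cfg.max_steps):
            x = descent_step(x, fitted, prior, cfg, step_size=step)
        assert np.all(np.isfinite(x))
        assert log_density_penalty(x, prior) < start_pen + 50.0


class TestSelectSeedWords:
    def lexicon(self, values):
        return NormLexicon(
            words=tuple(f"w{i}" for i in range(len(values))),
            metrics=("valence",),
            means=np.asarray(values, dtype=float)[:, None],
        )

    def test_hand_picked_extremes(self):
        # ratings 0.1, 0.5, 0.9: mean 0.5, sd 0.4 -> z=1 targets 0.9 / 0.1
        lex = self.lexicon([0.1, 0.5, 0.9])
        picked = select_seed_words(lex, "valence", 1.0, 1)
        assert set(picked) == {"w0", "w2"}

    def test_zero_offset_picks_words_nearest_the_mean(self):
        lex = self.lexicon([0.0, 0.45, 0.5, 0.55, 1.0])
        picked = select_seed_words(lex, "valence", 0.0, 2)
        # both targets collapse to the mean (0.5); the four nearest words
        # win, with the 0.0/1.0 tie going alphabetically to w0
        assert len(picked) == 4 and len(set(picked)) == 4
        assert set(picked) == {"w1", "w2", "w3", "w0"}

    def test_insufficient_words(self):
        with pytest.raises(ValueError):
            select_seed_words(self.lexicon([0.1, 0.9]), "valence", 1.0, 2)
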