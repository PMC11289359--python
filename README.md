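# affectnorm

Affective and lexical-semantic *norms* — per-word mean human ratings of
valence, arousal, dominance, concreteness, age of acquisition and similar
dimensions, typically collected on 9-point scales — exist for only a few
thousand words per language. `affectnorm` is a toolkit for researchers in
psycholinguistics and affective science who want to

1. **extrapolate** norms to unrated words by regressing them on word
   embeddings,
2. **evaluate** such extrapolations honestly — against the aleatoric noise
   ceiling set by rater noise, under attenuation, and under the
   *missing-not-at-random* selection bias that inflates cross-validated
   accuracy, and
3. **generate matched word stimuli** for experiments: given a seed word,
   find a semantically close word whose predicted rating on one dimension
   differs by at least a chosen margin while other dimensions stay level.

Everything runs end to end on a bundled synthetic word-world with known
ground truth, so no external corpus, norm database or pretrained encoder is
required.

## The model

Each metric *m* gets its own regression head over a fixed d-dimensional
embedding space:

```
ŷ_m(x) = σ( w₂ᵀ · LayerNorm(W₁ x + b₁) + b₂ )
```

a dense layer, layer normalization, a scalar output layer, and a sigmoid
that pins predictions to the normalized (0, 1) rating scale. Heads are
trained jointly by mini-batch AdamW (decoupled weight decay, amsgrad) with
a learning-rate multiplier that ramps linearly over the first warm-up steps
and decays linearly to zero, and early stopping keeps the parameters of the
epoch with the best mean validation Pearson r. Gradients are analytic in
both the parameters and the *input embedding* — the latter powers the
stimulus search.

**Stimuli descent.** To match stimuli, the search iterates

```
x ← x − η · P( ∇ₓ[ −s·ŷ_target(x) + λ·½(x−μ)ᵀΣ⁻¹(x−μ) ] )
```

where `s = ±1` picks the direction of manipulation, the quadratic term is a
Gaussian prior fitted to the embedding cloud (keeping the search where
words actually live), and `P` projects out the gradients of the controlled
metrics ("controlled gradients") so their predictions stay approximately
constant. After each step, nearby vocabulary words (by cosine similarity)
are tested against three constraints — rating difference ≥ Δ_min r, cosine
similarity to the seed ≥ a floor, controlled drifts within tolerance — and
the first word satisfying all of them is returned. No match yields an
explicit `X` marker, never a silent best guess.

**Key psychometric statistics.**

- noise ceiling: `r_max = √(1 − mean(sd²/n) / Var(observed means))`, the
  correlation a perfect predictor could reach against noisy mean ratings;
- attenuation correction: `r / √reliability`;
- out-of-distribution accuracy drop: `1 − r₂/r₁`;
- an MNAR robustness harness that trains under covariate-restricted
  selection (e.g. concrete words only) and compares accuracy on the
  held-out stratum against a length-matched random test set.

## Worked example

Simulate a 600-word world, train, evaluate, and search for matched stimuli:

```sh
affectnorm simulate --config config.yaml --out world
affectnorm train --norms world/norms.csv --embeddings world/embeddings.txt \
    --config config.yaml --ratios 0.8,0.1,0.1 --out run
# -> best epoch 90: mean validation r = 0.9950
affectnorm evaluate --model run/model.json --norms world/norms.csv \
    --embeddings world/embeddings.txt --split run/split.tsv --out eval
```

prints, per metric, the test-set correlation and the noise ceiling implied
by the simulated raters (60 test words):

```
"arousal": { "n": 60, "r": 0.99, "r_full": 0.9941, "noise_ceiling": 0.9992 }
```

so the trained head sits ~0.005 below the best any predictor could do given
the rating noise. Then

```sh
affectnorm descend --model run/model.json --embeddings world/embeddings.txt \
    --norms world/norms.csv --auto-select --n-per-side 3 \
    --target valence --control arousal --delta-min-r 0.15 --out desc
# -> matched 9/12 level slots across 6 seed words
```

writes a match table (`level_1` requires Δr ≥ 0.15, `level_2` Δr ≥ 0.30,
`X` = no qualifying word):

```
seed      level_1    level_2
qsaqiry   uurri      X
mznp      afwizvgx   X
```

plus a JSON diagnostics file with the achieved Δr, cosine similarity and
controlled-metric drifts for every search. The library API
(`affectnorm.train_model`, `affectnorm.find_match`, …) exposes the same
functionality programmatically.

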