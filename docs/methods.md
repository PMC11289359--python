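# Methods

## Scope

`affectnorm` implements norm extrapolation by per-metric regression heads
over a fixed word-embedding space, the psychometric statistics needed to
evaluate such models honestly, and a controlled-gradient-descent search for
semantically matched word stimuli. Embeddings are treated as fixed inputs:
any encoder that yields one vector per word can feed the pipeline through
the `EmbeddingLexicon` interface (word2vec text format or headerless TSV).
Training the encoder itself is deliberately out of scope; the trainable
core is the regression head.

## Data model and normalization

A `NormLexicon` stores per-word mean ratings for one or more metrics,
optionally with rating SDs, rater counts and the proportion of participants
who knew the word. Ratings are normalized from their declared scale
(e.g. 1–9) to [0, 1] by `(x − min)/(max − min)`; SDs divide by the scale
width. Normalization uses the *declared* endpoints, not the empirical
min/max (an empirical mode exists for tables whose scale is unknown),
because the declared scale is what raters saw and what the sigmoid output
range should correspond to. Words are compared case-sensitively after
Unicode NFC normalization; duplicate words are a hard error since a silent
last-wins rule would corrupt splits.

Splits: the test set can be an explicit holdout list (holdout-by-exclusion,
as when an external reference corpus serves as test set) or a ratio.
Validation/test sizes are round-half-up of N·ratio and the training set
absorbs the remainder; with 12 885 words at 9:1 the validation set is
round(1288.5) = 1289. All shuffling is seeded and byte-reproducible.

## The regression head

`ŷ = σ(w₂ᵀ·LN(W₁x + b₁) + b₂)` with layer-norm epsilon 1e-5 inside the
variance denominator and population (ddof 0) variance per forward pass.
Dropout (inverted scaling) is applied to the layer-norm output and only in
training mode; inference is deterministic. The hidden width defaults to
the embedding dimension. Initialization is Glorot-uniform from a seeded
generator, with unit layer-norm gain, zero shifts and biases. The loss is
mean squared error — the natural choice for bounded regression through a
sigmoid — and a batch's loss is the mean over its word–metric pairs.

Backpropagation is written out analytically (sigmoid → dense → layer-norm
→ dense), for the parameters and for the input embedding. The input
gradient is validated against central finite differences (relative error
< 1e-4 over 100 seeded heads) in the test suite; the sign argument flips
it exactly.

## Training regime

AdamW with decoupled weight decay:
`θ ← θ − lr·mult·(m̂/(√v̂ + ε) + wd·θ)`, with bias-corrected moments and,
under amsgrad, the running elementwise maximum of the corrected second
moment in the denominator. Defaults follow the reference regime for
full-size corpora: lr 5e-5, ε 1e-8, weight decay 0.3, betas (0.9, 0.999),
amsgrad on, dropout 0.1, up to 1000 epochs, 600 warm-up steps. A "learning
step" is one mini-batch update (batch size 32 by default); the multiplier
ramps linearly from 0 to exactly 1 at the warm-up boundary and decays
linearly to 0 at `epochs × batches-per-epoch`, the total computed up
front. In very short runs the warm-up is clamped to the actual step budget
so the schedule stays well defined.

All heads train jointly on the summed per-metric loss; a word lacking a
metric contributes no loss for that head. Early stopping is implemented by
checkpointing: every epoch the per-metric Pearson r on the validation
words is computed, and the returned model is the snapshot of the epoch
with the highest *unweighted mean* r (the aggregate is a design choice;
the per-metric values are all recorded in the history). An undefined
validation correlation (constant predictions or fewer than two words) is
recorded as 0 with a warning, never an exception mid-run. Identical
config and seed reproduce the history bit for bit.

The desk-scale experiments in the test suite and `scripts/acceptance.py`
train small heads on worlds of 300–1000 words; those runs use an explicit
config (lr 0.01–0.02, 60–300 epochs, no weight decay or dropout) sized so
each training finishes in seconds while reaching the worlds' noise
ceilings. The full-corpus defaults would converge too slowly for heads
this small; this is a property of the problem size, and the configs are
part of the experiment definitions.

## Evaluation statistics

**Noise ceiling.** Each observed word mean carries sampling noise with
squared standard error `sd²/n`. A perfect predictor of the true scores
correlates with the noisy means at
`√(1 − mean(se²)/Var(observed means))` (floored at 0); the derivation is
the usual attenuation identity `corr(T, T+e) = √(σ_T²/(σ_T²+σ_e²))` with
`Var(observed) = σ_T² + mean(se²)`. The formula is validated against a
Monte-Carlo perfect-estimator simulation (2000 words, 10 seeds, agreement
within ±0.02).

**Attenuation correction** is `r/√reliability`, clamped to [−1, 1] with a
warning when the reliability estimate is too low to be consistent with r.

**Accuracy drop** is the percentage change `1 − r₂/r₁`. Applied to the
five published validation-study pairs it reproduces the 11% average drop;
applied to the concreteness-restriction table it gives the 0.15 (age of
acquisition) and 0.09 (arousal) correlation drops. These are recomputed
arithmetic, not asserted constants.

**MNAR harness.** To measure selection-bias sensitivity the harness trains
only on words whose covariate rating exceeds a threshold and evaluates on
(a) a seeded sample of the below-threshold stratum and (b) a random test
set from the above-threshold pool, greedily matched to (a) on word-length
distribution (lengths without a partner fall back to the nearest length)
and equal in size. Half of the below-threshold stratum is sampled for (a)
so that a reference model trained *without* the restriction (on everything
outside both test sets) still sees below-threshold words; its accuracy on
(b) is reported as `r_original`. Neither test set intersects any training
words. The covariate threshold for a "center of the distribution" split is
0.5 on the normalized scale.

**Reliability and rating records.** Per-participant test–retest
reliability is the Pearson r between first- and repeat-presentation
ratings over that participant's repeated words, pooled over their
dimensions. Exclusion is strictly below the threshold (0.8 by default);
participants with undefined reliability (constant ratings) are flagged for
review rather than auto-kept. Word means can be computed gender-balanced:
the mean of the per-gender mean ratings, skipping genders with no rating
for the word.

**Familiarity curve.** For each threshold p, accuracy is recomputed on the
words known by at least proportion p of participants; thresholds leaving
fewer than 3 words are reported as undefined rather than dropped.

## Stimuli descent

The search objective is `−s·ŷ_target(x) + λ·½(x−μ)ᵀΣ⁻¹(x−μ)` where the
Gaussian prior (mean and ridged sample covariance of the embedding cloud,
ridge = 1e-3·trace(cov)/d, falling back to the ridge fraction itself for a
degenerate cloud) penalizes leaving the region where words occur and model
predictions are supported. The gradients of the controlled metrics are
orthonormalized by modified Gram–Schmidt (near-zero vectors below 1e-12
dropped) and their components removed from the objective gradient; the
result is orthogonal to every control gradient to ~1e-8 scaled.

Steps move a fixed spatial distance along the *normalized* projected
gradient (default 0.1 × the mean per-coordinate SD of the embedding
cloud). Normalizing matters: near sigmoid saturation the raw gradient is
vanishingly small and unnormalized descent stalls precisely at the extreme
seed words one most wants to manipulate. A zero projected gradient is a
stationary point and leaves the position unchanged.

After every step the nearest vocabulary words by cosine similarity are
scanned (60 candidates per step by default; each word is evaluated at most
once per search). A candidate matches when (i) its predicted target-metric
difference from the seed, in the manipulated direction, is at least
Δ_min r; (ii) its cosine similarity *to the seed embedding* is at least
the floor (0.4 by default); and (iii) every controlled metric's predicted
drift is within tolerance (0.05 by default). Searches are deterministic;
failures return an explicit marker plus the best rating difference seen
among cosine-eligible candidates. Multi-level matching (e.g. medium/high
manipulations) runs sequential searches with cumulative exclusion and a
level-i requirement of i·Δ_min r.

Seed words can be picked from ratings alone: the n words nearest
mean + z·SD and the n nearest mean − z·SD (alphabetical tie-break),
with conventional offsets z = 1.0 for valence and 1.5 for arousal.

On dense synthetic worlds the search is verified against a brute-force
scan of the entire vocabulary: it succeeds exactly when a
constraint-satisfying word exists, and every returned match re-verifies by
direct prediction. On sparse real vocabularies a feasible word far off the
control-respecting path may still be missed — the brute-force scan is the
oracle, not the product, because it cannot rank by semantic-path proximity
and does not generalize to checking intermediate manipulation levels.

## The synthetic word-world

The generator emulates the *structure* of norm studies, not any real
lexicon: pseudo-words (random lowercase strings, lengths 3–10 so word
length exists as a covariate) with vectors from a seeded Gaussian mixture
(default 5 clusters, spread 0.5, d = 16); ground-truth norms
`σ(wᵀx + b)` per metric with the projection vectors drawn once per world
(norm 1.5, giving ratings spread over most of the scale) — a smooth,
locally linear map, which is the regime the descent search assumes;
simulated raters (default 25 per word) adding Gaussian noise (SD 0.5 on
the 9-point scale) with ratings clipped at the scale bounds — clipping
slightly biases extreme words, as real ceiling effects do; and logistic
covariate-dependent missingness for MNAR experiments. Per-participant
rating records with alternating gender labels and repeat presentations
support the reliability and gender-balancing code paths. Everything is
deterministic per seed.

What passing tests on this world do **not** show: performance on real
corpora (real embedding geometry is heavy-tailed and anisotropic, real
norm functions are not exactly sigmoid-linear, real rater panels are
correlated), or that specific published correlations would be reproduced —
those depend on the original datasets and encoders.

## Numerical choices and degenerate inputs

- Layer-norm ε 1e-5; optimizer ε 1e-8; seeds everywhere via
  `numpy.random.SeedSequence` streams so sub-processes never share state.
- Pearson correlation on constant input raises (`ConstantInputError`);
  only the training loop downgrades it to a warning-plus-zero, because a
  single degenerate epoch should not kill a run.
- Round-half-up for split sizes (never banker's rounding, which would make
  sizes depend on parity).
- Correlations in CLI reports are rounded to 2 decimals, with the full-
  precision value alongside.
- Serialized models are plain JSON of doubles; round-trips are exact.
- The failure marker in match tables is the literal string `X`.

## Known limitations

- Hidden width, batch size, the early-stopping aggregate and the descent
  step policy are defensible defaults, not reproductions of any original
  run's unstated settings.
- The MNAR harness reports unrounded per-metric correlations and their
  differences; it makes no claim about confidence intervals for the
  average drop, whose construction would need the underlying ratings.
- `accuracy_drop` is undefined at r₁ = 0 and misleading for very small r₁;
  it is a descriptive statistic, not a test.
- The descent search explores along the control-respecting path from one
  seed; it is not a global feasibility solver over the vocabulary.
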