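# Methods

This note documents the models, calibrations, and design choices behind
`qcla`, in the order the pipeline runs.

## Synthetic cohorts

The generator produces survey tables with the statistical structure the
analysis assumes: a single latent severity trait θ drives both the numeric
screening items and word choice, so the text→score pipeline can be
validated against ground truth.

**Severity distribution.** θ ~ LogNormal(μ = 0.0888, σ = 0.6674). The
published screening distribution is summarized only by its moments and its
floor-heaviness, so the lognormal was chosen as the simplest two-parameter
right-skewed family; the parameters were fit by moment-matching 400k draws
so that the *induced scale total* (below) has mean 7.40 and SD 3.68. The
resulting floor share (all items = 1) is ≈ 28% and the emergent at-risk
share (all items ≥ 4) is ≈ 5%; these are emergent properties, not fitted
targets. A rounding-based item map was tried first and could not exceed
≈ 21% floor share at the target moments, which is why the floor-threshold
map below is the default.

**Item map.** Each of the four Likert items is
`clip(1 + floor(θ + ε), 1, 5)` with ε ~ N(0, 0.25²) independent per item.
The map is monotone in θ, exactly deterministic at zero noise, and places
every θ < 1 − ε at the item floor, reproducing the strong floor pile-up of
community screening samples. Item noise 0.25 yields inter-item consistency
(Cronbach α ≈ 0.95 at n = 400) somewhat above the published ≈ 0.9; pushing
noise higher flattens the floor share, and the moments were prioritized.

**Word choice.** Each question has a disjoint signal lexicon (6 words,
slope b per word) and a shared 60-word neutral lexicon. Every token slot
draws a candidate signal word uniformly and accepts it with probability
logistic(a + b·θ), otherwise emits a uniform neutral word. Defaults
a = −3.0, b = 0.5 put baseline signal use below 5% and land the default
cohort in a realistic validity band — stacked-model out-of-fold r ≈ 0.45
and best single question ≈ 0.39 at n = 400 — comparable to what short
open-ended instruments achieve against numeric scales. Answers are 5–10
tokens (one per text field, at least 5 fields filled); if duplicate
collapse would leave fewer than 3 distinct words, distinct neutral words
are appended so honest records always satisfy the cleaning rules.

**Adversarial records.** Planted disjointly, in exact counts or by rate:
spam rows (one placeholder token in all 40 fields *and* completion time
≤ 5 min — the two behaviors co-occur in careless responding), clean-answer
speeders, manually flagged irrelevant rows, and rows with fewer than three
distinct words on one question. Honest completion times are N(14, 3²)
minutes truncated above 5.5.

**What the generator does not emulate.** Real morphology, spelling errors,
multi-word phrases, topic drift, answer-length/severity correlation, or
any non-lexical signal (syntax, word order). Passing the recovery tests
shows the pipeline can detect a *lexical* severity signal through the
embedding; it says nothing about how much signal real free text carries.

## Exclusion pipeline

Criteria run in a fixed order — completion time (cutoff *inclusive* at
5 minutes), irrelevance flag, per-question minimum of 3 distinct words —
and each removed record is attributed to the first criterion it fails, so
ledger counts are mutually exclusive and sum to the input count.
Tokenization is whitespace splitting, edge-punctuation stripping and
lowercasing; no spelling correction is attempted (the reference workflow
corrected spelling manually, which a library cannot reproduce — callers
with pre-cleaned text can feed it directly). Duplicate words are collapsed
to their first occurrence within one question only. Irrelevance is a
manual annotation consumed as a flag column; a placeholder-pattern
heuristic (`suggest_irrelevant`) can pre-populate flags but is off by
default because relevance judgment is not automatable in general.

## Encoding

The default encoder is a hashing bag-of-words: each word seeds a
pseudorandom unit vector in R^768 via blake2b(word, seed) — stable across
processes and platforms — and an answer is the L2-normalized sum of its
word vectors. This is deliberately the *test path*: deterministic, zero
download, and linear, so a ridge model can read exactly the additive
lexical signal the generator plants. The transformer adapter (optional
extra) pools the last hidden layer of a masked language model over tokens;
mean pooling is the default because it is the common choice for
sentence-level regression, with first-token pooling as the alternative.
Answers are embedded after aggregation and deduplication. Feature blocks
are always stacked in ascending question order regardless of how the
subset is written.

## Ridge prediction and evaluation

The solver computes `(XᵀX + λI)β = Xᵀy` on centered, per-fold-standardized
features with an unpenalized intercept, switching to the exact dual form
`β = Xᵀ(XXᵀ + λI)⁻¹y` when p > n. Metrics are computed on pooled
out-of-fold predictions (every respondent predicted exactly once by a
model that never saw them), not averaged per fold: pooling uses each
observation once and matches how predicted-vs-observed scatter plots are
drawn. The r p-value uses the t transform `t = r√((n−2)/(1−r²))`,
two-sided. Predictions may be clamped to the attainable scale range for
display only — never before metrics.

**Penalty default λ = 1000.** With 3072 standardized embedding columns at
a few hundred observations, near-zero penalties overfit badly enough that
the stacked model consistently loses to single-question models out of
fold (mean r 0.38 vs 0.47 over 6 cohorts at λ = 1), inverting the
information ordering the design expects. λ = 1000 restores the expected
dominance of the stacked model in every tested cohort while leaving
single-question performance essentially unchanged; `select_lambda`
offers an inner-CV grid choice when a data-driven penalty is wanted.
Folds are plain shuffled k-fold (k = 10, sizes differing by at most one),
not stratified.

## Correlation comparisons

Dependent overlapping correlations (two predictors, one criterion) use
Steiger's (1980) modified Fisher-z statistic
`Z = (z₁ − z₂)·√((n−3)/(2(1−s̄)))`, with the covariance term s̄ evaluated at
the mean of the two correlations — the standard statistic behind common
online calculators. It is validated against a trivariate-normal Monte
Carlo oracle (agreement within 0.05 on a worked triple; one-sided null
rejection rate within 2 points of nominal over 2000 replicates). The
inter-predictor correlation is computed from the two out-of-fold
prediction vectors. The independent-samples test is the classic Fisher z.
Both one- and two-sided p-values are reported. An external test-retest
reliability enters only as a configured (r, n) pair; it is not computable
from single-administration data, and n for the published reference value
is not public, so that comparison is reported but has no reference
implementation to check against.

## Word ablation

The scan operates per question on the frozen analysis set: fold
assignment, encoder and seeds are fixed once, each word is deleted from
every answer, only affected answers are re-encoded, and out-of-fold r is
recomputed on the same folds — so a word's delta reflects the word, not
resampling noise (a property asserted in the tests: per-word fold
re-randomization strictly inflates the delta spread on a null corpus).
Respondents are never re-excluded mid-scan, and an answer emptied by
deletion encodes to the zero vector. Deltas are standardized across the
vocabulary (population SD) into z-scores with two-sided normal p-values;
p = α exactly is not significant. On a null corpus the flag rate at
α = .05 calibrates to ≈ 5–6%. Word deletion re-encodes the text rather
than zeroing embedding components — the literal reading of removing a
word from the features. Word-cloud export floors negative z at zero for
sizing (a word whose removal helps the model is not a "driver") and
buckets p at < .01 / < .05 / ns.

## Problem sizes

Statistical checks run at sizes chosen to make their expected behavior
unambiguous while keeping the full suite fast: recovery and permutation
nulls at n = 400 over 20 cohorts, null ablation calibration at 100
respondents × ≥ 200 words × 50 replicates, the Steiger oracle at 100k
Monte Carlo replicates, and the solver oracle at 100 random systems.

## Known limitations

- The hashing encoder carries no semantics: synonyms share nothing. It
  bounds what the tests demonstrate to lexical-signal recovery.
- The generator's severity→text link is token-level and monotone; real
  language signal is distributional and context-dependent.
- Cronbach α of synthetic items runs high relative to community samples
  (see item map); matching moments, floor share *and* α would need a more
  flexible item model than two knobs.
- The at-risk share emerging from the calibrated severity distribution
  (≈ 5%) is about double the published 2.4%; classification rules are
  exact, so this only affects how rare the top of the scale is in
  synthetic cohorts.
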