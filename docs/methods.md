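# Methods

This note records the models, the numerical choices, and the limits of
what the package's tests demonstrate.

## Problem and model

The unit of classification is a user `u` with an ordered post sequence
`T = (t₁, …, t_y)` and a binary label (positive = suicidal-ideation
group). A user's document is the concatenation of their posts with a
separator token; classification is document-level.

**Hierarchical vote ensemble.** The imbalanced training corpus `D` is
divided into `n` balanced sub-datasets `D₁ … Dₙ`: each contains all
minority-class users plus an equal-sized majority sample. For each `Dₚ`,
`m` base classifiers `c_p1 … c_pm` are trained. For a test user, the grid
of hard votes `r_pq` is reduced in two stages: `r_p = E(r_p1 … r_pm)` and
`r = E(r_1 … r_n)`, with `E` a hard majority vote. `E` is implemented as
hard voting because the method's combinatorial advantage is stated in
terms of counts of correct classifiers: the two-stage reduction can be
correct with only 4 of 9 correct base classifiers (2+2+0 across rows)
while a flat 9-vote majority needs 5. Both facts are verified by
exhaustive enumeration of all 512 correctness patterns
(`vote_pattern_census`). Probability-averaging ("soft") voting is an
extension point, deliberately not the default. Ties cannot occur at the
default odd `n = m = 3`; for even configurations the tie rule defaults to
the positive class, favouring recall in a screening context.

**Majority sampling.** Two strategies build the subsets.
`independent_sample` (default) draws each subset's majority sample
independently without replacement; samples overlap across subsets whenever
`n·|minority| > |majority|`, which holds in the reference regime (3 × 1284
> 2333), so disjoint majority samples are impossible there and cannot have
been intended. `disjoint_cycle` deals majority users round-robin from a
seeded shuffle and recycles only on exhaustion; it guarantees every
majority user appears in some subset whenever `n·|minority| ≥ |majority|`,
realising the coverage reading `D = D₁ ∪ … ∪ Dₙ`. Each subset also gets a
balanced validation view drawn from the global validation partition with
seed `seed + subset_index`.

**Sentence-level mask.** Masking deletes every post whose provenance tag
is in the masked set (default: `tree_hole`). It is provenance-based only;
no attempt is made to detect disclosure content when tags are absent.
Masking is idempotent, never increases any user's post count, and drops
(and reports) users left with zero posts.

## Base classifiers

The three architectures are implemented in NumPy with hand-written
backward passes (`quorum._net`), checked against central finite
differences in the test suite:

* **TextCNN** — parallel 1-D convolutions (kernel sizes 2/3/4) over learned
  word embeddings, max-over-time pooling, linear head.
* **FastText** — mean of unigram plus hashed-bigram embeddings (2048
  buckets), linear head.
* **DPCNN** — region convolution followed by repeated
  [stride-2 max-pool → conv → conv] blocks with residual connections and a
  global max pool; depth grows with the log of document length.

Word vectors are randomly initialised and learned end-to-end; no
pretrained embeddings. Training uses cross-entropy, minibatch Adam, batch
size 128, 20 epochs for the CNNs and 50 for FastText, with best-checkpoint
early stopping on validation F1 (patience 5): the parameters kept are
those of the epoch with the highest validation F1.

Width/learning-rate defaults are CPU-scale choices: embedding dim 32, 32
filters, max_len 256 (documents at the default corpus scale are ~100–250
tokens, so little is truncated), per-architecture Adam step sizes
(TextCNN 5·10⁻³, DPCNN 10⁻³, FastText 10⁻²). Two constraints shaped them:
single-precision matmul convolutions must keep a full experiment in
minutes on one core, and with batch 128 on a few hundred users an epoch is
only ~3 optimiser steps, so patience and step sizes must let the nets move
before stopping. All are overridable via `TrainConfig`; a random-search
helper is out of scope. Documents are padded to the longest
training-time document (capped at `max_len`) and the pad length is stored
with the classifier, so predictions are independent of batch composition.
Truncation keeps the head of the document by default (`tail` and seeded
`uniform` subsampling are options). The padding embedding is frozen at
zero.

The `dummy` architecture (bag-of-words logistic regression via
scikit-learn) is a deterministic, near-instant stand-in used to exercise
ensemble and pipeline machinery in tests; it carries no fidelity claim.

## Preprocessing

Cleaning applies, in order: drop system-generated posts; strip URLs,
@-mentions, emoticon tokens (bracketed shortcodes and Unicode emoji),
boilerplate phrases, listed location strings, and `#…#` SuperTopic titles;
drop posts with empty residue; drop users with fewer than
`min_posts_per_user` (default 3 — the smallest count that keeps
concatenated documents non-degenerate) remaining posts. The rule pipeline
iterates to a fixed point, making cleaning idempotent even under
adversarial substring overlaps. Default pattern inventories are
placeholders of the right shape, not faithful reconstructions of any
platform's emoticon set or a real administrative-division gazetteer; all
are config-overridable. Per-rule strip/removal tallies are reported so a
known injection ledger can be checked exactly.

## Evaluation

Confusion-matrix metrics with the positive class = at-risk group.
`0/0` ratios (e.g. a degenerate all-negative predictor) are reported as 0
and flagged in the report, so silent degeneracy is visible. Method
comparisons report percentage-point deltas. F1 is the headline metric:
on an imbalanced test set, accuracy rewards the degenerate all-majority
predictor.

## Synthetic corpus generator

The generator is a four-block unigram mixture: shared vocabulary,
positive-signal, tree-hole-signal and negative-signal blocks. Defaults
are a one-tenth scale of the reference corpus shape: 160 positive / 290
negative users, mean 8 vs 15 posts per user, mean 12 tokens per post;
post counts and lengths are Poisson(mean)+1 (a declared simplification —
real per-user dispersion is unknown).

Structure the generator reproduces on purpose:

* **Overt tree-hole signal.** Tree-hole posts mix tree-hole-signal tokens
  at weight 0.7 versus 0.2 for the subtle ordinary-timeline signal:
  disclosures in the tree hole are blatant, timeline signal is not.
  Every positive user has ≥ 1 tree-hole post (mirroring cohorts annotated
  from tree-hole activity); negative users have none.
* **Hidden users** (default fraction 0.3): their ordinary posts follow the
  negative class in count, length *and* content, and their only signal
  posts are tree-hole-tagged. Masking therefore removes all usable
  evidence for them by construction (verified by a chi-square
  indistinguishability test at `hidden_fraction = 1`), which is what makes
  the masked condition measurably harder.
* **Ambiguous negatives** (default fraction 0.2): normal users who quote
  positive-class and overt-disclosure vocabulary at low rate (0.1) —
  dark lyrics, complaints — without the label. These create genuine class
  overlap; without them tree-hole presence is a perfect label marker, a
  single classifier saturates, and neither imbalance nor ensembling has
  anything to do.

Signal strengths were calibrated once, at design time, so that single
architectures trained on the full imbalanced corpus land in the
unsaturated high-80s/low-90s F1 regime at the default scale, and then
frozen. With the frozen defaults (three seeds, medians): unmasked
baseline F1 ≈ 0.97 and ensemble ≈ 0.97; masked baseline ≈ 0.90 (a ~7-point
drop) and ensemble ≈ 0.90. The masking drop and the
ensemble-not-worse-than-baseline directions are stable; at the 45-user
test scale the ensemble typically ties rather than strictly beats the
best single model — one test user is ~6 F1 points, so strict gaps are not
resolvable at this scale.

What the generator does **not** emulate: real language (word order carries
no information beyond the bigram features), topic drift, time structure,
label noise from annotation, and platform-specific artefacts beyond the
injected noise kinds. Passing tests therefore demonstrate that the
machinery is correct and that the method's directional claims hold under
the generator's assumptions — not that these effect sizes transfer to real
corpora.

A dirty-corpus variant injects URLs, mentions, emoticons, boilerplate,
locations, SuperTopic titles, system posts and URL-only posts at known
rates and returns an exact injection ledger, against which the cleaning
tallies are asserted.

## Numerical and design choices

* Stratified split sizes: validation/test shares are rounded half-down
  per class, remainder to train; this reproduces the reference per-class
  counts (1606 → 1284/161/161, 2915 → 2333/291/291) and is guarded against
  float artefacts near exact .5 shares.
* Posts are kept in input order; no chronological sorting is applied.
* Oversampling duplicates whole users (fresh `#dup` ids), never single
  posts; undersampling keeps all minority users. Both are seeded.
* Labels: internal positive = `suicidal`; tie rule and 0/0 conventions as
  above.
* Determinism: every stochastic step (splitting, sampling, weight init,
  batch shuffling, generation, truncation) is driven by explicit seeds;
  per-cell training seeds derive stably from the fit seed and the grid
  position.

## Known limitations

* The NumPy nets are desk-scale: vocabulary in the low thousands and
  documents of a few hundred tokens. They are not a production deep
  learning stack.
* Whitespace tokenisation is the tested default; a Chinese segmenter can
  be plugged in via the `tokenizer` argument but is not bundled.
* The `disjoint_cycle` coverage guarantee assumes
  `n·|minority| ≥ |majority|`; outside that regime some majority users are
  unused by design.
* Selection of the "best" single baseline uses validation F1; with very
  small validation sets this choice is itself noisy.
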