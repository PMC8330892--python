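# Methods

## Problem and pipeline

`depsignal` estimates depression signal in a population of social-media
users from their public text. Case status is not clinical: a user is a
*case* when they publicly self-disclose a diagnosis, which is a noisy but
scalable label. The pipeline turns timelines into fixed-size text chunks,
scores chunks with a classifier, aggregates to users, fuses the score with
psycholinguistic/behavioural covariates, and aggregates scored chunks over
time into group trend curves.

## Cohort screening

Disclosure patterns are data-driven templates with an optional one-word
modifier slot `{x}`. The shipped defaults expand the canonical phrasings —
"I have/developed/got/suffer from/suffered from X depression", "my X
depression", "I'm/I am healing from X depression", "I'm/I am diagnosed with
X depression", and the profile self-labels "depression
fighter/sufferer/survivor" — with the modifier vocabulary {∅, severe,
major, clinical, chronic}. Matching is case-insensitive on raw text and
word-boundary anchored; both "I'm" and "I am" (and the curly apostrophe)
are accepted. Negations ("I don't have depression") are *not* special-cased:
self-disclosure screening of this kind is known to have imperfect precision,
and the package treats that as a property of the design rather than trying
to patch it with heuristics.

Users whose description contains a profession term (practitioner, counselor,
counsellor, therapist, psychiatrist) are excluded outright. A pattern match
overlapping a non-clinical phrase ("economic depression", "great
depression") is voided. Control eligibility is stricter than pattern
matching: the stem `depress` must be absent from the description and the
last 200 tweets, which reduces control contamination at the cost of
discarding some usable users.

Timeline trimming keeps tweets within a 90-day window ending at the anchor
date (the identifying tweet's date; for description-identified users, the
configured study end date), capped at the 200 most recent.

## Normalization and chunking

Three informal-text habits are marked with whitespace-delimited lowercase
tokens: fully capitalized words (≥ 2 letters) are rewritten in sentence case
and followed by `<allcaps>`; letters repeated ≥ 3 times are collapsed to one
and the word is followed by `<elongated>`; runs of a repeated terminal
punctuation mark are collapsed to a single mark followed by `<elongated>`;
runs of consecutive duplicate words are collapsed to one occurrence followed
by `<repeated>`. Marker order after a word is `<allcaps>`, `<elongated>`,
then attached punctuation. Normalization is idempotent: marker tokens pass
through unchanged.

A *word* is a whitespace-delimited token after normalization, markers
included. Chunks are built greedily in time order: whole tweets are appended
until the next tweet would exceed the budget (default 250 words). A single
tweet longer than the budget forms its own oversize chunk — tweets are never
split, preserving the consecutive-tweets contract. The trailing partial
chunk is kept in classification mode (a flag drops it) so short timelines
are not lost. In monitoring mode a chunk is dated by its middle tweet, index
⌊k/2⌋ (0-based) of its k tweets; for even k this is the later of the two
middles. Identifying tweets are removed before chunking so the classifier
cannot learn the screening patterns.

Splits are at user level (no user's chunks straddle train and test):
a 1:1-balanced test set is drawn first, then nested 1:1 training sets.
Within training, the 9:1 train/validation split is chunk-level random,
matching the protocol the pipeline mirrors; a user-level option would be
stricter but is not the default.

## Features

* **Lexicon scores** — percentage of tokens matching each category of a
  user-supplied lexicon (literal entries or `stem*` wildcards), computed on
  the user's concatenated (identifying-filtered) text. Tokenization is
  lowercase, punctuation-stripped, whitespace-split; normalization markers
  are excluded (they are not natural words). A token may count toward
  several categories. The shipped starter lexicon covers the 11 analyzed
  categories (i, posemo, negemo, anx, anger, sad, swear, bio, death, power,
  work) with small open word lists and is a documented stand-in for the
  proprietary psycholinguistic dictionary; unlike the real dictionary its
  categories are mutually non-matching (no nesting of sad/anx/anger inside
  negemo), which keeps planted-rate tests exact. Summary variables with
  unpublished formulas (Analytic, Clout, Authentic, Tone) are accepted only
  as externally supplied columns.
* **Sentiment** — a rule-based valence-lexicon scorer in the VADER style:
  a compact shipped lexicon of valenced words, booster words that amplify
  the following word's valence, and negators that flip valence within a
  three-token window (factor −0.74). Scores are the positive and absolute
  negative valence mass as fractions of total mass plus the neutral token
  count, giving proportion-style outputs in [0, 1].
* **Engagement** — proportion of tweets with mentions, number of replies
  ("responses" = tweets flagged as replies), unique mentions, total
  mentions, total tweets, plus log(x + 0.1) transforms of all five
  (natural log; the transform is applied to the proportion as well so the
  group has five raw and five transformed values).
* **Personality / demographics** — pass-through covariates from a provider
  contract (`user_id → {personality, gender, age_bin}`); the synthetic
  generator implements it, adapters for commercial inference services are
  out of scope. Personality requires ≥ 100 aggregate words, mirroring the
  minimum input of the external scoring service; users below the floor are
  flagged missing. Age uses four one-hot intervals (≤18, 19–29, 30–39, ≥40)
  and a binary gender label.
* **Mean chunk score** — arithmetic mean of the user's chunk confidences;
  missing when a user has no scored chunk.

A completeness filter retains only users with every requested group present,
the analog of feature-retrieval attrition in the original setting; the
pipeline manifest logs the retention fraction of every run.

Group contrasts use the two-sided Mann–Whitney U test with tie correction
(scipy); the reported U is that of the case sample.

## Chunk scoring

Any backend with `fit(texts, labels, config)` and `predict_score(texts) →
[0, 1]` can stand behind the pipeline, including fine-tuned transformers.
The shipped reference backend vectorizes word 1–2-grams (counts, min_df = 2)
and fits a regularized logistic head. Training honours the protocol of
epoch-based fine-tuning in a form meaningful for a convex model: the chunks
are split 9:1 into training and validation folds, one model is fitted per
regularization value C ∈ {0.05, 0.25, 1.0}, and the model with the best
validation accuracy + F1 is kept (ties resolve to stronger regularization).
Everything is deterministic at a fixed seed. Evaluation reports accuracy,
F1, AUC (rank statistic), precision and recall as percentages at a 0.5
threshold; AUC is reported missing when only one class is present.

## Fusion and importance

Fusion classifiers are logistic regression, a calibrated linear SVM
(`CalibratedClassifierCV(SVC(kernel="linear"), ensemble=False)`, so every
family exposes `predict_proba`), and a random forest, all fitted on
z-scored features (scaler fitted on the training fold only). The random
forest uses `max_features=None` — with every feature examined at each split,
duplicated columns cannot change the fitted predictions, a property the
test suite checks — and `min_samples_leaf=5`, since full-depth trees isolate
single users on uninformative columns and lend them spurious permutation
importance. Permutation importance is the mean drop in held-out
accuracy over 10 seeded column permutations (configurable to AUC), computed
on a random forest trained on the sentiment, engagement, personality and
lexicon groups — the mean chunk score is excluded there because it would
dominate and mask the contribution of individual features, and importance
is computed on the held-out test users.

## Trend monitoring and topics

Monitoring chunks are scored by the fitted chunk scorer. Scores are pooled
into bins of 3 days from the origin date; within each bin the top and
bottom ⌈trim·n⌉ scores are dropped (default trim 0.10; no trimming below
n = 3 — deterministic and conservative at small n), the remainder averaged,
and the bin means smoothed with a centered 5-bin moving average whose
window shrinks at the series edges (no padding). Trimming is per-bin by
default — robust bin means — with a documented global option, since either
reading of "trim the upper and lower 10% of the data" is defensible. Empty
bins stay missing; gaps are not interpolated and propagate to smoothing as
shorter windows. A changepoint is estimated as the location of the maximal
first difference of the smoothed series.

Topics use scikit-learn's variational LDA (k = 5 by default); the bespoke
logic is dominant-topic assignment (argmax of the k weights, ties to the
lowest topic id) and per-group dominant-topic counts before/after a cut
date. Topic label strings are human annotations and out of scope.

## Synthetic corpus generator

The generator defines the study conditions under which the pipeline is
validated. Tweets are bags of tokens: each token comes from a category
emission vocabulary with group-dependent probability rate/100, otherwise
from a neutral base vocabulary (none of whose words matches any category).
Default rates per 100 words (control → case): i 6.0 → 9.0, posemo 3.0 →
3.5, negemo 1.5 → 2.5, anx 0.4 → 0.6, anger 0.9 → 1.1, sad 0.5 → 1.0,
swear 0.55 → 0.8, bio 1.2 → 1.8, death 0.2 → 0.4, power 1.6 → 1.2, work
1.6 → 1.2 — directions mirror the documented group contrasts (cases higher
on first-person, affect, anxiety/anger/swear, biological-process and death
words; controls higher on power and work), with magnitudes chosen once as
plausibly strong planted effects. Personality shifts (case − control):
conscientiousness −0.12, extraversion −0.08, agreeableness −0.03,
neuroticism +0.15, openness 0 (so openness doubles as a null feature).
Tweet length is Poisson(15) truncated to [3, 60]; timeline lengths are
negative binomial (mean 45, dispersion 0.25, case engagement mean higher).
Disclosure texts are verbatim template instances of the screening phrases
(modifier slot ∅/severe/major), given to 60% of case users as a tweet and
30% as a description by default. Surface habits (ALL-CAPS, elongation,
duplicated words, punctuation runs) are applied only to base-vocabulary
tokens so category token rates are exact.

`inject_trend` multiplies the depression-associated category rates (those
with case rate > control rate) of case tweets after each changepoint,
redrawing affected tweet text while leaving timestamps, metadata,
disclosure tweets, control users, and all pre-changepoint text untouched.

What the generator does *not* emulate: real linguistic structure (syntax,
topics beyond token frequencies), user networks, bursty posting, label
noise in self-disclosure, or covariate-text dependence (personality and
demographics are drawn directly rather than inferred from text). Passing
tests therefore demonstrate that the pipeline's machinery recovers known
planted structure, not that the shipped effect sizes match any real
population.

## Benchmark problem sizes

The default benchmark used by the test suite and the acceptance script runs
800 users (1:1), a 200-user test set, 500 training users, and the reference
scorer. The trend benchmark uses a case-only monitoring cohort (500 users,
dense timelines of ~400 tweets over Jan 1 – May 22) with a ×2 step in
depression-language rates on March 13: dense timelines keep each 250-word
chunk's time-span near two 3-day bins, so middle-tweet dating does not blur
the changepoint, and the per-bin chunk counts keep bin means stable. The
null-flatness check runs the slope t-test on *raw* bin means, which are
independent across bins under the null; the smoothed series is
autocorrelated by construction and would invalidate the test. Null
calibration simulates 200 no-effect cohorts of 40 users and tests the
first-person category score, the least discrete of the category statistics.

## Known limitations

* Screening precision on real text is bounded by unhandled negation,
  sarcasm and quoting; the synthetic generator does not exercise these.
* The starter lexicons (categories and valence) are small open stand-ins;
  serious use requires supplying a full lexicon file.
* The reference scorer is a linear bag-of-n-grams model; its confidence
  scores can saturate near 0/1 on strongly separated corpora, compressing
  trend curves near the ceiling. Transformer backends plug into the same
  contract.
* Chunk-level validation splitting slightly overstates validation accuracy
  relative to a user-level split; a user-level option exists.
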