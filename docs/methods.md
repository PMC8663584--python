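# Methods

This note documents the models, parameter choices and numerical conventions
behind `plm`, and what the synthetic test substrate does and does not show.

## The embedding model

The core is a skip-gram negative-sampling (SGNS) word embedding, trained
from scratch.  Each vocabulary item *w* has an input vector `w_in` (used
for all similarity queries and the PCA map) and a context vector `w_out`
(used only during training).  For a center token *i*, an observed context
token *o* drawn from a window of radius sampled uniformly in `[1, c]`, and
*k* negatives drawn from the noise distribution, SGD minimizes the per-pair
loss

    L = −log σ(w_out,o · w_in,i) − Σ_{j=1..k} log σ(−w_out,neg_j · w_in,i).

Conventions and defaults (all in `TrainingConfig`):

| parameter | default | meaning |
|---|---|---|
| `dimension` | 100 | vector dimensionality |
| `window` | 5 | maximum context radius; actual radius resampled per center (dynamic window) |
| `negatives` | 5 | noise draws per positive pair |
| `subsample` | 1e-4 | threshold *t*; token of relative frequency *f* kept with probability `min(1, √(t/f))` |
| `epochs` | 5 | full passes over the corpus |
| `alpha` / `min_alpha` | 0.025 / 1e-4 | learning rate, linear decay over global pair progress |
| `noise_exponent` | 0.75 | `P_n(w) ∝ U(w)^0.75`, U = unigram count |
| `min_count` | 5 | vocabulary frequency floor |

These are the canonical settings of the algorithm family for a corpus on
the order of 10⁶ tokens.  Input vectors are initialized uniformly in
`±0.5/d`; context vectors start at zero.  Windows never cross post
boundaries.  A negative draw equal to the positive context is resampled:
an identical token on both sides of the pair objective would receive a
contradictory gradient signal.  Training is single-threaded; subsampling
masks, window radii, and negative draws are pregenerated per epoch from one
seeded generator and consumed by a sequential numba kernel, so a run is
reproducible bit-for-bit from its seed.

Two loss traces are recorded.  `epoch_mean_loss` is the conventional
running mean over each epoch's (pre-update) pair losses.  `eval_mean_loss`
freezes the first epoch's pair sample and re-evaluates it after every
epoch; this is the trace used for optimization-sanity assertions, because
the running mean resamples its pairs each epoch and can fluctuate by a few
millinats around the plateau even while the fixed-sample objective still
descends.

Gradient correctness is asserted against central differences at random
unsaturated parameter points (relative tolerance 1e-4).  In saturated
regions (|score| large) the true gradient falls below the finite-difference
noise floor (~1e-8 for these magnitudes), so agreement there is checked in
absolute rather than relative terms.

## Phrase handling

Multi-word community expressions must exist as single tokens before
training.  The tokenizer lowercases, NFC-normalizes and keeps word-internal
hyphens and apostrophes (so *pursed-lip* survives as one token; underscore
is reserved as the phrase joiner).  Adjacent bigrams are scored by the
count-ratio statistic `(count(ab) − δ)·N / (count(a)·count(b))` with
discount δ = 5 and count floor 5 by default, clamped at zero; bigrams above
a corpus-tuned threshold are merged greedily left-to-right, and a second
pass re-scores the merged corpus so trigram phrases can form.  Merging
never alters the underlying word sequence — splitting on the joiner
restores the input exactly.  Stop-words are not removed: frequent-word
subsampling is the mechanism that already discounts them.

## Lexicon expansion and curation

A lexicon starts from a few canonical seed terms and grows by taking the
top-k cosine neighbors of each seed above a similarity floor (defaults
k = 25, floor 0.4, one round; with more rounds, newly found terms become
probes).  Each found term records its best similarity and the seed it
traces back to.  Curation is explicit data, not an interactive step:
accept/reject token lists are applied to the expanded lexicon, rejected
terms are kept on record, and seeds cannot be rejected.  A term near the
seeds of two lexicons joins both; co-occurrence analysis deduplicates at
the post level, so no exclusivity rule is needed.  Severity lexicons
(mild / moderate / severe) have no canonical term list anywhere; they are
configuration-supplied seed lists expanded like any other lexicon and
should be read as a reconstruction.

## Counting and co-occurrence

The unit of analysis is the post.  A post is a hit for a lexicon if any
active term equals any token exactly (phrase terms match their merged
token; misspellings count only when they are explicit lexicon members —
there is no fuzzy matching by design).  Co-occurrence between two lexicons
is the exact cardinality of the intersection of their post-id hit sets.
Percentages are reported at two decimals with round-half-even, which
reproduces printed ratios such as 413/3938 → 10.49%.  Normalized profiles
divide entries by row or column mention counts; zero-denominator profiles
are reported as absent (NaN), never 0/0.  The ordering report ranks a
row's column values with explicit tie flags so downstream checks can
assert orderings without caring about magnitudes.  The set of scanned
posts is an explicit input (a post-id filter in the pipeline config): when
a mention denominator differs from the corpus total, that choice is logged
in the run manifest rather than implied.

## Salience map

Lexicon-member input vectors are L2-normalized — so Euclidean geometry in
the projection approximates cosine geometry in the embedding; this is an
interpretive convention, selectable off — column-mean-centered, and
projected onto the top-2 right singular vectors.  Per-axis sign is fixed by
making the largest-|loading| entry positive, which makes repeated
projections bit-identical.  Variance-explained ratios are reported for all
components and sum to one.  "Psychological salience" of a symptom cluster
is operationalized as the Euclidean distance of its 2D centroid from the
affective-states centroid; axis alignment between two clusters relative to
a reference is the |cosine| of the angle between the two centroid
displacement vectors.  Without normalization the map is invariant under a
constant shift of all vectors and equivariant (up to per-axis sign) under
orthogonal rotation.

## Synthetic corpus generator

The generator is the test substrate standing in for scraped forum data
that cannot be redistributed.  It emulates: variable post lengths
(negative binomial, default mean 190 tokens and dispersion 5 — several
thousand such posts give a corpus on the order of a million words); a
Zipf-distributed background vocabulary (exponent 1.0, default 2000 types),
so subsampling and the `U^0.75` noise distribution are exercised under a
natural-language-like frequency skew; planted synonym groups whose members
are drawn interchangeably from a shared within-group unigram distribution
(harmonic weights, first member canonical) — interchangeable contexts are
precisely what makes the members embeddable as neighbors, and this
learnability is asserted on raw text (context-count-vector cosines) before
any embedding is trained; per-post Bernoulli group activation with pairwise
topic links that force co-activation with a given probability, giving
`P(both) = p + (1 − p)·s_a·s_b` per post as the planted co-occurrence
rate; and deterministic misspelling variants (vowel drop, e.g. *phlegm* →
*phlgm*) that belong to their parent group.  Group tokens fill each token
slot of an active post with probability 0.2 (split across active groups),
background tokens otherwise.

What it does not emulate: forum register, syntax, threading, HTML, emoji,
author effects, or topic drift over time.  Passing planted-recovery tests
therefore shows that the pipeline recovers distributional structure when
it exists; it does not certify performance on real, messier language.

## Reproducibility plumbing

The pipeline runner derives one seed per stage from the global seed via
sha256 of `"<seed>/<stage>"` (first four bytes, mod 2³¹), so stages can be
rerun independently.  The run manifest records the config hash, per-stage
record counts and artifact checksums, and contains no timestamps, making
bit-identical reruns directly comparable.  Vectors are persisted in the
word2vec text format with 9-significant-digit scientific notation, which
round-trips float32 exactly.

## Test problem sizes

Unit tests use corpora of a few hundred posts.  The deeper recovery suites
use: ~110k tokens with three planted groups (shared session model), ~500k
tokens with ten groups for top-10 neighbor recovery (three seeds), 3000
posts for severity-ordering recovery, and 1000-post corpora (three seeds)
for the salience geometry.  These sizes were chosen as the smallest at
which the planted signals are comfortably above sampling noise for the
stated group shares and link probabilities.

## Known limitations

- The SGNS trainer is deliberately single-threaded; there is no
  asynchronous mode, GPU path, hierarchical softmax, CBOW, or subword
  modeling.
- Exact-token matching means orthographic variants not captured during
  lexicon expansion are invisible to the counting stage.
- The count-ratio phrase score with a fixed threshold is corpus-scale
  dependent; the threshold is a config knob, not an estimated quantity.
- Centroid distances on a 2D projection discard the variance outside the
  top two components; with weakly separated clusters the salience ranking
  can be unstable across seeds, which is why geometry assertions are made
  as majorities over seeds.
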