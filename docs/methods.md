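# Methods

## Model and procedure

The system reframes multiclass code assignment as translation followed
by nearest-description matching.

**Translation.** An encoder–decoder Transformer maps the (optionally
curated) source text to a canonical code description. Both sides use
word-level vocabularies built from the training pairs; source tokens
below a frequency cutoff (`vocab_min_freq`) map to a single UNK symbol,
which absorbs most one-off misspellings. The network is the standard
architecture — scaled dot-product multi-head attention, sinusoidal
positions, position-wise feed-forward blocks, causal decoder masking,
cross-attention to the encoder memory — in a pre-norm arrangement for
training stability, implemented in numpy with hand-written
backpropagation and Adam. Correctness of the gradients is established
by a finite-difference check in the test suite rather than by an
autodiff framework. Beam search returns hypotheses ranked by mean
per-token log-probability (length-normalized, since targets are long
and unnormalized beam scores favour premature end-of-sentence);
hypotheses are deduplicated after detokenization because distinct beam
paths can stringify identically.

**Matching.** Candidate sentences are scored against every catalog
description with similarity 1/(x+1), where x is a string distance.
Three metrics are available: character-level Levenshtein on the
space-joined sentence, Jaccard distance on whitespace-token sets, and
their combination as the arithmetic mean of the two *inverse scores*
(default). The per-sample, per-label score is the maximum over the
sample's candidates; the prediction is the argmax over labels, ties
broken toward the lexicographically smallest code so results are
independent of catalog order. The top-3 list takes each beam
candidate's best label in beam order (headed by the overall argmax) and
pads from the merged ranking when candidates collapse onto one label.
Both sides of every comparison are normalized into one text space
(lowercase, punctuation stripped, whitespace collapsed).

**Assumptions.** Exactly one gold code per case; a strict one-to-one
code↔description catalog; sources short enough that word-level
vocabularies stay small. Nothing in the method depends on model scale,
so the default configuration is deliberately desk-sized.

## Data handling

Cases are filtered against the catalog before modelling (unknown codes
excluded as invalid, configurable deprecated codes excluded with a
reason; the default deprecated set is {00740, 00810}). The temporal
holdout takes every case dated on or after the cutoff (default
2019-01-01) — the cutoff day itself belongs to the holdout, so the
development window is strictly earlier and no future information leaks
into training. Development cases are split 80/20 into train/validation
stratified by code; a label with a single case goes to train, because a
translator can only emit target sentences it has seen.

Curation order is fixed: trim → lowercase → acronym expansion →
spelling correction → stopword removal → lemmatization. Expansion
precedes correction so multi-word expansions are themselves curated.
The lemmatizer is a rule-based suffix stripper (plural/-ing/-ed, with
an exception list) iterated to a fixed point, which makes curation
idempotent; a heavyweight lemmatization model would be
disproportionate for 5-token phrases and is left pluggable. Target-side
normalization is lowercase + punctuation stripping only, keeping the
emitted sentences readable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `NmtConfig.embed_dim / layers / heads / ffn_dim` | 64 / 2 / 4 / 128 | Transformer size (per side) |
| `NmtConfig.beam_size` | 5 | beam width; must cover the k=3 retained candidates |
| `NmtConfig.epochs / batch_size / learning_rate` | 30 / 64 / 1e-3 | Adam training schedule (constant rate) |
| `NmtConfig.vocab_min_freq` | 1 | source-token frequency cutoff (2 in the study runs) |
| `transform.score_matrix(metric=...)` | `mean` | levenshtein / jaccard / mean of inverse scores |
| `SvmBaseline.min_count` | 4 (text), 15 (text+diagnosis) | raw corpus-frequency cutoff for n-grams |
| `bootstrap_ci(reps, sample_size)` | 500, 20,000 | percentile-bootstrap repetitions and resample size |
| `SynthConfig.zipf_exponent` | 1.2 | label imbalance; top 20% of codes carry ~75–84% of cases |
| `SynthConfig` noise rates | misspell 0.1, acronym 0.1, dropout 0.05, reorder 0.05 | per-token / per-case corruption probabilities |

The SVM baseline uses bigrams *plus unigrams* by default because
one-token sources (the observed minimum) produce no bigram at all; the
bigram-only behaviour is a flag. Its probabilities are a softmax over
the one-vs-rest linear margins: cross-validated Platt scaling cannot be
fit when the long-tailed label law leaves singleton classes, and only
the ranking of probabilities enters top-k accuracy. Regularization
strength is chosen on the validation set from a small grid
{0.1, 1, 10}.

BLEU is corpus-level with 4-gram modified precisions and brevity
penalty, reported on the 0–1 scale. Zero counts at orders ≥ 2 get
add-one smoothing (short references legitimately lack high-order
matches); zero unigram overlap yields BLEU 0. The percentile bootstrap
reports the 2.5th/97.5th percentiles of resampled accuracies; the
resample size is capped at the evaluation-set size so small sets are
not pathologically oversampled. For the imbalance analysis, codes are
sorted by training count and cut into near-equal-cardinality groups
(default 10), the remainder spread over the lowest groups; realized
count boundaries are recorded, and groups without evaluation samples
are reported as absent rather than zero.

## The synthetic generator

`make_catalog` builds descriptions around a unique (kind, procedure,
region) core triple — "anesthesia for open repair procedures on knee
…" — extended by qualifier phrases toward a mean of ~13 tokens, and
groups codes into contiguous synthetic body-region ranges.
`simulate_cases` draws codes from a truncated Zipf law (catalog index =
frequency rank), emits for each case a canonical short phrase (the core
triple plus extra description tokens, ~3–7 tokens, optional laterality
prefix), then corrupts it with recorded operators: acronym substitution
(from a table of first-letter acronyms of the kind–procedure bigram),
per-token character edits, token dropout, adjacent-token reordering.
Replaying the recorded operators reproduces the emitted text exactly,
which makes the noise model auditable and lets observed corruptions
double as demonstration spelling/acronym lexicons
(`lexicons_from_truth`) for testing the curation pipeline end to end.
Diagnoses are drawn from a small per-code vocabulary (region +
code-specific condition terms), so the diagnosis is informative about
the code, as in real records where the indication correlates with the
procedure. All randomness flows from one seed through named streams
(catalog, labels, noise, dates, diagnosis).

What the generator does **not** emulate: real clinical vocabulary and
its semantics, multi-code cases, seasonal drift between the development
and holdout windows, systematic coder error, or residual
"not otherwise specified" codes. Passing tests therefore demonstrate
the mechanics and the qualitative regime (noise robustness, imbalance
sensitivity, the value of diagnoses) — not clinical-grade accuracy on
real registries, where reported top-1 accuracies are substantially
lower than on this cleaner synthetic text.

## Numerical and design choices

- **Study conditions for tests and the acceptance script** (desk
  scale): 50-code catalog, 2,500 cases over 2017-01–2019-06, cutoff
  2019-01-01 (~1,950 development / ~550 holdout), misspell 0.1 /
  dropout 0.1, 15 training epochs, beam 5, k = 3. One fixed seed per
  suite; the acceptance script takes its seed on the command line.
- **Metric for the noise-free identity diagnostic.** When the raw
  (untranslated) short phrase is matched directly against full-length
  descriptions, character-level edit distance is dominated by the
  length difference and favours short descriptions regardless of
  content; that diagnostic therefore uses token-level Jaccard. This is
  precisely the regime the two-step design avoids: after translation,
  candidates are canonical-length and Levenshtein is informative, so
  the trained pipeline keeps the default mean metric.
- **Tie-breaking** is everywhere toward the smaller code string
  (argmax ties, SVM probability ties), making every ranking
  deterministic and permutation-invariant.
- **Degenerate inputs.** Empty normalized text stays a valid empty
  value; an empty decode falls back to a sentinel candidate with -inf
  score; labels with one case never enter validation; empty groups are
  absent, not zero.
- **Determinism.** Training, decoding, simulation, splits, and
  bootstrap are bit-reproducible given their seeds (single-threaded
  numpy/BLAS); tests assert byte-identical corpora and decodes.

## Known limitations

- Beam search recomputes the decoder over the full prefix per step
  (no incremental cache); adequate at a few hundred decodes, wasteful
  at registry scale.
- The numpy Transformer trains on one CPU; there is no GPU path, no
  subword vocabulary, and no learning-rate schedule beyond a constant
  rate — all acceptable at the corpus sizes used here.
- Exhaustive candidate-vs-catalog scoring is O(M·k·N); intended for
  catalogs of a few hundred codes, not for vocabulary-scale matching.
- The rule-based lemmatizer over-stems occasional tokens; since both
  corpus sides pass through the same normalization, this costs
  readability, not accuracy.
- Single-label prediction only: operative cases carrying several codes
  are out of scope.
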