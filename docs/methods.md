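# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Task and data model

A *self-acknowledged limitation* (SAL) is a weakness of a study stated by
its own authors.  The toolkit treats SAL analysis as two sentence-level
classification problems over RCT full texts:

1. **SAL detection** — is this sentence a limitation statement?
2. **SAL typing** — which limitation types does it express?

Types come from a two-level taxonomy of 15 top-level categories and 24
sub-categories with parent links (`SampleSize → UnderpoweredStudy`,
`Unicentric → Setting`, …), shipped as a versioned TSV inside the package
and loadable from a user path for specialty extensions.  Labels are
*sets*: one sentence may acknowledge several limitations, and at fine
granularity a top-level name remains a valid label for sentences too
vague for any sub-category.  `coarsen` maps a fine label set to its
top-level image (idempotent, never cardinality-increasing); the `Other`
category is allowed to co-occur with specific labels, and validation
reports flag such combinations rather than rejecting them.

Typing is sentence-level by design even though annotations are spans:
span extents for limitation types are heterogeneous (noun phrases to full
sentences) and agree poorly between annotators, while the downstream
question — *which* limitation types does an article report — only needs
sentence-level sets.  Span annotations are projected onto sentences by
≥1-character overlap, with duplicate categories consolidated and
straddling spans labeling every overlapped sentence.

## Classifiers

Both stages share an **encoder contract**: any object mapping a batch of
strings to fixed-width vectors.  A domain-pretrained transformer's pooled
output satisfies the contract; the bundled default is a signed
feature-hashing encoder over word uni- and bigrams (md5-derived indices,
L2 normalization), chosen because it is deterministic across processes
and platforms and trains in seconds on a CPU.  The input string
concatenates the sentence with its top and innermost section headers
around a `[SEP]` marker — sentence first for the binary task,
headers first for the type task (both orders are supported; the defaults
mirror each task's convention).

- *Binary head*: one logit, sigmoid, binary cross-entropy, mini-batch
  gradient descent with seeded initialization and shuffling; L2 penalty
  1e-4.  Decision rule `p ≥ 0.5` (boundary inclusive).
- *Type head*: one hidden tanh layer (64 units) and a softmax over the
  label space.  Multi-label gold sets are encoded as uniform
  distributions over the gold labels for the cross-entropy objective; a
  sigmoid + BCE head is available behind `head="sigmoid"` for
  independent per-label probabilities.  Softmax probabilities are what
  thresholds apply to by default.

**Dynamic thresholding.**  For each label independently, the threshold is
the point of a fixed grid (0.01…0.99, step 0.01) maximizing that label's
binary F1 on the development split; ties break to the smallest
threshold, and a label absent from the dev gold receives the grid
maximum with a warning.  Optimality per label is grid-exhaustive by
construction and verified against an independent oracle in the tests.
When no label clears its threshold the default fallback emits the argmax
label, since every input to the type stage is already a SAL sentence.

**Funding rule.**  `Funding` examples are too scarce and too entangled
with other labels to train or augment, so a rule supplements the
classifier: a sentence is Funding when any token's stem equals `financ`
or `fund` under the bundled Porter-family stemmer.  The stem set is
configurable (the literal strings `finance`/`fund` may be used instead;
note a suffix-stripping stemmer itself never produces `finance`).

## Agreement

Krippendorff's α is computed in the coincidence-matrix formulation:
α = 1 − D_o/D_e with observed disagreement pooled over pairable values
within units (weight 1/(m_u−1)) and expected disagreement from the
pooled value marginals.  Units with fewer than two annotations are
dropped (standard missing-data treatment).  The distance between
set-valued labels is MASI, d = 1 − J·M (J Jaccard; M = 1 identical, 2/3
strict sub/superset, 1/3 crossing, 0 disjoint); two empty sets are
identical.  The distance is used directly as the δ² term; a
`square_distance` switch squares it instead for users who prefer that
reading.  Cohen's κ handles pairwise token-level agreement over
category-vs-`O` labels, with κ defined as 1 when both annotators are
constant and identical (p_e = 1); the module emits the full pairwise
matrix.

## Augmentation

Classes with fewer than `target = 70` training sentences are filled to
exactly 70.  Counting is per label over SAL sentences; only single-label
sentences seed generation (multi-label features are entangled), and
`Funding` is ineligible.  Routes:

- **Oversampling** — uniform duplication with replacement from the
  class's single-label examples.
- **EDA** — one operator per variant (synonym replacement from a small
  bundled lexicon, random insertion, random deletion, random swap) at a
  per-word rate of 0.1; deletion always retains ≥1 word.
- **Dual view** — a generator produces 10 candidates per seed, prompted
  either with the seed's RAKE keywords (Input View) or with the label
  name alone (Output View).  RAKE scores words by degree/frequency over
  the candidate-phrase graph and phrases by member-word sums.  The
  production generator (a soft-prompt-tuned encoder–decoder) sits behind
  a contract; the bundled stand-in fills label-specific sentence
  skeletons deterministically so the whole route runs offline.

Consistency filtering keeps candidates whose predicted label (from a
classifier trained on the original training set) matches the intended
one.  Because filtering systematically starves rare classes — the
filter is trained on exactly the distribution being corrected — the
recommended preset is Output View *without* filtering; both toggles
exist.  `balance` then draws exactly `70 − n` samples per deficient
class uniformly without replacement, warning (never fabricating) on
shortfalls.  No route ever alters, relabels, or removes an original
record.

## Significance tests

McNemar's test uses the discordant counts b, c of paired binary
correctness: χ² = (b−c)²/(b+c) without continuity correction against
χ²(1), switching to the exact two-sided binomial below b+c = 25; b+c = 0
gives p = 1.  The Bhapkar test of marginal homogeneity forms the square
contingency table of paired categorical outcomes, takes the first k−1
marginal differences d_i = n_i· − n_·i and their consistent covariance
estimate S (S_ii = n_i· + n_·i − 2n_ii − d_i²/n, S_ij = −(n_ij + n_ji)
− d_i d_j/n), and refers d′S⁻¹d to χ²(k−1); a singular S falls back to
the Moore–Penrose inverse with rank degrees of freedom, flagged.
Multi-label outcomes become composite classes via their sorted label
tuple; an empty set maps to a reserved `∅` class.  How ties and
"both wrong, differently" cases enter the binary McNemar mapping is a
modeling choice: correctness here means exact set equality with gold.
On 2-category tables Bhapkar equals M/(1 − M/n) with M the uncorrected
McNemar statistic — a closed form the tests verify.

Run aggregation reports mean and sample SD (k−1 denominator) over
k = 5 seeded runs by default.  Corpus profiles report per-article means
with t-distribution 95% confidence intervals.

## Synthetic corpora

The generator emulates the *structure* of an annotated RCT limitation
corpus, not its prose.  Articles have
Abstract/Introduction/Methods/Results/Discussion/Limitations sections;
SAL sentences occur only in the abstract and keyword-matching sections;
counts per article are truncated-Poisson with mean 4.8; a sentence gains
a second label with probability 0.15 (mean 1.15 labels/sentence).  The
label distribution is long-tailed: the five frequencies reported for the
reference corpus (Population 192/1090, OutcomeMeasures 190,
UnderpoweredStudy 185, Setting 12, Funding 4) are used as given, and the
residual mass is interpolated over the remaining ten types with
Intervention largest.  Classes listed in `minority_classes` are capped
(default 40 occurrences per corpus) so a training split always contains
several classes under the augmentation target.  Each type owns cue
phrases that appear in no other type's templates, making fixtures
separable by a bag-of-words model.

Consequently, green pipeline tests demonstrate that the machinery —
splitting, training, thresholding, the two-stage hand-off, profiling,
augmentation bookkeeping — is correct and deterministic.  They do *not*
demonstrate accuracy on real scientific text, where limitation cues are
paraphrased, hedged, and shared across types; that requires a
domain-pretrained transformer encoder behind the same contract and a
real annotated corpus.

## Numerical and design choices

- Offsets are 0-based, end-exclusive everywhere (BRAT convention).
- Header keyword matching is case-insensitive substring on both header
  levels; the abstract is the section whose top header equals
  "Abstract" (or the first section when flagged in metadata).
- Sentence segmentation is a deterministic punctuation-based rule set
  with decimal/abbreviation guards, pluggable where consumed.
- Splits are article-level; dev/test sizes are floor(ratio·n) and the
  remainder goes to training (200 → 120/40/40).
- Training hyperparameters (epochs, learning rate 0.5, batch 32, hidden
  64) are repository choices sized for the hashing encoder, not
  published values.
- Problem sizes in tests and the acceptance script (200-article corpora,
  ≥200 randomized oracle instances per statistic) are chosen so the full
  suite runs in well under a minute while keeping sampling error far
  from the asserted bounds.
- Softmax-probability thresholding is the default; per-label score
  thresholding is available via the sigmoid head.

## Known limitations

- The bundled encoder is lexical; synonymy and negation are invisible to
  it.  It exists for determinism and testability, and the encoder
  contract is the intended extension point.
- The template generator cannot produce genuinely novel phrasings, so
  augmentation gains measured on fixtures overstate what template
  generation achieves on real data.
- Krippendorff's α is exact but O(V²) in the number of distinct label
  sets, which is fine at realistic label-set diversity.
- The Funding rule is intentionally high-recall and will fire on
  non-limitation mentions of funding inside SAL sentences.
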