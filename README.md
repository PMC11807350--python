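# salnlp

Detection and multi-label categorization of **self-acknowledged
limitations (SALs)** in randomized controlled trial (RCT) publications.

Authors are expected (e.g. by the CONSORT guideline) to discuss the
weaknesses of their trial — a small sample, unblinded assessors, a single
recruiting center.  Whether and how they do so is a reporting-quality
question that journals, peer reviewers, and meta-researchers would like
to check automatically.  `salnlp` is a toolkit for that task: it finds
the sentences in which authors acknowledge limitations and assigns each
one a set of limitation *types* from a fixed two-level taxonomy of
15 top-level categories (e.g. `UnderpoweredStudy`, `Population`,
`Blinding`) refined by 24 sub-categories (e.g. `SampleSize`,
`Unicentric`).

## What is inside

The pipeline is two-stage, with all of the experimental machinery around
it:

- **Sentence stage** — a binary classifier over the target sentence
  concatenated with its top and innermost section headers; a pluggable
  text encoder feeds a linear head trained with binary cross-entropy on
  a single logit, and a sentence is positive when
  σ(w·x + b) ≥ τ (τ = 0.5 by default).
- **Type stage** — a multi-label classifier (MLP + softmax over the label
  space; multi-label gold sets become uniform target distributions under
  cross-entropy) with **dynamic thresholding**: for each label ℓ the
  decision threshold t_ℓ is the grid point maximizing that label's
  binary F1 on the development split.  A rule-based detector supplements
  the `Funding` class (fires when a stemmed token equals `financ` or
  `fund`).
- **Corpus handling** — BRAT standoff parsing with surface verification,
  sentence segmentation, keyword-based selection of discussion- and
  limitation-related sections (*discussion, limitation, weakness,
  conclusion, caveat, shortcoming, drawback*), span→sentence label
  projection, article-level 120/40/40-style splits, JSON Lines I/O.
- **Agreement** — Krippendorff's α (coincidence-matrix form, any number
  of annotators, missing cells) with the MASI set distance
  d = 1 − J·M, and pairwise token-level Cohen's κ.
- **Augmentation** — class balancing to a target of 70 sentences per
  class via oversampling, EDA perturbations, or dual-view prompt
  generation (Input View: RAKE keywords of a seed sentence; Output View:
  the label name), with optional consistency filtering.  Multi-label
  seeds and `Funding` are excluded by design.
- **Evaluation** — micro/macro P/R/F1 over (sentence, label) decisions,
  5-run mean±SD aggregation, McNemar's test on paired correctness, and
  the Bhapkar χ² test of marginal homogeneity (d′S⁻¹d, df = k−1) with
  multi-label outcomes encoded as composite classes.
- **Synthetic corpora** — a deterministic generator of sectioned,
  cue-phrase-separable fixture articles matching the corpus statistics
  (≈4.8 SAL sentences/article, ≈1.15 labels/sentence, long-tailed label
  distribution), so everything above runs offline and reproducibly.

## Worked example

```python
from salnlp import PipelineConfig, SynthConfig, generate_corpus, run_end_to_end

corpus = generate_corpus(SynthConfig(n_articles=200, seed=1))
result = run_end_to_end(corpus.articles, corpus.sentences, PipelineConfig(seed=1))
print(result.sentence_scores)   # {'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'accuracy': 1.0}
print(result.type_scores)       # {'precision': 0.889, 'recall': 0.971, 'f1': 0.928}
```

On the separable synthetic corpus the sentence stage is essentially
perfect and the type stage reaches micro-F1 ≈ 0.93 on the held-out test
articles — the numbers say the machinery (training, thresholding, the
two-stage hand-off) works end to end; they say nothing about accuracy on
real prose, which requires a stronger encoder (see `docs/methods.md`).
The profile in `result.profile` tabulates, per limitation type, how many
sentences express it and what fraction of articles report it, e.g.
`OutcomeMeasures 57.5% of articles` on the example corpus, with t-based
95% confidence intervals for per-article means.

Narrative scripts in `examples/` walk through each capability
(simulation, agreement, training and thresholding, augmentation,
significance testing, profiling); each prints the numbers it computes and
what they mean.  A thin CLI mirrors the stages:

```bash
salnlp simulate --n-articles 50 --seed 1 --jsonl-out corpus/
salnlp train-sentence corpus/sentences.jsonl sent.npz
salnlp train-type corpus/sentences.jsonl type.npz
salnlp fit-thresholds type.npz corpus/sentences.jsonl thresholds.json
salnlp profile corpus/articles.jsonl sent.npz type.npz thresholds.json
```

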