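"""Full pipeline: train, threshold, evaluate, and profile a corpus.

The corpus-level profile mirrors a large-scale limitation survey: per
limitation type, how many sentences express it and what fraction of
articles report it at least once.
"""

from salnlp import PipelineConfig, SynthConfig, generate_corpus, run_end_to_end

corpus = generate_corpus(SynthConfig(n_articles=200, seed=1))
result = run_end_to_end(corpus.articles, corpus.sentences, PipelineConfig(seed=1))

print("sentence classifier:", {k: round(v, 3) for k, v in result.sentence_scores.items()})
print("type classifier:    ", {k: round(v, 3) for k, v in result.type_scores.items()})

prof = result.profile
print(f"\nprofiled {prof.n_articles} test articles; "
      f"{prof.n_articles_with_sal} had SAL sentences")
m, lo, hi = prof.sal_sentences_per_article
print(f"SAL sentences/article: {m:.2f} [95% CI {lo:.2f}, {hi:.2f}]")
print("\ntop reported limitation types (document level):")
table = prof.type_table.sort_values("document_pct", ascending=False)
for label, row in table.head(5).iterrows():
    print(f"  {label:<20s} {row['document_pct']:5.1f}% of articles "
          f"({int(row['document_count'])} docs, {int(row['sentence_count'])} sentences)")
# Document-level percentages count each type once per article, so they
# need not sum to 100; sentence-level percentages do.
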