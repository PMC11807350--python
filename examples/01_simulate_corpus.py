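"""Generate a synthetic labeled RCT corpus and inspect its statistics.

The generator emulates an annotated limitation corpus: sectioned articles
whose abstract and discussion/limitation sections carry template SAL
sentences with known type labels, a long-tailed label distribution, and
roughly 4.8 SAL sentences per article at 1.15 labels per sentence.
"""

import statistics
from collections import Counter

from salnlp import SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(n_articles=100, seed=42))
sal = [s for s in corpus.sentences if s.is_sal]
per_article = Counter(s.article_id for s in sal)
label_counts = Counter(l for s in sal for l in s.types_top)

print(f"articles:            {len(corpus.articles)}")
print(f"sentences:           {len(corpus.sentences)}")
print(f"SAL sentences:       {len(sal)}")
print(f"SAL/article (mean):  {statistics.mean(per_article[a.article_id] for a in corpus.articles):.2f}")
print(f"labels/SAL sentence: {statistics.mean(len(s.types_top) for s in sal):.3f}")
print("most / least common types:")
for label, n in label_counts.most_common(3):
    print(f"  {label:<20s} {n}")
for label, n in label_counts.most_common()[-3:]:
    print(f"  {label:<20s} {n}")
# The head of the distribution (Population, OutcomeMeasures,
# UnderpoweredStudy) dominates while Setting/Funding stay rare -- the
# imbalance the augmentation machinery exists to correct.
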