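"""Train both classifiers and fit per-label dynamic thresholds.

Stage one flags SAL sentences (binary, BCE on a single logit); stage two
assigns limitation types (multi-label, softmax over 15 top-level
categories) and picks one decision threshold per label by maximizing that
label's F1 on the development split.
"""

from salnlp import (
    SynthConfig,
    TrainConfig,
    fit_thresholds,
    generate_corpus,
    load_taxonomy,
    split_corpus,
    train_binary,
    train_type,
)

tax = load_taxonomy()
corpus = generate_corpus(SynthConfig(n_articles=80, seed=5))
train_arts, dev_arts, _ = split_corpus(corpus.articles, seed=5)
train_ids = {a.article_id for a in train_arts}
dev_ids = {a.article_id for a in dev_arts}
train = [s for s in corpus.sentences if s.article_id in train_ids]
dev_sal = [s for s in corpus.sentences if s.article_id in dev_ids and s.is_sal]

sent_clf = train_binary(train, TrainConfig(seed=5, epochs=40))
print(f"sentence classifier: final BCE {sent_clf.loss_history[-1]:.4f}")

type_clf = train_type(
    [s for s in train if s.is_sal], "top",
    TrainConfig(seed=5, epochs=120, header_order="headers_first"), taxonomy=tax,
)
tv = fit_thresholds(type_clf.predict_proba(dev_sal),
                    [s.types_top for s in dev_sal], type_clf.label_space)
shown = sorted(tv.thresholds.items())[:5]
for label, t in shown:
    print(f"threshold[{label}] = {t:.2f}")
# Thresholds differ per label: rare labels typically need a lower cut to
# reach their best F1 than frequent ones.
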