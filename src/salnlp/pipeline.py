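"""End-to-end orchestration: extract -> train sentence classifier ->
train type classifier -> fit thresholds -> (optional augmentation) ->
evaluate -> profile.

Every stage records its seeds and configuration into the report so a
rerun with identical inputs reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

from . import __version__
from .augment import (
    DEFAULT_N_PER_SEED,
    DEFAULT_TARGET,
    TemplateGenerator,
    balance,
    build_plan,
    consistency_filter,
    generate_dual_view,
    oversample,
)
from .corpus_io import Article, LabeledSentence, split_corpus
from .encoders import Encoder, get_encoder
from .eval_stats import CorpusProfile, micro_prf, profile_corpus
from .sentence_model import TrainConfig, evaluate_binary, predict_sal, train_binary
from .taxonomy import Taxonomy, load_taxonomy
from .type_model import fit_thresholds, predict_with_rules, train_type

__all__ = ["PipelineConfig", "PipelineResult", "run_end_to_end"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    granularity: str = "top"
    encoder_name: str = "hashing"
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    augmentation: str = "none"  # none|oversample|eda|promda|promda-input|promda-output
    consistency_filtering: bool = False
    target_size: int = DEFAULT_TARGET
    n_per_seed: int = DEFAULT_N_PER_SEED
    fallback: str = "argmax"
    use_funding_rule: bool = True
    sentence_epochs: int = 60
    type_epochs: int = 120

    def digest(self) -> str:
        return hashlib.md5(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    taxonomy_version: str
    package_version: str
    sentence_scores: dict
    type_scores: dict
    thresholds: dict[str, float]
    profile: CorpusProfile
    n_train_sentences: int
    n_augmented: int
    stage_log: list[str] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable evaluation report with full provenance."""
        return {
            "package_version": self.package_version,
            "taxonomy_version": self.taxonomy_version,
            "config": asdict(self.config),
            "config_hash": self.config.digest(),
            "sentence_scores": self.sentence_scores,
            "type_scores": self.type_scores,
            "thresholds": dict(sorted(self.thresholds.items())),
            "n_train_sentences": self.n_train_sentences,
            "n_augmented": self.n_augmented,
            "profile": {
                "n_articles": self.profile.n_articles,
                "n_sal_sentences": self.profile.n_sal_sentences,
                "n_articles_with_sal": self.profile.n_articles_with_sal,
                "sal_sentences_per_article": list(self.profile.sal_sentences_per_article),
                "types_per_article": list(self.profile.types_per_article),
                "type_table": self.profile.type_table.round(6).to_dict(orient="index"),
            },
            "stages": self.stage_log,
        }


def _gold_sets(records: Sequence[LabeledSentence], granularity: str):
    return [r.types_top if granularity == "top" else r.types_fine for r in records]


def _augment_training(
    train_sal: list[LabeledSentence], cfg: PipelineConfig, encoder: Encoder, taxonomy: Taxonomy,
    log: list[str],
) -> list[LabeledSentence]:
    plan = build_plan(train_sal, target=cfg.target_size, granularity=cfg.granularity)
    if cfg.augmentation == "oversample":
        out = oversample(train_sal, plan, seed=cfg.seed)
        log.append(f"augment: oversampled to target {cfg.target_size}")
        return out
    if cfg.augmentation == "eda":
        from .augment import eda_variants

        pool = []
        for cp in plan.deficient():
            for var_round in range(10):  # up to 10 variants per seed sentence
                for i in cp.seed_ids:
                    rec = train_sal[i]
                    pool.extend(
                        eda_variants(
                            rec.text, cp.label, n_variants=1,
                            seed=cfg.seed + 7919 * var_round + i,
                        )
                    )
        out, warns = balance(train_sal, plan, pool, seed=cfg.seed)
        log.extend(warns)
        return out
    if cfg.augmentation in ("promda", "promda-input", "promda-output"):
        views = {
            "promda": ("input_view", "output_view"),
            "promda-input": ("input_view",),
            "promda-output": ("output_view",),
        }[cfg.augmentation]
        gen = TemplateGenerator(seed=cfg.seed)
        pool = []
        for cp in plan.deficient():
            for i in cp.seed_ids:
                for view in views:
                    pool.extend(
                        generate_dual_view(
                            train_sal[i], gen, n_per_seed=cfg.n_per_seed,
                            view=view, granularity=cfg.granularity,
                        )
                    )
        if cfg.consistency_filtering:
            filter_clf = train_type(
                train_sal, cfg.granularity,
                TrainConfig(seed=cfg.seed, epochs=cfg.type_epochs, header_order="headers_first"),
                taxonomy=taxonomy, encoder=encoder,
            )

            def filter_model(text: str) -> str:
                from .corpus_io import SentenceRecord

                rec = SentenceRecord(
                    article_id="filter", section_index=0, char_start=0,
                    char_end=len(text), text=text,
                    top_header="Discussion", innermost_header="Limitations",
                )
                probs = filter_clf.predict_proba([rec])[0]
                return filter_clf.label_space[int(probs.argmax())]

            pool = consistency_filter(pool, filter_model)
            log.append(f"augment: consistency filter kept {len(pool)} candidates")
        out, warns = balance(train_sal, plan, pool, seed=cfg.seed)
        log.extend(warns)
        return out
    raise ValueError(f"unknown augmentation preset {cfg.augmentation!r}")


def run_end_to_end(
    articles: Sequence[Article],
    gold_sentences: Sequence[LabeledSentence],
    config: PipelineConfig | None = None,
    taxonomy: Taxonomy | None = None,
) -> PipelineResult:
    """Train, evaluate and profile on a labeled corpus.

    ``gold_sentences`` are sentence-level gold records for (at least) the
    abstract and discussion/limitation-related sections of every article.
    The split is article-level; the profile runs over the test articles.
    """
    cfg = config or PipelineConfig()
    tax = taxonomy or load_taxonomy()
    log: list[str] = []

    def stage(name):
        log.append(name)
        return name

    try:
        stage("split")
        train_arts, dev_arts, test_arts = split_corpus(
            list(articles), cfg.split_ratios, seed=cfg.seed
        )
        ids = {a.article_id: "train" for a in train_arts}
        ids.update({a.article_id: "dev" for a in dev_arts})
        ids.update({a.article_id: "test" for a in test_arts})
        by_split: dict[str, list[LabeledSentence]] = {"train": [], "dev": [], "test": []}
        for rec in gold_sentences:
            if rec.article_id in ids:
                by_split[ids[rec.article_id]].append(rec)
    except Exception as exc:
        raise PipelineError("split", exc) from exc

    encoder = get_encoder(cfg.encoder_name)

    try:
        stage("train-sentence")
        sent_clf = train_binary(
            by_split["train"],
            TrainConfig(seed=cfg.seed, epochs=cfg.sentence_epochs, encoder_name=cfg.encoder_name),
            encoder=encoder,
        )
    except Exception as exc:
        raise PipelineError("train-sentence", exc) from exc

    try:
        stage("augment" if cfg.augmentation != "none" else "augment:skipped")
        train_sal = [r for r in by_split["train"] if r.is_sal]
        if cfg.augmentation != "none":
            train_typed = _augment_training(train_sal, cfg, encoder, tax, log)
        else:
            train_typed = train_sal
    except Exception as exc:
        raise PipelineError("augment", exc) from exc

    try:
        stage("train-type")
        type_clf = train_type(
            train_typed, cfg.granularity,
            TrainConfig(seed=cfg.seed, epochs=cfg.type_epochs, header_order="headers_first"),
            taxonomy=tax, encoder=encoder,
        )
    except Exception as exc:
        raise PipelineError("train-type", exc) from exc

    try:
        stage("fit-thresholds")
        dev_sal = [r for r in by_split["dev"] if r.is_sal]
        probs = type_clf.predict_proba(dev_sal)
        thresholds = fit_thresholds(probs, _gold_sets(dev_sal, cfg.granularity), type_clf.label_space)
    except Exception as exc:
        raise PipelineError("fit-thresholds", exc) from exc

    try:
        stage("evaluate")
        test_all = by_split["test"]
        sent_pred = [flag for _, flag in predict_sal(sent_clf, test_all)]
        sent_scores = evaluate_binary([r.is_sal for r in test_all], sent_pred)
        test_sal = [r for r in test_all if r.is_sal]
        type_pred = predict_with_rules(type_clf, thresholds, test_sal, fallback=cfg.fallback) \
            if cfg.use_funding_rule else None
        if type_pred is None:
            from .type_model import predict_types

            type_pred = predict_types(type_clf, thresholds, test_sal, fallback=cfg.fallback)
        if cfg.granularity == "top":
            type_pred = [tax.coarsen(p) for p in type_pred]
        p, r, f1 = micro_prf(_gold_sets(test_sal, cfg.granularity), type_pred)
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    try:
        stage("profile")
        prof = profile_corpus(
            test_arts, sent_clf, type_clf, thresholds, tax,
            use_funding_rule=cfg.use_funding_rule, fallback=cfg.fallback,
        )
    except Exception as exc:
        raise PipelineError("profile", exc) from exc

    return PipelineResult(
        config=cfg,
        taxonomy_version=tax.version,
        package_version=__version__,
        sentence_scores={
            "precision": sent_scores.precision,
            "recall": sent_scores.recall,
            "f1": sent_scores.f1,
            "accuracy": sent_scores.accuracy,
        },
        type_scores={"precision": p, "recall": r, "f1": f1},
        thresholds=thresholds.thresholds,
        profile=prof,
        n_train_sentences=len(by_split["train"]),
        n_augmented=len(train_typed) - len(train_sal),
        stage_log=log,
    )
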