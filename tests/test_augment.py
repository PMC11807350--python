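"""Augmentation planning, oversampling, EDA, RAKE, dual-view generation,
consistency filtering, and class balancing."""

import pytest

from salnlp.augment import (
    DEFAULT_N_PER_SEED,
    DEFAULT_TARGET,
    GeneratorContractError,
    SyntheticSample,
    TemplateGenerator,
    balance,
    build_plan,
    consistency_filter,
    eda_variants,
    generate_dual_view,
    oversample,
    rake_keywords,
)
from tests.conftest import make_sentence


def _training_set():
    """65 Population, 80 UnderpoweredStudy (single-label), 3 multi-label
    Funding sentences."""
    out = []
    for i in range(65):
        out.append(make_sentence(f"The narrow patient spectrum {i} was a concern.",
                                 fine={"Population"}, article_id=f"P{i}"))
    for i in range(80):
        out.append(make_sentence(f"The small sample size {i} limited power.",
                                 fine={"SampleSize"}, article_id=f"U{i}"))
    for i in range(3):
        out.append(make_sentence(f"Funding gaps {i} and the small sample size hurt.",
                                 fine={"Funding", "SampleSize"}, article_id=f"F{i}"))
    return out


class TestPlan:
    def test_deficits_and_funding_ineligible(self):
        plan = build_plan(_training_set(), target=70)
        assert plan.classes["Population"].deficit == 5
        assert plan.classes["UnderpoweredStudy"].deficit == 0
        assert not plan.classes["Funding"].eligible

    def test_multi_label_excluded_from_seed_pools(self):
        plan = build_plan(_training_set(), target=70)
        # the 3 Funding/UnderpoweredStudy sentences count toward n but not seeds
        assert plan.classes["UnderpoweredStudy"].n == 83
        assert len(plan.classes["UnderpoweredStudy"].seed_ids) == 80

    def test_all_classes_at_target_no_deficit(self):
        train = [make_sentence(f"s{i}", fine={"Population"}, article_id=str(i))
                 for i in range(70)]
        plan = build_plan(train, target=70)
        assert plan.classes["Population"].deficit == 0
        assert plan.deficient() == []

    def test_class_with_only_multilabel_examples_flagged(self):
        train = [make_sentence("x", fine={"Setting", "Population"})] + \
            [make_sentence(f"y{i}", fine={"Population"}, article_id=str(i)) for i in range(70)]
        plan = build_plan(train, target=70)
        assert plan.classes["Setting"].deficit == 69
        assert plan.classes["Setting"].empty_seed_pool

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            build_plan([], target=70)


class TestOversample:
    def test_reaches_target_with_byte_identical_duplicates(self):
        train = _training_set()
        plan = build_plan(train, target=70)
        out = oversample(train, plan, seed=1)
        pop = [r for r in out if r.types_top == {"Population"}]
        assert len(pop) == 70
        originals = set(id(r) for r in train)
        for r in out:
            if id(r) not in originals:
                assert r in train  # duplicate of an original, unmodified

    def test_class_at_target_unchanged(self):
        train = _training_set()
        plan = build_plan(train, target=70)
        out = oversample(train, plan, seed=1)
        ups = [r for r in out if "UnderpoweredStudy" in r.types_top]
        assert len(ups) == 83  # untouched

    def test_originals_never_removed(self):
        train = _training_set()
        out = oversample(train, build_plan(train, target=70), seed=0)
        assert out[: len(train)] == train


class TestEda:
    def test_deterministic(self):
        a = eda_variants("the sample was small indeed", "Population", 5, seed=4)
        b = eda_variants("the sample was small indeed", "Population", 5, seed=4)
        assert a == b

    def test_label_preserved(self):
        for v in eda_variants("the small trial had bias", "Setting", 8, seed=2):
            assert v.intended_label == "Setting" and v.view == "eda"

    def test_full_deletion_leaves_one_word(self):
        # rate 1.0 deletion keeps at least one word
        found_deletion = False
        for seed in range(30):
            (v,) = eda_variants("the sample was small", "Population", 1,
                                rate=1.0, seed=seed)
            words = v.text.split()
            assert len(words) >= 1
            if len(words) == 1:
                found_deletion = True
        assert found_deletion

    def test_one_word_sentence_with_deletion_unchanged(self):
        for seed in range(20):
            (v,) = eda_variants("word", "Population", 1, rate=1.0, seed=seed)
            assert v.text in ("word",) or len(v.text.split()) >= 1

    def test_swap_on_two_words_reverses(self):
        seen = set()
        for seed in range(40):
            (v,) = eda_variants("alpha beta", "Population", 1, seed=seed)
            seen.add(v.text)
        assert "beta alpha" in seen  # the swap operator reverses the pair

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            eda_variants("  ", "Population", 1)


class TestRake:
    def test_degree_over_frequency_hand_example(self):
        out = rake_keywords("small sample size limited the statistical power",
                            stopwords=frozenset({"the"}))
        assert out[0] == ("small sample size limited", 16.0)
        assert out[1] == ("statistical power", 4.0)

    def test_single_word(self):
        assert rake_keywords("power", stopwords=frozenset({"the"})) == [("power", 1.0)]

    def test_empty_and_all_stopwords(self):
        assert rake_keywords("") == []
        assert rake_keywords("the of and", stopwords=frozenset({"the", "of", "and"})) == []

    def test_punctuation_splits_candidates(self):
        out = rake_keywords("small sample, low power", stopwords=frozenset())
        phrases = [p for p, _ in out]
        assert "small sample" in phrases and "low power" in phrases


class TestDualView:
    def _seed(self):
        return make_sentence("The small sample size limited the statistical power.",
                             fine={"SampleSize"})

    def test_exact_candidate_count(self):
        gen = TemplateGenerator(seed=0)
        out = generate_dual_view(self._seed(), gen, view="output_view")
        assert len(out) == DEFAULT_N_PER_SEED == 10
        assert all(s.intended_label == "UnderpoweredStudy" for s in out)

    def test_output_view_prompt_uses_label_not_seed_text(self):
        captured = {}

        def gen(prompt, count):
            captured["prompt"] = prompt
            return [f"c{i}" for i in range(count)]

        generate_dual_view(self._seed(), gen, view="output_view")
        assert captured["prompt"] == "UnderpoweredStudy"

    def test_input_view_prompt_uses_rake_keywords(self):
        captured = {}

        def gen(prompt, count):
            captured["prompt"] = list(prompt)
            return [f"c{i}" for i in range(count)]

        generate_dual_view(self._seed(), gen, view="input_view")
        assert any("sample" in p for p in captured["prompt"])

    def test_template_generator_deterministic(self):
        a = TemplateGenerator(seed=9)("Population", 10)
        b = TemplateGenerator(seed=9)("Population", 10)
        assert a == b and all(a)

    def test_wrong_count_contract_error(self):
        def broken(prompt, count):
            return ["only one"]

        with pytest.raises(GeneratorContractError):
            generate_dual_view(self._seed(), broken)

    def test_multi_label_seed_rejected(self):
        seed = make_sentence("x", fine={"Funding", "SampleSize"})
        with pytest.raises(ValueError, match="single-label"):
            generate_dual_view(seed, TemplateGenerator())


class TestConsistencyFilter:
    def _pool(self):
        return [
            SyntheticSample("a", "Population", "output_view"),
            SyntheticSample("b", "Setting", "output_view"),
            SyntheticSample("c", "Population", "output_view"),
        ]

    def test_oracle_filter_keeps_all(self):
        pool = self._pool()
        kept = consistency_filter(pool, lambda text: next(
            s.intended_label for s in pool if s.text == text))
        assert [s.text for s in kept] == ["a", "b", "c"]
        assert all(s.kept_by_filter for s in kept)

    def test_constant_filter_keeps_matching_only(self):
        kept = consistency_filter(self._pool(), lambda text: "Population")
        assert [s.intended_label for s in kept] == ["Population", "Population"]

    def test_matches_brute_force(self):
        pool = self._pool()
        fm = lambda text: "Setting" if text == "b" else "Other"
        kept = consistency_filter(pool, fm)
        expected = [s for s in pool if fm(s.text) == s.intended_label]
        assert [s.text for s in kept] == [s.text for s in expected]


class TestBalance:
    def test_exact_fill_arithmetic(self):
        train = [make_sentence(f"s{i}", fine={"Population"}, article_id=str(i))
                 for i in range(12)]
        plan = build_plan(train, target=70)
        pool = [SyntheticSample(f"p{i}", "Population", "output_view") for i in range(120)]
        out, warns = balance(train, plan, pool, seed=0)
        assert len(out) == 70 and not warns

    def test_shortfall_warned_not_fabricated(self):
        train = [make_sentence(f"s{i}", fine={"Population"}, article_id=str(i))
                 for i in range(12)]
        plan = build_plan(train, target=70)
        pool = [SyntheticSample(f"p{i}", "Population", "output_view") for i in range(30)]
        out, warns = balance(train, plan, pool, seed=0)
        assert len(out) == 42 and len(warns) == 1

    def test_deterministic_under_seed(self):
        train = _training_set()
        plan = build_plan(train, target=70)
        pool = [SyntheticSample(f"p{i}", "Population", "output_view") for i in range(50)]
        a, _ = balance(train, plan, pool, seed=3)
        b, _ = balance(train, plan, pool, seed=3)
        assert [r.text for r in a] == [r.text for r in b]

    def test_originals_untouched(self):
        train = _training_set()
        plan = build_plan(train, target=70)
        pool = [SyntheticSample(f"p{i}", "Population", "output_view") for i in range(50)]
        out, _ = balance(train, plan, pool, seed=3)
        assert out[: len(train)] == train
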