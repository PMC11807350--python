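"""Article/BRAT I/O, section selection, span projection, splits."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salnlp.corpus_io import (
    Article,
    BratParseError,
    Section,
    parse_brat,
    project_spans_to_sentences,
    read_articles,
    read_sentences,
    select_limitation_sections,
    split_corpus,
    to_document_frame,
    write_articles,
    write_sentences,
    SpanAnnotation,
    SentenceRecord,
)
from tests.conftest import make_sentence


def _rec(text, start=0, art="A1", sec=0):
    return SentenceRecord(
        article_id=art, section_index=sec, char_start=start,
        char_end=start + len(text), text=text,
        top_header="Discussion", innermost_header="",
    )


class TestParseBrat:
    DOC = "A tiny presmall sample here."  # [10:22] == "small sample"

    def test_single_text_bound_line(self, taxonomy):
        ann = "T1\tSampleSize 10 22\tsmall sample\n"
        spans = parse_brat(self.DOC, ann, taxonomy=taxonomy)
        assert len(spans) == 1
        sp = spans[0]
        assert (sp.char_start, sp.char_end, sp.category) == (10, 22, "SampleSize")

    def test_empty_annotation_text(self, taxonomy):
        assert parse_brat(self.DOC, "", taxonomy=taxonomy) == []

    def test_overlapping_spans_both_returned(self, taxonomy):
        ann = "T1\tSampleSize 10 22\tsmall sample\nT2\tPopulation 16 22\tsample\n"
        spans = parse_brat(self.DOC, ann, taxonomy=taxonomy)
        assert {s.category for s in spans} == {"SampleSize", "Population"}

    def test_surface_mismatch_names_line(self, taxonomy):
        ann = "T1\tSampleSize 10 22\twrong-surface\n"
        with pytest.raises(BratParseError, match="line 1"):
            parse_brat(self.DOC, ann, taxonomy=taxonomy)

    def test_unknown_label_rejected(self, taxonomy):
        ann = "T1\tNotALabel 10 22\tsmall sample\n"
        with pytest.raises(BratParseError, match="NotALabel"):
            parse_brat(self.DOC, ann, taxonomy=taxonomy)

    def test_offsets_outside_document(self, taxonomy):
        ann = "T1\tSampleSize 10 999\tx\n"
        with pytest.raises(BratParseError, match="outside"):
            parse_brat(self.DOC, ann, taxonomy=taxonomy)


class TestSectionSelection:
    def _article(self, headers):
        return Article(
            article_id="A",
            sections=[Section(h, "", "Body text.") for h in headers],
        )

    def test_keyword_sections_selected(self):
        art = self._article(["Introduction", "Methods", "Discussion", "Study Limitations"])
        assert select_limitation_sections(art) == [2, 3]

    def test_weakness_substring_matches(self):
        art = self._article(["Strengths and weaknesses"])
        assert select_limitation_sections(art) == [0]

    def test_abstract_always_included(self):
        art = self._article(["Abstract", "Results"])
        assert select_limitation_sections(art) == [0]
        assert select_limitation_sections(art, include_abstract=False) == []

    def test_innermost_header_also_consulted(self):
        art = Article("A", [Section("Back matter", "Caveats", "x.")])
        assert select_limitation_sections(art) == [0]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.sampled_from(["discussion", "LIMITATION", "Weakness", "ShortComing", "drawback"]),
           st.booleans())
    def test_case_insensitive(self, kw, upper):
        header = kw.upper() if upper else kw.lower()
        art = Article("A", [Section(header, "", "x.")])
        assert select_limitation_sections(art) == [0]


class TestProjection:
    def test_span_inside_sentence(self, taxonomy):
        sents = [_rec("First one here.", 0), _rec("Sample was small.", 16)]
        spans = [SpanAnnotation("A1", 23, 26, "SampleSize")]
        out = project_spans_to_sentences(sents, spans, taxonomy)
        assert out[0].types_fine == frozenset() and not out[0].is_sal
        assert out[1].types_fine == {"SampleSize"}
        assert out[1].types_top == {"UnderpoweredStudy"}

    def test_duplicate_spans_consolidated(self, taxonomy):
        sents = [_rec("Sample was small.", 0)]
        spans = [
            SpanAnnotation("A1", 0, 6, "SampleSize"),
            SpanAnnotation("A1", 11, 16, "SampleSize"),
        ]
        out = project_spans_to_sentences(sents, spans, taxonomy)
        assert out[0].types_fine == {"SampleSize"}

    def test_straddling_span_labels_both(self, taxonomy):
        sents = [_rec("One sentence.", 0), _rec("Two sentence.", 14)]
        spans = [SpanAnnotation("A1", 10, 18, "Population")]
        out = project_spans_to_sentences(sents, spans, taxonomy)
        assert out[0].types_fine == {"Population"} == out[1].types_fine

    def test_span_outside_document_errors(self, taxonomy):
        sents = [_rec("Short.", 0)]
        spans = [SpanAnnotation("A1", 2, 50, "Population")]
        with pytest.raises(ValueError, match="outside"):
            project_spans_to_sentences(sents, spans, taxonomy, document_length=6)

    def test_label_conservation(self, taxonomy, small_corpus):
        """Every span reaches at least one sentence."""
        for art in small_corpus.articles[:5]:
            gold = small_corpus.gold_for_article(art.article_id)
            doc_recs = to_document_frame(art, gold)
            spans = small_corpus.spans_by_article[art.article_id]
            out = project_spans_to_sentences(doc_recs, spans, taxonomy)
            labeled_pairs = {(r.char_start, l) for r in out for l in r.types_fine}
            assert len(labeled_pairs) <= len(spans) + len(spans)  # straddle bound
            for sp in spans:
                assert any(
                    r.char_start < sp.char_end and sp.char_start < r.char_end
                    and sp.category in r.types_fine
                    for r in out
                )


class TestSplit:
    def _articles(self, n):
        return [Article(f"A{i:03d}", [Section("Abstract", "", "x.")]) for i in range(n)]

    def test_published_split_sizes(self):
        tr, dev, test = split_corpus(self._articles(200), (0.6, 0.2, 0.2), seed=0)
        assert (len(tr), len(dev), len(test)) == (120, 40, 40)

    def test_small_exact_arithmetic(self):
        tr, dev, test = split_corpus(self._articles(10), (0.6, 0.2, 0.2), seed=5)
        assert (len(tr), len(dev), len(test)) == (6, 2, 2)

    def test_remainder_goes_to_train(self):
        tr, dev, test = split_corpus(self._articles(101), (0.6, 0.2, 0.2), seed=1)
        assert (len(tr), len(dev), len(test)) == (61, 20, 20)

    def test_deterministic_and_disjoint(self):
        arts = self._articles(50)
        a = split_corpus(arts, seed=9)
        b = split_corpus(arts, seed=9)
        assert [[x.article_id for x in part] for part in a] == [
            [x.article_id for x in part] for part in b
        ]
        ids = [x.article_id for part in a for x in part]
        assert len(ids) == len(set(ids)) == 50

    def test_too_few_articles(self):
        with pytest.raises(ValueError):
            split_corpus(self._articles(2), seed=0)


class TestJsonl:
    def test_sentence_round_trip(self, tmp_path):
        recs = [
            make_sentence("Sample was small.", fine={"SampleSize"}),
            make_sentence("Neutral text.", start=20),
        ]
        path = tmp_path / "s.jsonl"
        write_sentences(path, recs)
        assert read_sentences(path) == recs

    def test_missing_field_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"article_id": "A", "section_index": 0}\n')
        with pytest.raises(ValueError, match="line 1"):
            read_sentences(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_sentences(path) == []

    def test_article_round_trip(self, tmp_path, small_corpus):
        path = tmp_path / "a.jsonl"
        write_articles(path, small_corpus.articles[:5])
        back = read_articles(path)
        assert back == small_corpus.articles[:5]
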