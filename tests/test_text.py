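import pytest
from hypothesis import given, settings, strategies as st

from ontoextend.ontology import Ontology, OntologyClass, build_term_dictionary
from ontoextend.text import (
    AnnotatedCorpus,
    Document,
    annotate_corpus,
    annotate_mentions,
    normalize_mentions,
    preprocess,
)


def make_dictionary(entries: dict[str, set[str]]):
    from ontoextend.ontology import TermDictionary
    return TermDictionary(entries=entries)


class TestPreprocess:
    def test_stopwords_and_punctuation_removed(self):
        assert preprocess("The cat is here.").tokens == ["cat", "here"]

    def test_empty_input_gives_empty_document(self):
        assert preprocess("").tokens == []

    def test_intra_word_hyphen_survives(self):
        doc = preprocess("limb-shaking episodes - observed (rare).")
        assert doc.tokens == ["limb-shaking", "episodes", "observed", "rare"]

    def test_fixed_paragraph_matches_hand_tokenization(self):
        raw = ("In this study, we examined the clinical records of 40 "
               "patients; each patient was diagnosed with type-2 diabetes "
               "mellitus, and all of them were treated at a single center "
               "between 2001 and 2009 (inclusive). Outcomes varied.")
        expected = [
            "study", "examined", "clinical", "records", "40",
            "patients", "each", "patient", "diagnosed", "type-2",
            "diabetes", "mellitus", "all", "treated", "single",
            "center", "between", "2001", "2009", "inclusive",
            "outcomes", "varied",
        ]
        assert preprocess(raw).tokens == expected

    @settings(deadline=None, max_examples=50)
    @given(st.text(max_size=200))
    def test_output_is_clean(self, raw):
        from ontoextend.text import DEFAULT_STOPWORDS
        for tok in preprocess(raw).tokens:
            assert tok == tok.lower()
            assert tok not in DEFAULT_STOPWORDS
            assert " " not in tok and "." not in tok and "," not in tok
            assert not tok.startswith("-") and not tok.endswith("-")


class TestAnnotateMentions:
    def test_single_longest_match(self):
        d = make_dictionary({"diabetes mellitus": {"X"}})
        doc = Document("d", ["diabetes", "mellitus", "study"])
        anns = annotate_mentions(doc, d)
        assert len(anns) == 1
        assert (anns[0].start_token, anns[0].end_token) == (0, 2)
        assert anns[0].class_ids == {"X"}

    def test_longest_match_beats_prefix_entry(self):
        d = make_dictionary({"diabetes": {"X"}, "diabetes mellitus": {"Y"}})
        doc = Document("d", ["diabetes", "mellitus", "study"])
        anns = annotate_mentions(doc, d)
        assert len(anns) == 1
        assert anns[0].end_token == 2 and anns[0].class_ids == {"Y"}

    def test_no_match_returns_empty(self):
        d = make_dictionary({"cancer": {"X"}})
        assert annotate_mentions(Document("d", ["healthy", "cohort"]), d) == []

    def test_annotations_sorted_and_non_overlapping(self):
        d = make_dictionary({"a b": {"X"}, "b c": {"Y"}, "c": {"Z"}})
        doc = Document("d", ["a", "b", "c", "b", "c"])
        anns = annotate_mentions(doc, d)
        assert anns == sorted(anns)
        for first, second in zip(anns, anns[1:]):
            assert first.end_token <= second.start_token

    def test_generator_fixture_matches_placement_log(self, small_spec):
        """Every planted mention (including two-token nested-prefix forms)
        is recovered exactly, and nothing else fires."""
        from ontoextend.synthetic import generate_corpus, generate_ontology
        onto, truth = generate_ontology(small_spec)
        corpus = generate_corpus(onto, truth, small_spec)
        dictionary = build_term_dictionary(onto)
        annotated = annotate_corpus(corpus.as_documents(), dictionary)
        got = {(a.doc_id, a.start_token, a.end_token, a.surface)
               for a in annotated.annotations}
        expected = {(p.doc_id, p.start_token, p.end_token, p.surface)
                    for p in corpus.placements}
        assert got == expected
        by_span = {(a.doc_id, a.start_token): a.class_ids
                   for a in annotated.annotations}
        for p in corpus.placements:
            assert p.class_id in by_span[(p.doc_id, p.start_token)]

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.sampled_from("abcde"), max_size=30),
           st.sets(st.tuples(st.sampled_from("abcde"),
                             st.sampled_from("abcde")), max_size=8))
    def test_never_overlaps_on_random_input(self, tokens, bigrams):
        entries = {f"{x} {y}": {"ID:" + x + y} for x, y in bigrams}
        entries.update({x: {"ID:" + x} for x, _ in bigrams})
        if not entries:
            return
        anns = annotate_mentions(Document("d", tokens),
                                 make_dictionary(entries))
        for first, second in zip(anns, anns[1:]):
            assert first.end_token <= second.start_token


class TestNormalizeMentions:
    def _annotated(self):
        d = make_dictionary({"prediabetes syndrome": {"DOID:11716"}})
        docs = [Document("d", ["prediabetes", "syndrome", "patients"])]
        return annotate_corpus(docs, d)

    def test_span_replaced_by_identifier_token(self):
        normalized = normalize_mentions(self._annotated())
        assert normalized.documents[0].tokens == ["DOID:11716", "patients"]
        assert normalized.normalized

    def test_document_without_annotations_unchanged(self):
        corpus = AnnotatedCorpus(documents=[Document("d", ["x", "y"])])
        assert normalize_mentions(corpus).documents[0].tokens == ["x", "y"]

    def test_double_normalization_rejected(self):
        with pytest.raises(ValueError):
            normalize_mentions(normalize_mentions(self._annotated()))

    def test_ambiguous_span_takes_smallest_id(self):
        d = make_dictionary({"cancer": {"DOID:2", "DOID:1"}})
        corpus = annotate_corpus([Document("d", ["cancer"])], d)
        assert normalize_mentions(corpus).documents[0].tokens == ["DOID:1"]

    def test_token_count_identity_and_mention_counts(self, small_spec):
        """Normalization shrinks each document by exactly sum(span - 1),
        and yields exactly mentions_per_class identifier tokens per class."""
        from ontoextend.synthetic import generate_corpus, generate_ontology
        onto, truth = generate_ontology(small_spec)
        corpus = generate_corpus(onto, truth, small_spec)
        dictionary = build_term_dictionary(onto)
        annotated = annotate_corpus(corpus.as_documents(), dictionary)
        normalized = normalize_mentions(annotated)
        for before, after in zip(annotated.documents, normalized.documents):
            shrink = sum(a.end_token - a.start_token - 1
                         for a in annotated.annotations
                         if a.doc_id == before.doc_id)
            assert len(after.tokens) == len(before.tokens) - shrink
        counts: dict[str, int] = {}
        for doc in normalized.documents:
            for t in doc.tokens:
                if t.startswith("SYN:"):
                    counts[t] = counts.get(t, 0) + 1
        for leaf in truth:
            assert counts[leaf] == small_spec.mentions_per_class

    def test_reannotation_of_normalized_corpus_finds_nothing(self):
        d = make_dictionary({"prediabetes syndrome": {"DOID:11716"}})
        normalized = normalize_mentions(self._annotated())
        assert annotate_mentions(normalized.documents[0], d) == []
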