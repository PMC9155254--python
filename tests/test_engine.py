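"""Difficult-span detection, candidate ranking, rules, edits and replay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simpedit import engine
from simpedit.core_text import tokenize
from simpedit.resources import (EmbeddingTable, FrequencyLexicon,
                                SentenceRule, SubstitutionLexicon)


def small_freq():
    entries = {f"common{i}": 10_000 for i in range(20)}
    entries.update({"utilize": 10, "the": 10_000, "we": 10_000})
    return FrequencyLexicon(entries)


def small_subs():
    return SubstitutionLexicon(entries={"utilize": ["use"],
                                        "common1": ["ordinary"]})


class TestDetection:
    def test_empty_document_flags_nothing(self):
        assert engine.detect_difficult_spans(
            tokenize(""), small_freq(), small_subs(), 0.5) == []

    def test_rare_word_flagged_common_not(self):
        """Brute-force threshold check: at level 0.5 the median count is
        10000, so only the frequency-10 word with a candidate is flagged."""
        doc = tokenize("We utilize common1 daily.")
        sugg = engine.detect_difficult_spans(doc, small_freq(), small_subs(), 0.5)
        assert [s.surface for s in sugg] == ["utilize"]
        assert sugg[0].candidates == [("use", None)]

    def test_flagged_span_count_monotone_in_level(self, toy_original_doc,
                                                  freq_lex, subs_lex):
        counts = [len(engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, lvl))
            for lvl in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts)

    def test_multiword_phrase_longest_match(self, toy_original_doc,
                                            freq_lex, subs_lex):
        surfaces = [s.surface.lower() for s in engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, 0.9)]
        assert "adverse effects" in surfaces
        assert "adverse" not in surfaces        # consumed by the longer match

    def test_flagged_spans_do_not_overlap(self, toy_original_doc,
                                          freq_lex, subs_lex):
        sugg = engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, 1.0)
        spans = sorted((s.start, s.end) for s in sugg)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_level_out_of_range_rejected(self, toy_original_doc,
                                         freq_lex, subs_lex):
        with pytest.raises(ValueError):
            engine.detect_difficult_spans(toy_original_doc, freq_lex,
                                          subs_lex, 1.5)


class TestCandidateRanking:
    def test_collinear_candidate_outranks_orthogonal(self):
        """Hand-built vectors: candidate A parallel to the context scores
        1.0, candidate B orthogonal scores 0.0."""
        emb = EmbeddingTable(dimension=2, vectors={
            "context": np.array([1.0, 0.0]),
            "parallel": np.array([2.0, 0.0]),
            "orthogonal": np.array([0.0, 3.0]),
        })
        subs = SubstitutionLexicon(entries={"hard": ["orthogonal", "parallel"]})
        doc = tokenize("Context hard.")
        freq = FrequencyLexicon({"context": 100, "hard": 1, "filler": 100})
        sugg = engine.detect_difficult_spans(doc, freq, subs, 1.0)
        ranked = engine.suggest_candidates(doc, sugg[0], subs, emb, 1.0)
        assert [c for c, _ in ranked] == ["parallel", "orthogonal"]
        assert ranked[0][1] == pytest.approx(1.0)
        assert ranked[1][1] == pytest.approx(0.0)

    def test_minimum_variety_shows_exactly_one(self, toy_original_doc,
                                               freq_lex, subs_lex, emb_table):
        sugg = engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, 0.5)
        subsequent = next(s for s in sugg if s.surface.lower() == "subsequent")
        assert len(engine.suggest_candidates(
            toy_original_doc, subsequent, subs_lex, emb_table, 0.0)) == 1

    def test_maximum_variety_shows_all_three(self, toy_original_doc,
                                             freq_lex, subs_lex, emb_table):
        sugg = engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, 0.5)
        subsequent = next(s for s in sugg if s.surface.lower() == "subsequent")
        ranked = engine.suggest_candidates(
            toy_original_doc, subsequent, subs_lex, emb_table, 1.0)
        assert len(ranked) == 3
        scores = [sc for _, sc in ranked if sc is not None]
        assert scores == sorted(scores, reverse=True)

    def test_candidate_count_monotone_in_variety(self, toy_original_doc,
                                                 freq_lex, subs_lex, emb_table):
        sugg = engine.detect_difficult_spans(
            toy_original_doc, freq_lex, subs_lex, 0.5)
        subsequent = next(s for s in sugg if s.surface.lower() == "subsequent")
        lens = [len(engine.suggest_candidates(
            toy_original_doc, subsequent, subs_lex, emb_table, v))
            for v in (0.0, 0.3, 0.6, 1.0)]
        assert lens == sorted(lens)

    def test_out_of_vocabulary_candidate_keeps_lexicon_order(self):
        emb = EmbeddingTable(dimension=2, vectors={})
        subs = SubstitutionLexicon(entries={"hard": ["first", "second"]})
        doc = tokenize("Context hard.")
        freq = FrequencyLexicon({"context": 100, "hard": 1, "x": 100})
        sugg = engine.detect_difficult_spans(doc, freq, subs, 1.0)
        ranked = engine.suggest_candidates(doc, sugg[0], subs, emb, 1.0)
        assert ranked == [("first", None), ("second", None)]

    def test_determinism(self, toy_original_doc, freq_lex, subs_lex, emb_table):
        runs = []
        for _ in range(2):
            sugg = engine.detect_difficult_spans(
                toy_original_doc, freq_lex, subs_lex, 0.7)
            runs.append([(s.surface, engine.suggest_candidates(
                toy_original_doc, s, subs_lex, emb_table, 0.7)) for s in sugg])
        assert runs[0] == runs[1]


class TestSentenceRules:
    def test_no_rules_no_suggestions(self, toy_original_doc):
        assert engine.match_sentence_rules(toy_original_doc, []) == []

    def test_literal_duration_rule_fires_on_its_span(self, toy_original_doc,
                                                     rule_catalog):
        hits = engine.match_sentence_rules(toy_original_doc, rule_catalog)
        duration = [s for s in hits if s.rule_id == "duration-phrase"]
        assert len(duration) == 1
        assert duration[0].surface == "months or years"
        assert duration[0].guidance and duration[0].example

    def test_nominalization_rule_fires_on_nominalization_only(self, rule_catalog):
        nom = next(r for r in rule_catalog if r.id == "nominalization")
        hit = engine.match_sentence_rules(
            tokenize("The utilization of inhalers grew."), [nom])
        miss = engine.match_sentence_rules(
            tokenize("People use inhalers."), [nom])
        assert len(hit) == 1 and hit[0].surface.lower() == "utilization of"
        assert miss == []

    def test_one_suggestion_per_sentence_rule_pair(self, rule_catalog):
        doc = tokenize("Utilization of X. Consumption of Y.")
        nom = [r for r in rule_catalog if r.id == "nominalization"]
        assert len(engine.match_sentence_rules(doc, nom)) == 2


class TestEditsAndReplay:
    def test_identity_edit_leaves_text_unchanged(self, toy_original_doc):
        doc = toy_original_doc
        new = engine.apply_edit(doc, 0, 6, doc.text[0:6])
        assert new.text == doc.text

    def test_replacement_updates_text_and_tokens(self):
        doc = tokenize("It was subsequent to that.")
        start = doc.text.index("subsequent")
        new = engine.apply_edit(doc, start, start + len("subsequent"),
                                "followed by")
        assert "followed by" in new.text
        assert len(new.word_tokens()) == len(doc.word_tokens()) + 1

    def test_stale_version_rejected(self):
        doc = tokenize("Some text here.")
        with pytest.raises(engine.StaleSpanError):
            engine.apply_edit(doc, 0, 4, "More", expected_version="000000000000")

    def test_tampered_log_rejected(self):
        doc = tokenize("Alpha beta gamma.")
        log = engine.EditLog(original_text=doc.text)
        log, doc = engine.log_event(log, doc, 0, 5, "Delta", timestamp=0.0)
        bad = engine.EditLog(original_text="Different original.",
                             events=list(log.events))
        with pytest.raises(engine.StaleSpanError):
            engine.replay(bad)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 10),
                              st.text(alphabet="abc XYZ.", max_size=8)),
                    max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_replay_reproduces_final_text(self, edits):
        """Replaying the event log over the original text reproduces the
        final text for arbitrary edit sequences."""
        doc = tokenize("The patient may utilize an inhaler daily.")
        log = engine.EditLog(original_text=doc.text)
        for offset, length, replacement in edits:
            start = min(offset, len(doc.text))
            end = min(start + length, len(doc.text))
            log, doc = engine.log_event(log, doc, start, end, replacement,
                                        timestamp=0.0)
        assert engine.replay(log) == doc.text
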