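"""The measurement vector behind the editor's "Statistics" tab and the
original-vs-simplified comparison report.

For one document: word count, sentence count, mean sentence length, exact
lexical chain count, verb and noun counts, average corpus frequency of
in-lexicon words (a lexical-difficulty proxy — higher means more common,
simpler words), and the Flesch-Kincaid grade.  A comparison report pairs
the original and simplified vectors with per-field percent change, rounded
half-away-from-zero to one decimal, matching how such tables are printed.

Out-of-lexicon words are excluded from the average frequency (the
alternative, counting them as zero, would let lexicon coverage dominate the
statistic); the attained coverage is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .chains import build_chains
from .core_text import Document, flesch_kincaid
from .resources import FrequencyLexicon

__all__ = ["TextStats", "ComparisonReport", "compute_stats", "compare",
           "percent_change"]

#: fields compared in the report, in display order
_COMPARED_FIELDS = ("word_count", "sentence_count", "mean_sentence_length",
                    "exact_chain_count", "verb_count", "noun_count",
                    "avg_word_frequency", "flesch_kincaid_grade")


@dataclass
class TextStats:
    word_count: int
    sentence_count: int
    mean_sentence_length: float
    exact_chain_count: int
    verb_count: int
    noun_count: int
    avg_word_frequency: float | None   # None when no word is in the lexicon
    lexicon_coverage: float            # fraction of word tokens in the lexicon
    flesch_kincaid_grade: float


@dataclass
class ComparisonReport:
    original: TextStats
    simplified: TextStats
    #: field -> percent change (1 decimal); absent when undefined (original 0
    #: or either side missing)
    percent_change: dict[str, float]


def percent_change(original: float, new: float) -> float | None:
    """``(new - original) / original * 100`` rounded half-away-from-zero to
    one decimal; None when the original is zero."""
    if original == 0:
        return None
    raw = (new - original) / original * 100.0
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
                 if raw >= 0 else
                 -Decimal(repr(-raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_stats(doc: Document, freq: FrequencyLexicon) -> TextStats:
    """Compute the full statistics vector for one document."""
    words = doc.word_tokens()
    if not words:
        raise ValueError("compute_stats requires a document with at least one word")
    n_sent = sum(
        1 for s in doc.sentences
        if any(doc.tokens[i].is_word for i in range(s.first, s.last)))
    in_lex = [freq.get(t.surface) for t in words if t.surface.lower() in freq]
    return TextStats(
        word_count=len(words),
        sentence_count=n_sent,
        mean_sentence_length=len(words) / n_sent,
        exact_chain_count=len(build_chains(doc, "EXACT")),
        verb_count=sum(1 for t in words if t.pos == "VERB"),
        noun_count=sum(1 for t in words if t.pos == "NOUN"),
        avg_word_frequency=(sum(in_lex) / len(in_lex)) if in_lex else None,
        lexicon_coverage=len(in_lex) / len(words),
        flesch_kincaid_grade=flesch_kincaid(doc),
    )


def compare(original: TextStats, simplified: TextStats) -> ComparisonReport:
    """Original-vs-simplified report with per-field percent changes."""
    changes: dict[str, float] = {}
    for name in _COMPARED_FIELDS:
        o, s = getattr(original, name), getattr(simplified, name)
        if o is None or s is None:
            continue
        pc = percent_change(o, s)
        if pc is not None:
            changes[name] = pc
    return ComparisonReport(original=original, simplified=simplified,
                            percent_change=changes)
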