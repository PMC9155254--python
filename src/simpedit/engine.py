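"""The editor core: flag difficult spans, rank substitutions in context,
match sentence-structure rules, apply edits and log them.

The engine mirrors an interactive simplification editor.  Word-level
suggestions flag spans that (a) carry a known substitution and (b) are rare
under the frequency lexicon — the rarity cutoff is the *simplification
level* slider, interpreted as a quantile of the lexicon's count
distribution, so raising the slider flags more (rarer and less rare) words.
Candidates for a flagged span are ranked by a word-embedding context filter:
the cosine between a candidate's (mean) vector and the mean vector of the
other words in the sentence.  The *variety level* slider controls how many
ranked candidates are shown.  All suggestions are advisory; nothing is
replaced without an explicit edit, and every edit is logged so the final
text can be reproduced by replaying the log over the original.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

from .core_text import Document, tokenize
from .resources import (EmbeddingTable, FrequencyLexicon, SentenceRule,
                        SubstitutionLexicon)

__all__ = [
    "Suggestion", "EditEvent", "EditLog", "StaleSpanError",
    "detect_difficult_spans", "suggest_candidates", "match_sentence_rules",
    "apply_edit", "log_event", "replay", "document_version",
    "variety_to_k", "VARIETY_K",
]

#: Candidate-list sizes per variety-level quartile.
VARIETY_K = (1, 3, 5, 8)


@dataclass
class Suggestion:
    kind: str                      # "WORD" or "SENTENCE"
    token_first: int               # token index range [first, last)
    token_last: int
    start: int                     # character range [start, end)
    end: int
    surface: str
    candidates: list[tuple[str, float | None]] = field(default_factory=list)
    rule_id: str | None = None
    guidance: str | None = None
    example: str | None = None

    def __post_init__(self):
        if self.kind == "WORD" and not self.candidates:
            raise ValueError("WORD suggestion requires candidates")
        if self.kind == "SENTENCE" and not self.guidance:
            raise ValueError("SENTENCE suggestion requires guidance")


@dataclass(frozen=True)
class EditEvent:
    """One replacement: characters ``[start, end)`` of the version
    ``version_before`` replaced by ``replacement``."""

    start: int
    end: int
    old: str
    replacement: str
    version_before: str
    version_after: str
    timestamp: float = 0.0


@dataclass
class EditLog:
    """Append-only record of a simplification session."""

    original_text: str
    events: list[EditEvent] = field(default_factory=list)


class StaleSpanError(ValueError):
    """An edit referenced a document version that is no longer current."""


def document_version(text: str) -> str:
    return hashlib.sha1(text.encode("utf-8")).hexdigest()[:12]


def _phrase_frequency(words: list[str], freq: FrequencyLexicon) -> int:
    """Frequency of a (possibly multiword) phrase: minimum token frequency."""
    return min(freq.get(w) for w in words)


def detect_difficult_spans(doc: Document, freq: FrequencyLexicon,
                           subs: SubstitutionLexicon,
                           simplification_level: float = 0.5) -> list[Suggestion]:
    """Flag difficult word/phrase spans.

    A span is flagged iff it is the leftmost-longest match of a phrase in
    the substitution lexicon *and* its frequency (minimum token frequency
    for multiword phrases; 0 for out-of-lexicon words) falls strictly below
    the ``simplification_level``-quantile of the frequency lexicon's count
    distribution.  Flagged spans never overlap; the flagged count is
    nondecreasing in the level.  Candidates are attached in lexicon order,
    unranked (ranking is :func:`suggest_candidates`' job).
    """
    if not 0.0 <= simplification_level <= 1.0:
        raise ValueError("simplification_level must be in [0, 1]")
    threshold = freq.quantile(simplification_level)
    word_idx = [i for i, t in enumerate(doc.tokens) if t.is_word]
    max_len = subs.max_phrase_tokens()
    out: list[Suggestion] = []
    pos = 0
    while pos < len(word_idx):
        hit_len = 0
        hit_phrase = None
        for length in range(min(max_len, len(word_idx) - pos), 0, -1):
            words = [doc.tokens[word_idx[pos + k]].surface.lower()
                     for k in range(length)]
            phrase = " ".join(words)
            if phrase in subs and _phrase_frequency(words, freq) < threshold:
                hit_len, hit_phrase = length, phrase
                break
        if hit_phrase is None:
            pos += 1
            continue
        first_tok = word_idx[pos]
        last_tok = word_idx[pos + hit_len - 1] + 1
        start = doc.tokens[first_tok].start
        end = doc.tokens[last_tok - 1].end
        out.append(Suggestion(
            kind="WORD", token_first=first_tok, token_last=last_tok,
            start=start, end=end, surface=doc.text[start:end],
            candidates=[(c, None) for c in subs.candidates(hit_phrase)]))
        pos += hit_len
    return out


def variety_to_k(variety_level: float) -> int:
    """Map the variety slider in [0,1] to a candidate-list size (1, 3, 5 or 8)."""
    if not 0.0 <= variety_level <= 1.0:
        raise ValueError("variety_level must be in [0, 1]")
    return VARIETY_K[min(3, int(variety_level * 4))]


def suggest_candidates(doc: Document, suggestion: Suggestion,
                       subs: SubstitutionLexicon, emb: EmbeddingTable,
                       variety_level: float = 0.5) -> list[tuple[str, float | None]]:
    """Rank a flagged span's candidates by context fit and truncate by variety.

    The context vector is the mean embedding of the *other* word tokens in
    the span's sentence; a multiword candidate's vector is the mean of its
    word vectors.  Candidates are sorted by cosine to the context,
    descending, ties (and unscorable candidates) keeping lexicon order;
    unscorable candidates sort after scored ones with score ``None``.  The
    list is truncated to ``k(variety_level)`` entries, ``k >= 1``.
    """
    phrase = " ".join(w.lower() for w in suggestion.surface.split())
    cands = subs.candidates(phrase)
    if not cands:
        cands = [c for c, _ in suggestion.candidates]
    sent = doc.sentence_of(suggestion.token_first)
    context_words = []
    if sent is not None:
        for i in range(sent.first, sent.last):
            t = doc.tokens[i]
            if t.is_word and not (suggestion.token_first <= i < suggestion.token_last):
                context_words.append(t.surface.lower())
    context_vec = emb.mean_vector(context_words)

    scored: list[tuple[str, float | None]] = []
    for cand in cands:
        cand_vec = emb.mean_vector(cand.lower().split())
        score = emb.cosine(cand_vec, context_vec) \
            if (cand_vec is not None and context_vec is not None) else None
        scored.append((cand, score))
    order = sorted(range(len(scored)),
                   key=lambda i: (scored[i][1] is None,
                                  -(scored[i][1] or 0.0), i))
    k = variety_to_k(variety_level)
    return [scored[i] for i in order[:k]]


def match_sentence_rules(doc: Document,
                         rules: list[SentenceRule]) -> list[Suggestion]:
    """One SENTENCE suggestion per (sentence, matching rule).

    Each rule's pattern is searched case-insensitively in every sentence's
    text; a match yields a suggestion on the matched span carrying the
    rule's fixed guidance and example (examples are generic, not adapted to
    the text).
    """
    out: list[Suggestion] = []
    for span in doc.sentences:
        word_first = next((i for i in range(span.first, span.last)
                           if doc.tokens[i].is_word), None)
        if word_first is None:
            continue
        sent_start = doc.tokens[span.first].start
        sent_text = doc.sentence_text(span)
        for rule in rules:
            m = next(iter(rule.finditer(sent_text)), None)
            if m is None:
                continue
            start, end = sent_start + m.start(), sent_start + m.end()
            toks = [i for i in range(span.first, span.last)
                    if doc.tokens[i].end > start and doc.tokens[i].start < end]
            out.append(Suggestion(
                kind="SENTENCE",
                token_first=toks[0] if toks else span.first,
                token_last=(toks[-1] + 1) if toks else span.last,
                start=start, end=end, surface=doc.text[start:end],
                rule_id=rule.id, guidance=rule.guidance, example=rule.example))
    return out


def apply_edit(doc: Document, start: int, end: int, replacement: str,
               expected_version: str | None = None) -> Document:
    """Replace characters ``[start, end)`` and re-tokenize.

    If ``expected_version`` is given and does not match the current
    document, a :class:`StaleSpanError` is raised (the span belongs to an
    outdated version and its offsets cannot be trusted).
    """
    if expected_version is not None and expected_version != document_version(doc.text):
        raise StaleSpanError(
            f"edit targets version {expected_version}, document is "
            f"{document_version(doc.text)}")
    if not (0 <= start <= end <= len(doc.text)):
        raise ValueError(f"span [{start}, {end}) outside document of length {len(doc.text)}")
    return tokenize(doc.text[:start] + replacement + doc.text[end:])


def log_event(log: EditLog, doc: Document, start: int, end: int,
              replacement: str, timestamp: float | None = None
              ) -> tuple[EditLog, Document]:
    """Apply an edit and append the corresponding event to the session log."""
    before = document_version(doc.text)
    new_doc = apply_edit(doc, start, end, replacement, expected_version=before)
    event = EditEvent(start=start, end=end, old=doc.text[start:end],
                      replacement=replacement, version_before=before,
                      version_after=document_version(new_doc.text),
                      timestamp=time.time() if timestamp is None else timestamp)
    log.events.append(event)
    return log, new_doc


def replay(log: EditLog) -> str:
    """Re-apply every logged event over the original text; returns the final text.

    Version hashes are checked at each step, so a tampered or re-ordered log
    raises :class:`StaleSpanError` instead of silently producing a different
    document.
    """
    text = log.original_text
    for ev in log.events:
        if document_version(text) != ev.version_before:
            raise StaleSpanError(
                f"replay expected version {ev.version_before}, have "
                f"{document_version(text)}")
        if text[ev.start:ev.end] != ev.old:
            raise StaleSpanError("logged span content does not match document")
        text = text[:ev.start] + ev.replacement + text[ev.end:]
        if document_version(text) != ev.version_after:
            raise StaleSpanError("replayed edit produced an unexpected version")
    return text
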