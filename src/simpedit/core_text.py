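"""Text substrate: tokenization, sentence splitting, coarse POS tags, syllables,
Flesch-Kincaid grade.

Everything downstream (difficult-word detection, lexical chains, text
statistics, recall scoring) operates on the :class:`Document` produced here.
The tokenizer is a deterministic rule system — Unicode word boundaries,
hyphenated/apostrophe forms kept as single tokens — so that every count the
package reports is reproducible without a trained model.  The part-of-speech
tagger is likewise a small heuristic (closed-class lists plus suffix and
context rules) mapping onto a six-tag coarse set; it is adequate for
noun/verb counts and noun chaining on encyclopedic prose, not a general
tagger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Token",
    "SentenceSpan",
    "Document",
    "tokenize",
    "count_syllables",
    "flesch_kincaid",
    "coarse_pos",
]

# --- token patterns -------------------------------------------------------

# A word: alphanumeric runs, optionally glued by internal hyphens/apostrophes
# ("self-report", "don't", "patient's").
_WORD_RE = re.compile(r"\w+(?:['’\-]\w+)*", re.UNICODE)
# Anything else that is not whitespace is punctuation/symbols.
_PUNCT_RE = re.compile(r"[^\w\s]+", re.UNICODE)

_SENT_TERMINAL = {".", "!", "?", "...", "?!", "!?"}

#: Abbreviations whose trailing period does not end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "prof", "e.g", "i.e", "vs", "etc", "fig",
     "al", "no", "st", "eg", "ie", "cf", "approx"}
)

# --- coarse POS -----------------------------------------------------------

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "some",
                "any", "no", "each", "every", "either", "neither", "both",
                "all", "such", "its", "his", "her", "their", "our", "my",
                "your"}
_PREPOSITIONS = {"of", "in", "on", "at", "by", "for", "with", "about",
                 "against", "between", "into", "through", "during", "before",
                 "after", "above", "below", "to", "from", "up", "down",
                 "over", "under", "than", "as", "without", "within", "upon",
                 "among", "per", "via", "toward", "towards"}
_CONJUNCTIONS = {"and", "or", "but", "nor", "so", "yet", "if", "because",
                 "while", "although", "though", "since", "unless", "whereas",
                 "when", "where", "whether", "that", "which", "who", "whom",
                 "whose", "what", "how", "why"}
_PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "me", "him",
             "them", "us", "himself", "herself", "itself", "themselves",
             "someone", "anyone", "everyone", "something", "anything",
             "nothing", "one", "there"}
_MODALS = {"can", "could", "may", "might", "must", "shall", "should",
           "will", "would", "not", "n't"}
_AUX_VERBS = {"is", "are", "was", "were", "be", "been", "being", "am",
              "has", "have", "had", "having", "do", "does", "did", "doing"}
# Frequent verbs whose form gives no suffix cue.
_COMMON_VERBS = {"say", "said", "says", "get", "got", "make", "made", "go",
                 "went", "gone", "know", "knew", "known", "take", "took",
                 "taken", "see", "saw", "seen", "come", "came", "think",
                 "thought", "look", "want", "give", "gave", "given", "use",
                 "used", "uses", "find", "found", "tell", "told", "ask",
                 "asked", "work", "seem", "feel", "felt", "try", "tried",
                 "leave", "left", "call", "called", "become", "became",
                 "include", "includes", "included", "occur", "occurs",
                 "occurred", "cause", "causes", "caused", "lead", "leads",
                 "led", "affect", "affects", "affected", "help", "helps",
                 "helped", "need", "needs", "needed", "begin", "begins",
                 "began", "begun", "start", "starts", "started", "sat",
                 "sit", "sits", "ran", "run", "runs", "slept", "sleep",
                 "sleeps", "eat", "ate", "eaten", "drink", "drank",
                 "develop", "develops", "developed", "treat", "treats",
                 "treated", "reduce", "reduces", "reduced", "improve",
                 "improves", "improved", "remain", "remains", "remained",
                 "keep", "kept", "show", "shows", "showed", "shown"}
_COMMON_ADJECTIVES = {"good", "new", "first", "last", "long", "great",
                      "little", "own", "other", "old", "right", "big",
                      "high", "small", "large", "young", "important", "few",
                      "bad", "same", "able", "common", "severe", "chronic",
                      "acute", "simple", "difficult", "easy", "many", "most",
                      "more", "less", "low", "early", "late", "short",
                      "several", "main", "certain", "possible", "likely"}
_COMMON_ADVERBS = {"very", "also", "often", "always", "never", "sometimes",
                   "again", "here", "too", "well", "then", "now", "just",
                   "even", "still", "however", "perhaps", "rather", "quite",
                   "almost", "already", "soon", "together", "away", "back",
                   "only", "usually", "typically"}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "less", "ish",
                 "ary", "ic", "ical", "ant", "ent")
_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ism", "ance",
                  "ence", "ship", "hood", "itis", "osis", "logy", "gram",
                  "graph", "ia")
_ADV_SUFFIX = "ly"
_VERB_SUFFIXES = ("ize", "ise", "ify", "ate", "izes", "ises", "ifies",
                  "ates", "ized", "ised", "ified", "ated", "izing", "ising",
                  "ifying", "ating")


@dataclass(frozen=True)
class Token:
    """One token with character offsets into the source text.

    ``pos`` is one of ``NOUN, VERB, ADJ, ADV, OTHER, PUNCT``; ``is_word`` is
    true only for tokens with alphabetic content (so numbers and punctuation
    never enter word counts).
    """

    surface: str
    lemma: str
    pos: str
    start: int
    end: int
    is_word: bool


@dataclass(frozen=True)
class SentenceSpan:
    """Token-index range of one sentence: inclusive ``first``, exclusive ``last``."""

    first: int
    last: int


@dataclass
class Document:
    text: str
    tokens: list[Token] = field(default_factory=list)
    sentences: list[SentenceSpan] = field(default_factory=list)

    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]

    def sentence_text(self, span: SentenceSpan) -> str:
        first, last = self.tokens[span.first], self.tokens[span.last - 1]
        return self.text[first.start:last.end]

    def sentence_of(self, token_index: int) -> SentenceSpan | None:
        for s in self.sentences:
            if s.first <= token_index < s.last:
                return s
        return None


def _lemma(surface: str, pos: str) -> str:
    w = surface.lower()
    if pos != "NOUN" or len(w) < 4:
        return w
    # crude depluralization; enough to chain "month"/"months"
    if w.endswith("ies"):
        return w[:-3] + "y"
    if w.endswith(("ches", "shes", "sses", "xes", "zes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def coarse_pos(surface: str, prev: str | None = None) -> str:
    """Heuristic coarse tag for a word token given the previous word (lowercased)."""
    w = surface.lower()
    if not any(c.isalpha() for c in w):
        return "OTHER"
    if w in _AUX_VERBS or w in _COMMON_VERBS:
        return "VERB"
    if (w in _DETERMINERS or w in _PREPOSITIONS or w in _CONJUNCTIONS
            or w in _PRONOUNS or w in _MODALS):
        return "OTHER"
    if w in _COMMON_ADVERBS:
        return "ADV"
    if w in _COMMON_ADJECTIVES:
        return "ADJ"
    if w.endswith(_ADV_SUFFIX) and len(w) > 4 and not w.endswith(("ply", "aly")):
        return "ADV"
    if w.endswith(_NOUN_SUFFIXES):
        return "NOUN"
    if w.endswith(_VERB_SUFFIXES) and len(w) > 4:
        return "VERB"
    if w.endswith(_ADJ_SUFFIXES) and len(w) > 4:
        return "ADJ"
    if prev == "to" and not w.endswith("s"):
        return "VERB"
    if w.endswith(("ed", "ing")) and len(w) > 4 and prev not in _DETERMINERS:
        return "VERB"
    return "NOUN"


def _raw_tokens(text: str) -> list[tuple[str, int, int, bool]]:
    out: list[tuple[str, int, int, bool]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        m = _WORD_RE.match(text, i)
        if m is None:
            m = _PUNCT_RE.match(text, i)
        if m is None:  # pragma: no cover - every non-space char matches one class
            i += 1
            continue
        surf = m.group(0)
        is_word = any(c.isalpha() for c in surf)
        out.append((surf, m.start(), m.end(), is_word))
        i = m.end()
    return out


def tokenize(text: str,
             abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS) -> Document:
    """Tokenize and sentence-split ``text`` into a :class:`Document`.

    Sentences end at terminal punctuation (``. ! ?``) followed by an
    uppercase-initial token or end of text, unless the preceding word is a
    known abbreviation.  Empty input yields an empty Document.
    """
    abbrev = {a.lower().rstrip(".") for a in abbreviations}
    raw = _raw_tokens(text)
    tokens: list[Token] = []
    prev_word: str | None = None
    for surf, start, end, is_word in raw:
        if is_word:
            pos = coarse_pos(surf, prev_word)
            prev_word = surf.lower()
        else:
            pos = "PUNCT" if _PUNCT_RE.fullmatch(surf) else "OTHER"
        tokens.append(Token(surface=surf, lemma=_lemma(surf, pos), pos=pos,
                            start=start, end=end, is_word=is_word))

    sentences: list[SentenceSpan] = []
    sent_start = 0
    for i, tok in enumerate(tokens):
        if tok.pos != "PUNCT" or not set(tok.surface) & set(".!?"):
            continue
        # abbreviation guard: "Dr." etc. does not terminate
        if "." in tok.surface and i > 0:
            prev = tokens[i - 1]
            if prev.is_word and prev.surface.lower() in abbrev:
                continue
        nxt = next((t for t in tokens[i + 1:] if t.is_word), None)
        if nxt is None or nxt.surface[:1].isupper() or nxt.surface[:1].isdigit():
            # close the sentence after any trailing quotes/brackets
            j = i + 1
            while j < len(tokens) and tokens[j].pos == "PUNCT" \
                    and not set(tokens[j].surface) & set(".!?"):
                j += 1
            if sent_start < j:
                sentences.append(SentenceSpan(sent_start, j))
                sent_start = j
    if sent_start < len(tokens):
        sentences.append(SentenceSpan(sent_start, len(tokens)))
    return Document(text=text, tokens=tokens, sentences=sentences)


_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Syllables of an alphabetic word by the vowel-group heuristic.

    Maximal runs of ``aeiouy`` are counted; a silent final ``e`` is dropped
    unless it carries the only vowel group; the result is at least 1.
    Raises ``ValueError`` on non-alphabetic input.
    """
    if not word or not word.replace("-", "").replace("'", "").isalpha():
        raise ValueError(f"count_syllables expects an alphabetic word, got {word!r}")
    w = word.lower()
    total = 0
    for part in re.split(r"[-']", w):
        if not part:
            continue
        groups = _VOWEL_GROUP_RE.findall(part)
        n = len(groups)
        if n > 1 and part.endswith("e") and not part.endswith(("ee", "le", "ye")):
            n -= 1
        total += max(1, n)
    return max(1, total)


def flesch_kincaid(doc: Document) -> float:
    """Flesch-Kincaid *grade level*: ``0.39 W/S + 11.8 Syl/W − 15.59``.

    ``W`` = word tokens, ``S`` = sentences containing at least one word,
    ``Syl`` = total syllables over word tokens.  May be negative for very
    simple text.  Raises ``ValueError`` on a document without words.
    """
    words = doc.word_tokens()
    n_sent = sum(
        1 for s in doc.sentences
        if any(doc.tokens[i].is_word for i in range(s.first, s.last))
    )
    if not words or n_sent == 0:
        raise ValueError("flesch_kincaid requires at least one word and sentence")
    syllables = 0
    for t in words:
        try:
            syllables += count_syllables(t.surface)
        except ValueError:
            syllables += 1
    return 0.39 * (len(words) / n_sent) + 11.8 * (syllables / len(words)) - 15.59
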