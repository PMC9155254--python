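"""Scoring free-recall answers against a source text.

After reading, participants write what they remember; these metrics score
that answer against the stimulus text:

* ROUGE-1 / ROUGE-2 — clipped n-gram overlap; recall divides by the
  reference's n-gram count, precision by the answer's.
* ROUGE-L — longest common subsequence over the flat token sequences.
* Embedding cosine — cosine between the mean word vector of answer and text.
* Similar/matching word proportions — the fraction of answer words that
  literally occur in the text (matching), or that occur or embed within
  cosine ``tau`` of some text word (similar).

Throughout, the *answer* is the candidate and the *text* is the reference:
a short answer against a long text then shows low recall but can show high
precision, which is the regime these measures are designed for.
Preprocessing for all metrics is lowercasing with punctuation stripped; no
stemming and no stopword removal by default (both are switchable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core_text import tokenize
from .resources import EmbeddingTable

__all__ = ["RougeScore", "prep_tokens", "rouge_n", "rouge_l",
           "embedding_similarity", "word_match_proportions",
           "unique_word_count"]


@dataclass(frozen=True)
class RougeScore:
    precision: float
    recall: float
    f_measure: float
    variant: str                 # "UNIGRAM", "BIGRAM" or "LCS"
    degenerate: bool = False     # empty answer: P undefined, reported 0


def _f_measure(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


_STEM_SUFFIXES = ("ing", "ed", "es", "s")


def prep_tokens(text: str, lowercase: bool = True, stem: bool = False,
                stopwords: frozenset[str] | None = None) -> list[str]:
    """Word tokens of ``text`` for metric computation.

    Punctuation is always stripped (only word tokens survive).  ``stem``
    applies a crude suffix stripper; ``stopwords`` removes the given forms
    after lowercasing.  Defaults: lowercase only.
    """
    toks = [t.surface for t in tokenize(text).tokens if t.is_word]
    if lowercase:
        toks = [t.lower() for t in toks]
    if stopwords:
        toks = [t for t in toks if t not in stopwords]
    if stem:
        out = []
        for t in toks:
            for suf in _STEM_SUFFIXES:
                if t.endswith(suf) and len(t) - len(suf) >= 3:
                    t = t[:-len(suf)]
                    break
            out.append(t)
        toks = out
    return toks


def unique_word_count(tokens: list[str]) -> int:
    """Number of distinct lowercased word forms (answer-length measure)."""
    return len({t.lower() for t in tokens})


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def rouge_n(answer: list[str], reference: list[str], n: int) -> RougeScore:
    """ROUGE-N for ``n`` in {1, 2} over pre-tokenized lowercased words.

    Overlap counts are clipped (each reference n-gram can be matched at most
    as often as it occurs).  A reference shorter than ``n`` is an error; an
    answer shorter than ``n`` yields the degenerate all-zero score.
    """
    if n not in (1, 2):
        raise ValueError(f"n must be 1 or 2, got {n}")
    ref_grams = _ngrams(reference, n)
    if not ref_grams:
        raise ValueError(f"reference has no {n}-grams")
    ans_grams = _ngrams(answer, n)
    variant = "UNIGRAM" if n == 1 else "BIGRAM"
    if not ans_grams:
        return RougeScore(0.0, 0.0, 0.0, variant, degenerate=True)
    overlap = sum((ans_grams & ref_grams).values())
    p = overlap / sum(ans_grams.values())
    r = overlap / sum(ref_grams.values())
    return RougeScore(p, r, _f_measure(p, r), variant)


def _lcs_length(a: list[str], b: list[str]) -> int:
    """Iterative two-row LCS dynamic program."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, 1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def rouge_l(answer: list[str], reference: list[str]) -> RougeScore:
    """ROUGE-L: longest common subsequence over flat token sequences.

    ``P = LCS/|answer|``, ``R = LCS/|reference|``.  An empty reference is an
    error; an empty answer yields the degenerate all-zero score.
    """
    if not reference:
        raise ValueError("reference is empty")
    if not answer:
        return RougeScore(0.0, 0.0, 0.0, "LCS", degenerate=True)
    lcs = _lcs_length(answer, reference)
    p = lcs / len(answer)
    r = lcs / len(reference)
    return RougeScore(p, r, _f_measure(p, r), "LCS")


def embedding_similarity(answer: list[str], text: list[str],
                         emb: EmbeddingTable) -> float:
    """Cosine between the mean word vectors of answer and text.

    Raises ``ValueError`` when either side has no in-vocabulary word.
    """
    va = emb.mean_vector(answer)
    vt = emb.mean_vector(text)
    if va is None or vt is None:
        side = "answer" if va is None else "text"
        raise ValueError(f"no in-vocabulary words in the {side}")
    cos = emb.cosine(va, vt)
    if cos is None:
        raise ValueError("zero-norm mean vector")
    return cos


def word_match_proportions(answer: list[str], text: list[str],
                           emb: EmbeddingTable | None = None,
                           tau: float = 0.5) -> tuple[float, float]:
    """(proportion similar, proportion matching) of answer words vs the text.

    *Matching*: the answer word's lowercased form occurs in the text.
    *Similar*: matching, or its maximum embedding cosine to any text word is
    at least ``tau``.  By construction ``prop_similar >= prop_matching``.
    """
    if not answer:
        raise ValueError("answer has no word tokens")
    text_set = {w.lower() for w in text}
    text_vecs = None
    if emb is not None:
        vecs = [v for v in (emb.get(w) for w in text_set) if v is not None]
        if vecs:
            m = np.array(vecs, dtype=float)
            norms = np.linalg.norm(m, axis=1)
            keep = norms > 0
            text_vecs = m[keep] / norms[keep, None]
    n_match = 0
    n_similar = 0
    for w in answer:
        lw = w.lower()
        if lw in text_set:
            n_match += 1
            n_similar += 1
            continue
        if text_vecs is not None and emb is not None:
            v = emb.get(lw)
            if v is not None:
                nv = np.linalg.norm(v)
                if nv > 0 and float(np.max(text_vecs @ (v / nv))) >= tau:
                    n_similar += 1
    n = len(answer)
    return n_similar / n, n_match / n
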