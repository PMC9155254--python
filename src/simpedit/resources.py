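"""Lexical resources the editor consumes, and their on-disk formats.

Four resource types back the suggestion engine and the statistics:

* :class:`FrequencyLexicon` — word -> corpus occurrence count (TSV); the
  frequency of a word is the editor's proxy for its difficulty.
* :class:`EmbeddingTable` — word vectors in the word2vec *text* format
  (header ``V D``, then one ``word v1 .. vD`` line each); used by the
  context filter, semantic lexical chains and recall metrics.
* :class:`SubstitutionLexicon` — phrase -> ordered simpler candidates (TSV,
  candidates ``|``-separated), each entry tagged with the resource it came
  from so individual resources can be switched off like the editor's
  checkbox panel.
* :class:`SentenceRule` — a sentence-structure pattern (case-insensitive
  regex over the sentence text) with fixed guidance and example (TSV).

Every reader has a matching writer and the pair round-trips exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FrequencyLexicon", "EmbeddingTable", "SubstitutionLexicon", "SentenceRule",
    "read_frequency_list", "write_frequency_list",
    "read_embeddings", "write_embeddings",
    "read_substitution_lexicon", "write_substitution_lexicon",
    "read_rule_catalog", "write_rule_catalog",
    "ResourceFormatError",
]


class ResourceFormatError(ValueError):
    """A resource file violates its documented format; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class FrequencyLexicon:
    entries: dict[str, int] = field(default_factory=dict)

    def get(self, word: str, default: int = 0) -> int:
        return self.entries.get(word.lower(), default)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def quantile(self, q: float) -> float:
        """The ``q``-quantile of the count distribution (over lexicon entries)."""
        if not self.entries:
            return 0.0
        return float(np.quantile(np.fromiter(self.entries.values(), dtype=float), q))


@dataclass
class EmbeddingTable:
    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, word: str) -> np.ndarray | None:
        return self.vectors.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def mean_vector(self, words) -> np.ndarray | None:
        """Mean vector over the in-vocabulary words, or None if none are known."""
        vecs = [v for v in (self.get(w) for w in words) if v is not None]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)

    def cosine(self, a, b) -> float | None:
        """Cosine between two words or vectors; None on out-of-vocabulary input."""
        va = self.get(a) if isinstance(a, str) else a
        vb = self.get(b) if isinstance(b, str) else b
        if va is None or vb is None:
            return None
        na, nb = float(np.linalg.norm(va)), float(np.linalg.norm(vb))
        if na == 0.0 or nb == 0.0:
            return None
        return float(np.dot(va, vb) / (na * nb))


@dataclass
class SubstitutionLexicon:
    #: phrase (lowercased, single-space-joined tokens) -> ordered candidates
    entries: dict[str, list[str]] = field(default_factory=dict)
    #: phrase -> name of the resource it came from
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: str) -> bool:
        return phrase.lower() in self.entries

    def candidates(self, phrase: str) -> list[str]:
        return list(self.entries.get(phrase.lower(), []))

    def max_phrase_tokens(self) -> int:
        return max((p.count(" ") + 1 for p in self.entries), default=0)

    def restrict(self, enabled_sources) -> "SubstitutionLexicon":
        """Keep only entries whose source resource is enabled (checkbox panel)."""
        enabled = set(enabled_sources)
        keep = {p: c for p, c in self.entries.items()
                if self.sources.get(p, "default") in enabled}
        return SubstitutionLexicon(
            entries=keep,
            sources={p: self.sources.get(p, "default") for p in keep})


@dataclass
class SentenceRule:
    id: str
    pattern: str
    guidance: str
    example: str
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.guidance or not self.example:
            raise ValueError(f"rule {self.id!r}: guidance and example must be non-empty")
        try:
            self._compiled = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"rule {self.id!r}: pattern does not compile: {exc}") from exc

    def finditer(self, sentence_text: str):
        return self._compiled.finditer(sentence_text)


# --- frequency lexicon ----------------------------------------------------

def read_frequency_list(path) -> FrequencyLexicon:
    """Read a ``word<TAB>count`` TSV; duplicate words have their counts summed."""
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ResourceFormatError(path, lineno, "expected 'word<TAB>count'")
            word, count_s = parts
            try:
                count = int(count_s)
            except ValueError:
                raise ResourceFormatError(path, lineno, f"count {count_s!r} is not an integer")
            if count < 0:
                raise ResourceFormatError(path, lineno, "count must be nonnegative")
            key = word.lower()
            entries[key] = entries.get(key, 0) + count
    return FrequencyLexicon(entries)


def write_frequency_list(lex: FrequencyLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(lex.entries):
            fh.write(f"{word}\t{lex.entries[word]}\n")


# --- embeddings (word2vec text format) ------------------------------------

def read_embeddings(path) -> EmbeddingTable:
    """Read word vectors in word2vec text format.

    Header line ``V D`` declares the vocabulary size and dimension; each of
    the following ``V`` lines is a word followed by ``D`` floats.  Any
    dimension mismatch or row-count mismatch is an error.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ResourceFormatError(path, 1, "header must be 'V D'")
        try:
            n_rows, dim = int(header[0]), int(header[1])
        except ValueError:
            raise ResourceFormatError(path, 1, "header must hold two integers")
        if dim <= 0:
            raise ResourceFormatError(path, 1, "dimension must be positive")
        vectors: dict[str, np.ndarray] = {}
        lineno = 1
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != dim + 1:
                raise ResourceFormatError(
                    path, lineno, f"expected word + {dim} floats, got {len(parts) - 1}")
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=float)
            except ValueError:
                raise ResourceFormatError(path, lineno, "non-numeric vector component")
            vectors[parts[0].lower()] = vec
        if len(vectors) != n_rows:
            raise ResourceFormatError(
                path, lineno, f"header declared {n_rows} rows, file holds {len(vectors)}")
    return EmbeddingTable(dimension=dim, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for word in sorted(table.vectors):
            comps = " ".join(repr(float(x)) for x in table.vectors[word])
            fh.write(f"{word} {comps}\n")


# --- substitution lexicon -------------------------------------------------

def read_substitution_lexicon(path, source: str | None = None) -> SubstitutionLexicon:
    """Read ``phrase<TAB>cand|cand|...[<TAB>source]`` lines; order preserved."""
    default_source = source or Path(path).stem
    entries: dict[str, list[str]] = {}
    sources: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ResourceFormatError(
                    path, lineno, "expected 'phrase<TAB>cand|cand|...[<TAB>source]'")
            phrase = " ".join(parts[0].lower().split())
            if not phrase:
                raise ResourceFormatError(path, lineno, "empty phrase")
            cands = [c.strip() for c in parts[1].split("|") if c.strip()]
            if not cands:
                raise ResourceFormatError(path, lineno, f"no candidates for {phrase!r}")
            entries[phrase] = cands
            sources[phrase] = parts[2] if len(parts) == 3 else default_source
    return SubstitutionLexicon(entries=entries, sources=sources)


def write_substitution_lexicon(lex: SubstitutionLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for phrase, cands in lex.entries.items():
            src = lex.sources.get(phrase, "default")
            fh.write(f"{phrase}\t{'|'.join(cands)}\t{src}\n")


# --- sentence-rule catalog ------------------------------------------------

def read_rule_catalog(path) -> list[SentenceRule]:
    """Read ``id<TAB>pattern<TAB>guidance<TAB>example`` lines into compiled rules."""
    rules: list[SentenceRule] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ResourceFormatError(
                    path, lineno, "expected 'id<TAB>pattern<TAB>guidance<TAB>example'")
            try:
                rules.append(SentenceRule(*parts))
            except ValueError as exc:
                raise ResourceFormatError(path, lineno, str(exc))
    return rules


def write_rule_catalog(rules: list[SentenceRule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rules:
            fh.write(f"{r.id}\t{r.pattern}\t{r.guidance}\t{r.example}\n")
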