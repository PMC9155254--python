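"""Lexical chains over a document's nouns, at three widening match levels.

A lexical chain is a thread of related nouns running through a text; texts
whose chains interleave ("cross") tend to be harder to read, so the chain
layout and its statistics are a cohesion diagnostic.  Three relatedness
levels are supported, each strictly broader than the last:

* ``EXACT``    — same lemma;
* ``SYNONYM``  — same lemma, or membership in the same synonym set;
* ``SEMANTIC`` — the synonym criteria, or embedding cosine >= ``theta``.

Chaining is greedy and deterministic: nouns are scanned left to right and
each is attached to the *most recently updated* chain containing a related
member, else it opens a new chain.  Only chains with at least two members
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_text import Document
from .resources import EmbeddingTable

__all__ = ["LexicalChain", "ChainStats", "build_chains", "chain_stats", "LEVELS"]

LEVELS = ("EXACT", "SYNONYM", "SEMANTIC")


@dataclass
class LexicalChain:
    level: str
    members: list[int]          # token indices, strictly increasing
    head: str                   # lemma of the first member

    def span(self) -> tuple[int, int]:
        return self.members[0], self.members[-1]


@dataclass
class ChainStats:
    chain_count: int
    mean_length: float
    spans: list[tuple[int, int]] = field(default_factory=list)
    crossing_pair_count: int = 0


def _related(lemma_a: str, lemma_b: str, level: str,
             synonyms: dict[str, str] | None,
             emb: EmbeddingTable | None, theta: float) -> bool:
    if lemma_a == lemma_b:
        return True
    if level == "EXACT":
        return False
    if synonyms is not None:
        sa, sb = synonyms.get(lemma_a), synonyms.get(lemma_b)
        if sa is not None and sa == sb:
            return True
    if level == "SYNONYM":
        return False
    if emb is not None:
        cos = emb.cosine(lemma_a, lemma_b)
        if cos is not None and cos >= theta:
            return True
    return False


def build_chains(doc: Document, level: str = "EXACT",
                 synonyms: dict[str, str] | None = None,
                 emb: EmbeddingTable | None = None,
                 theta: float = 0.6) -> list[LexicalChain]:
    """Chain the document's NOUN tokens at the given match level.

    ``synonyms`` maps a lemma to its synonym-set id; ``emb`` and ``theta``
    are required only at the SEMANTIC level (``theta`` must lie in [-1, 1]).
    Chains are returned in order of first member; singletons are dropped.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if not -1.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [-1, 1], got {theta}")
    if level == "SEMANTIC" and emb is None:
        raise ValueError("SEMANTIC chaining requires an embedding table")

    # each open chain: (members, lemmas, last_update_step)
    open_chains: list[dict] = []
    step = 0
    for i, tok in enumerate(doc.tokens):
        if tok.pos != "NOUN" or not tok.is_word:
            continue
        step += 1
        target = None
        for chain in sorted(open_chains, key=lambda c: -c["updated"]):
            if any(_related(tok.lemma, lm, level, synonyms, emb, theta)
                   for lm in chain["lemmas"]):
                target = chain
                break
        if target is None:
            open_chains.append({"members": [i], "lemmas": [tok.lemma],
                                "updated": step})
        else:
            target["members"].append(i)
            target["lemmas"].append(tok.lemma)
            target["updated"] = step

    chains = [LexicalChain(level=level, members=c["members"],
                           head=c["lemmas"][0])
              for c in open_chains if len(c["members"]) >= 2]
    chains.sort(key=lambda c: c.members[0])
    return chains


def chain_stats(chains: list[LexicalChain]) -> ChainStats:
    """Summary statistics of one document's chains.

    Two chains *cross* iff their position spans interleave without nesting:
    with A the chain starting first, ``min(A) < min(B) <= max(A) < max(B)``.
    """
    if not chains:
        return ChainStats(chain_count=0, mean_length=0.0)
    spans = [c.span() for c in chains]
    crossing = 0
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (a_lo, a_hi), (b_lo, b_hi) = sorted([spans[i], spans[j]])
            if a_lo < b_lo <= a_hi < b_hi:
                crossing += 1
    return ChainStats(
        chain_count=len(chains),
        mean_length=sum(len(c.members) for c in chains) / len(chains),
        spans=spans,
        crossing_pair_count=crossing)
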