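"""Deterministic synthetic data: tiny resources and participant responses.

Nothing in this package requires downloads.  This module builds, from a
seed, (a) the lexical resources the engine consumes — a frequency lexicon,
a small embedding table with *designed* geometry (synonym clusters with
cosine >= 0.9, designated distractor pairs orthogonal), a substitution
lexicon and a sentence-rule catalog, plus a toy original/simplified text
pair — and (b) a participant-responses table with the structure the study
pipeline assumes.

The response generator emulates a two-condition reading study: each
participant reads 4 texts, 2 original and 2 simplified, assigned by one of
the 6 counterbalancing combinations (the ways of picking which 2 of 4 texts
are original).  Perceived difficulty is a 4-point Likert item drawn from a
discretized normal whose condition means default to 2.28 (original) and
2.28 + 0.27 (simplified); question correctness is Bernoulli with
per-question baseline accuracies; recall metrics and expert scores are
clipped normals; a configurable fraction of readings is faster than the
one-minute exclusion cutoff.  All condition effects can be zeroed
(:func:`zero_effect_config`) for type-I-error calibration, or left at their
defaults, which mirror the magnitudes the study design anticipates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources as res

__all__ = [
    "SyntheticConfig", "zero_effect_config",
    "make_resources", "make_responses", "make_recall_answers",
    "likert_population_mean", "likert_effect_population",
    "TOY_ORIGINAL_TEXT", "TOY_SIMPLIFIED_TEXT",
    "TEXT_IDS", "DESIGNED_SYNONYM_GROUPS", "DESIGNED_DISTRACTORS",
]

TEXT_IDS = ("asthma", "cirrhosis", "pemphigus", "polycythemia")

#: per-question correct-answer probability (original, simplified)
QUESTION_PROBS: dict[str, tuple[float, float]] = {
    "tf_before_1": (0.67, 0.63), "tf_before_2": (0.71, 0.71),
    "tf_before_3": (0.51, 0.53), "tf_before_4": (0.76, 0.72),
    "tf_before_5": (0.33, 0.59),
    "mc_while_1": (0.80, 0.83), "mc_while_2": (0.71, 0.70),
    "tf_after_1": (0.66, 0.62), "tf_after_2": (0.93, 0.88),
    "tf_after_3": (0.66, 0.72), "tf_after_4": (0.93, 0.92),
    "tf_after_5": (0.52, 0.78),
    "mc_after_1": (0.37, 0.57), "mc_after_2": (0.68, 0.75),
    "mc_after_3": (0.33, 0.59), "mc_after_4": (0.33, 0.29),
}

#: continuous recall metrics: (mean_orig, sd_orig, mean_simp, sd_simp, lo, hi)
METRIC_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    "unique_word_count": (25.0, 14.0, 23.0, 12.0, 0.0, math.inf),
    "prop_similar": (0.76, 0.16, 0.82, 0.11, 0.0, 1.0),
    "prop_matching": (0.53, 0.18, 0.59, 0.14, 0.0, 1.0),
    "cosine_similarity": (0.111, 0.013, 0.117, 0.009, -1.0, 1.0),
    "correct_facts": (7.5, 4.4, 8.1, 6.6, 0.0, math.inf),
    "completeness": (2.10, 0.89, 2.17, 0.84, 0.0, 4.0),
    "correctness": (3.18, 0.86, 3.21, 0.71, 0.0, 4.0),
    "rouge_lcs_recall": (0.093, 0.063, 0.108, 0.070, 0.0, 1.0),
    "rouge_lcs_precision": (0.487, 0.212, 0.436, 0.125, 0.0, 1.0),
    "rouge_lcs_f": (0.151, 0.095, 0.164, 0.090, 0.0, 1.0),
    "rouge_unigram_recall": (0.085, 0.051, 0.119, 0.080, 0.0, 1.0),
    "rouge_unigram_precision": (0.689, 0.152, 0.654, 0.133, 0.0, 1.0),
    "rouge_unigram_f": (0.147, 0.079, 0.191, 0.111, 0.0, 1.0),
    "rouge_bigram_recall": (0.037, 0.038, 0.044, 0.039, 0.0, 1.0),
    "rouge_bigram_precision": (0.316, 0.263, 0.240, 0.145, 0.0, 1.0),
    "rouge_bigram_f": (0.064, 0.064, 0.070, 0.056, 0.0, 1.0),
}

MAIN_POINT_PROBS = (0.67, 0.67)

EDUCATION_PROBS = (0.02, 0.24, 0.16, 0.29, 0.24, 0.05)   # ordinal 1-6
LANGUAGE_PROBS = (0.0, 0.02, 0.07, 0.31, 0.60)           # ordinal 1-5

DESIGNED_SYNONYM_GROUPS: tuple[tuple[str, ...], ...] = (
    ("use", "utilize", "employ"),
    ("doctor", "physician"),
    ("later", "subsequent", "following"),
    ("begin", "start", "commence"),
    ("illness", "disease", "sickness"),
)
DESIGNED_DISTRACTORS: tuple[str, ...] = (
    "cat", "liver", "lungs", "airway", "inhaler", "month", "year",
    "swelling", "scarring", "breathing",
)

_COMMON_WORDS: dict[str, int] = {
    "the": 1_000_000, "a": 800_000, "an": 200_000, "and": 700_000,
    "of": 650_000, "to": 600_000, "in": 500_000, "is": 450_000,
    "it": 400_000, "that": 350_000, "for": 300_000, "can": 250_000,
    "with": 240_000, "this": 230_000, "may": 150_000, "or": 280_000,
    "use": 120_000, "later": 90_000, "begin": 60_000, "start": 80_000,
    "doctor": 70_000, "following": 65_000, "followed": 40_000, "by": 260_000,
    "disease": 55_000, "illness": 30_000, "side": 85_000, "effects": 45_000,
    "bad": 95_000, "cat": 50_000, "sat": 20_000, "month": 75_000,
    "months": 70_000, "year": 88_000, "years": 82_000, "lungs": 15_000,
    "airway": 9_000, "inhaler": 5_000, "breathing": 25_000, "people": 140_000,
    "over": 110_000, "time": 160_000, "treat": 35_000, "help": 90_000,
    "swelling": 12_000, "liver": 14_000, "scarring": 4_000, "your": 210_000,
    "medicine": 28_000, "symptoms": 22_000, "worse": 26_000, "better": 60_000,
}
_HARD_WORDS: dict[str, int] = {
    "utilize": 10, "subsequent": 8, "commence": 12, "physician": 600,
    "employ": 700, "sickness": 800, "adverse": 300, "utilization": 6,
    "inflammation": 450, "exacerbation": 5, "chronic": 900,
}

_SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("utilize", "use"),
    ("subsequent", "later|following|followed by"),
    ("commence", "begin|start"),
    ("physician", "doctor"),
    ("adverse effects", "side effects|bad effects"),
    ("exacerbation", "flare-up"),
    ("inflammation", "swelling"),
)

_RULES: tuple[tuple[str, str, str, str], ...] = (
    ("nominalization",
     r"\b\w+(?:tion|ment|ance|ence)s?\s+of\b",
     "Replace the nominalization with the verb it comes from.",
     "The utilization of the brush was easy. -> Using the brush was easy."),
    ("duration-phrase",
     r"months or years",
     "State the time span directly instead of an open-ended range.",
     "Plaque builds up over months or years. -> Plaque builds up slowly over time."),
    ("passive-voice",
     r"\b(?:is|are|was|were|been|be)\s+\w+(?:ed|en)\b",
     "Rewrite in active voice: say who does the action.",
     "The teeth are cleaned by the dentist. -> The dentist cleans the teeth."),
)

TOY_ORIGINAL_TEXT = (
    "Asthma is a chronic disease of the lungs. "
    "Many people utilize an inhaler when symptoms commence. "
    "A physician may treat the inflammation over months or years. "
    "Subsequent exacerbation can make breathing worse. "
    "The utilization of medicine can have adverse effects. "
    "The airway swelling is reduced by the medicine."
)
TOY_SIMPLIFIED_TEXT = (
    "Asthma is a disease of the lungs that lasts a long time. "
    "Many people use an inhaler when symptoms begin. "
    "A doctor may treat the swelling over time. "
    "A later flare-up can make breathing worse. "
    "Using medicine can have side effects. "
    "The medicine reduces the airway swelling."
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults are the emulated study's own conditions: 49 participants, 4
    texts each (2 per version) over 6 counterbalancing combinations, a
    Likert condition effect of +0.27 on a baseline of 2.28 (latent SD 0.70),
    per-question accuracies as configured, and 20.9% of readings faster
    than the one-minute cutoff.
    """

    seed: int = 0
    n_participants: int = 49
    texts_per_participant: int = 4
    likert_mean_original: float = 2.28
    likert_effect: float = 0.27
    likert_sd: float = 0.70
    question_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(QUESTION_PROBS))
    metric_params: dict[str, tuple[float, float, float, float, float, float]] = \
        field(default_factory=lambda: dict(METRIC_PARAMS))
    main_point_probs: tuple[float, float] = MAIN_POINT_PROBS
    fast_read_fraction: float = 41 / 196
    slow_read_median_seconds: float = 160.0
    slow_read_sigma: float = 0.35
    embedding_dim: int = 32
    embedding_noise: float = 0.08


def zero_effect_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A config with every condition effect removed (null hypothesis true)."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    cfg.likert_effect = 0.0
    cfg.question_probs = {q: (p, p) for q, (p, _) in cfg.question_probs.items()}
    cfg.metric_params = {m: (mu, sd, mu, sd, lo, hi)
                         for m, (mu, sd, _, _, lo, hi) in cfg.metric_params.items()}
    cfg.main_point_probs = (cfg.main_point_probs[0], cfg.main_point_probs[0])
    return cfg


# --- Likert model ---------------------------------------------------------

def _likert_probs(mu: float, sd: float) -> np.ndarray:
    """Categorical probabilities over 1..4 from a discretized normal."""
    from scipy.stats import norm
    edges = np.array([1.5, 2.5, 3.5])
    cdf = norm.cdf((edges - mu) / sd)
    p = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    return p / p.sum()


def likert_population_mean(mu: float, sd: float) -> float:
    """Exact mean of the discretized-normal Likert distribution."""
    return float(np.dot(_likert_probs(mu, sd), np.arange(1, 5)))


def likert_effect_population(cfg: SyntheticConfig) -> float:
    """The generator's true (population) Likert group-mean difference."""
    return (likert_population_mean(cfg.likert_mean_original + cfg.likert_effect,
                                   cfg.likert_sd)
            - likert_population_mean(cfg.likert_mean_original, cfg.likert_sd))


# --- resources ------------------------------------------------------------

def _build_embeddings(cfg: SyntheticConfig, vocab: list[str]) -> res.EmbeddingTable:
    rng = np.random.default_rng(cfg.seed)
    dim = cfg.embedding_dim
    n_reserved = len(DESIGNED_SYNONYM_GROUPS) + len(DESIGNED_DISTRACTORS)
    if dim < n_reserved + 2:
        raise ValueError(f"embedding_dim must be >= {n_reserved + 2}")
    vectors: dict[str, np.ndarray] = {}
    axis = 0
    for group in DESIGNED_SYNONYM_GROUPS:
        base = np.zeros(dim)
        base[axis] = 1.0
        for member in group:
            noise = rng.normal(size=dim)
            noise[:n_reserved] = 0.0          # keep designed axes clean
            noise *= cfg.embedding_noise / np.linalg.norm(noise)
            v = base + noise
            vectors[member] = v / np.linalg.norm(v)
        axis += 1
    for word in DESIGNED_DISTRACTORS:
        v = np.zeros(dim)
        v[axis] = 1.0
        vectors[word] = v
        axis += 1
    for word in vocab:
        lw = word.lower()
        if lw not in vectors:
            v = rng.normal(size=dim)
            vectors[lw] = v / np.linalg.norm(v)
    return res.EmbeddingTable(dimension=dim, vectors=vectors)


def make_resources(cfg: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Write every resource file the engine consumes; returns their paths.

    Emits ``frequencies.tsv``, ``embeddings.txt`` (word2vec text format),
    ``substitutions.tsv``, ``rules.tsv`` and the toy text pair
    ``texts/<id>_{original,simplified}.txt``.  Byte-identical per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "texts").mkdir(exist_ok=True)

    freq = res.FrequencyLexicon({**_COMMON_WORDS, **_HARD_WORDS})
    paths = {"frequencies": out / "frequencies.tsv",
             "embeddings": out / "embeddings.txt",
             "substitutions": out / "substitutions.tsv",
             "rules": out / "rules.tsv"}
    res.write_frequency_list(freq, paths["frequencies"])

    vocab = sorted(set(freq.entries)
                   | {w for t in (TOY_ORIGINAL_TEXT, TOY_SIMPLIFIED_TEXT)
                      for w in t.lower().replace(".", " ").split()}
                   | {w for p, c in _SUBSTITUTIONS
                      for w in (p + " " + c.replace("|", " ")).split()})
    emb = _build_embeddings(cfg, vocab)
    res.write_embeddings(emb, paths["embeddings"])

    subs = res.SubstitutionLexicon(
        entries={p: c.split("|") for p, c in _SUBSTITUTIONS},
        sources={p: "synthetic-core" for p, _ in _SUBSTITUTIONS})
    res.write_substitution_lexicon(subs, paths["substitutions"])

    rules = [res.SentenceRule(*r) for r in _RULES]
    res.write_rule_catalog(rules, paths["rules"])

    orig_path = out / "texts" / "toy_original.txt"
    simp_path = out / "texts" / "toy_simplified.txt"
    orig_path.write_text(TOY_ORIGINAL_TEXT, encoding="utf-8")
    simp_path.write_text(TOY_SIMPLIFIED_TEXT, encoding="utf-8")
    paths["text_original"] = orig_path
    paths["text_simplified"] = simp_path
    return paths


# --- responses ------------------------------------------------------------

_COMBINATIONS = tuple(itertools.combinations(range(4), 2))  # which 2 texts original


def make_responses(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate the participant-responses table (one row per reading).

    Rows follow the study pipeline's column dictionary; assignment of text
    versions is counterbalanced over the 6 combinations and the text order
    is randomized per participant.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    p_orig = _likert_probs(cfg.likert_mean_original, cfg.likert_sd)
    p_simp = _likert_probs(cfg.likert_mean_original + cfg.likert_effect,
                           cfg.likert_sd)
    for pid in range(1, cfg.n_participants + 1):
        combo = (pid - 1) % len(_COMBINATIONS)
        original_texts = set(_COMBINATIONS[combo])
        education = 1 + rng.choice(6, p=np.array(EDUCATION_PROBS)
                                   / sum(EDUCATION_PROBS))
        language = 1 + rng.choice(5, p=np.array(LANGUAGE_PROBS)
                                  / sum(LANGUAGE_PROBS))
        order = rng.permutation(cfg.texts_per_participant)
        for t in order:
            t = int(t) % len(TEXT_IDS)
            simplified = t not in original_texts
            cidx = 1 if simplified else 0
            row: dict = {
                "participant_id": pid,
                "text_id": TEXT_IDS[t],
                "condition": "simplified" if simplified else "original",
                "combination": combo + 1,
                "education_level": int(education),
                "language_level": int(language),
            }
            if rng.random() < cfg.fast_read_fraction:
                row["reading_seconds"] = float(rng.uniform(15.0, 59.5))
            else:
                secs = rng.lognormal(math.log(cfg.slow_read_median_seconds),
                                     cfg.slow_read_sigma)
                row["reading_seconds"] = float(max(60.0, secs))
            row["likert"] = int(rng.choice(4, p=p_simp if simplified else p_orig)) + 1
            for q, probs in cfg.question_probs.items():
                row[q] = int(rng.random() < probs[cidx])
            for m, (mu0, sd0, mu1, sd1, lo, hi) in cfg.metric_params.items():
                mu, sd = (mu1, sd1) if simplified else (mu0, sd0)
                val = float(np.clip(rng.normal(mu, sd), lo, hi))
                if m in ("unique_word_count", "correct_facts"):
                    val = float(round(val))
                row[m] = val
            row["main_point"] = int(rng.random() < cfg.main_point_probs[cidx])
            row["completeness"] = float(round(row["completeness"]))
            row["correctness"] = float(round(row["correctness"]))
            rows.append(row)
    return pd.DataFrame(rows)


def make_recall_answers(cfg: SyntheticConfig) -> pd.DataFrame:
    """Short synthetic free-recall answers over the toy text pair.

    Each answer samples words from the stimulus text (more, and more
    faithfully, for the simplified condition) mixed with off-text filler,
    yielding a small corpus for exercising the recall metrics end to end.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    filler = ["thing", "stuff", "someone", "maybe", "really", "about"]
    rows = []
    for pid in range(1, cfg.n_participants + 1):
        for condition, text in (("original", TOY_ORIGINAL_TEXT),
                                ("simplified", TOY_SIMPLIFIED_TEXT)):
            words = [w.strip(".,").lower() for w in text.split()]
            overlap = 0.55 if condition == "original" else 0.65
            n_words = int(rng.integers(8, 28))
            picked = [words[int(rng.integers(len(words)))]
                      if rng.random() < overlap
                      else filler[int(rng.integers(len(filler)))]
                      for _ in range(n_words)]
            rows.append({"participant_id": pid, "text_id": "toy",
                         "condition": condition, "answer": " ".join(picked)})
    return pd.DataFrame(rows)
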