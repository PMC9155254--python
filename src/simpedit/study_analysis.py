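"""The study pipeline: response filtering, one-way ANOVA by text version,
one-tailed Pearson correlations, Bonferroni, and report tables.

The unit of observation is one participant x text reading.  A responses
table (CSV / DataFrame) follows a documented column dictionary (see
:data:`COLUMN_DICTIONARY`): identifiers, condition (``original`` /
``simplified``), reading time, a 4-point perceived-difficulty Likert item
(4 = easiest), per-question correctness indicators, automated recall
metrics, expert scores, and two ordinal demographics (education level 1-6,
language-spoken-at-home 1-5).

Readings faster than one minute are excluded per *text* (never the whole
participant), the cutoff being the fastest plausible reading of text plus
in-text questions.  Each dependent measure is analysed with a one-way ANOVA
over the two conditions; each reading is treated as an independent
observation.  Secondary analyses correlate question accuracy (all items
answered with or after the text, excluding the five before-reading items)
with the two demographics, one-tailed for a positive association, with a
Bonferroni-adjusted threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult", "COLUMN_DICTIONARY", "QUESTION_COLUMNS",
    "MEASURE_COLUMNS", "ACCURACY_COLUMNS",
    "filter_responses", "one_way_anova", "pearson_one_tailed",
    "bonferroni_threshold", "build_report", "secondary_accuracy",
    "demographic_correlations", "per_text_accuracy",
]

TF_BEFORE = [f"tf_before_{i}" for i in range(1, 6)]
MC_WHILE = [f"mc_while_{i}" for i in range(1, 3)]
TF_AFTER = [f"tf_after_{i}" for i in range(1, 6)]
MC_AFTER = [f"mc_after_{i}" for i in range(1, 5)]
QUESTION_COLUMNS = TF_BEFORE + MC_WHILE + TF_AFTER + MC_AFTER

#: question items entering the secondary-analysis accuracy: everything
#: answered with or after the text (the 5 before-reading items excluded)
ACCURACY_COLUMNS = MC_WHILE + TF_AFTER + MC_AFTER

ROUGE_COLUMNS = [f"rouge_{v}_{m}"
                 for v in ("lcs", "unigram", "bigram")
                 for m in ("recall", "precision", "f")]

#: dependent measures reported row-by-row, in table order
MEASURE_COLUMNS = (
    ["likert"] + QUESTION_COLUMNS
    + ["unique_word_count", "prop_similar", "prop_matching",
       "cosine_similarity", "correct_facts", "main_point",
       "completeness", "correctness"]
    + ROUGE_COLUMNS
)

COLUMN_DICTIONARY: dict[str, str] = {
    "participant_id": "participant identifier",
    "text_id": "stimulus text identifier",
    "condition": "text version read: 'original' or 'simplified'",
    "combination": "counterbalancing combination 1-6",
    "reading_seconds": "seconds spent on the text and its 2 in-text questions",
    "likert": "perceived difficulty, 1-4, 4 = easiest",
    **{c: "true/false item before reading, 1 = correct" for c in TF_BEFORE},
    **{c: "multiple-choice item while reading, 1 = correct" for c in MC_WHILE},
    **{c: "true/false item after reading, 1 = correct" for c in TF_AFTER},
    **{c: "multiple-choice item after reading, 1 = correct" for c in MC_AFTER},
    "unique_word_count": "distinct words in the free-recall answer",
    "prop_similar": "fraction of answer words similar to the text (0-1)",
    "prop_matching": "fraction of answer words matching the text (0-1)",
    "cosine_similarity": "embedding cosine between answer and text",
    "correct_facts": "expert count of correct facts recalled",
    "main_point": "expert judgment: main point conveyed (0/1)",
    "completeness": "expert completeness score 0-4",
    "correctness": "expert correctness score 0-4",
    **{c: "ROUGE metric of the free-recall answer vs the text"
       for c in ROUGE_COLUMNS},
    "education_level": "ordinal 1-6: <HS, HS, associate, bachelor, master, doctorate",
    "language_level": "ordinal 1-5: English at home never ... only",
}

CONDITIONS = ("original", "simplified")


@dataclass
class AnovaResult:
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]
    f_value: float
    p_value: float
    df_between: int
    df_within: int


def filter_responses(records: pd.DataFrame, min_seconds: float = 60.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (retained, excluded) by per-text reading time.

    A reading is excluded iff ``reading_seconds < min_seconds`` (exactly the
    cutoff is retained); records with missing timing go to the excluded
    frame flagged ``missing_timing`` so they are never analysed unverified
    but remain visible.  Retained rows are returned unaltered.
    """
    secs = pd.to_numeric(records["reading_seconds"], errors="coerce")
    missing = secs.isna()
    fast = ~missing & (secs < min_seconds)
    excluded = records[missing | fast].copy()
    excluded["exclusion_reason"] = np.where(missing[missing | fast],
                                            "missing_timing", "fast")
    return records[~(missing | fast)].copy(), excluded


def one_way_anova(*groups) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA over the given value groups.

    F = MS_between / MS_within from the between/within sum-of-squares
    decomposition; p is the upper tail of the F(df_between, df_within)
    distribution.  Degenerate zero-within-variance data give F = 0, p = 1
    when the group means agree and F = inf, p = 0 when they differ.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("one_way_anova needs >= 2 groups of >= 2 observations")
    n_total = sum(a.size for a in arrs)
    grand = sum(a.sum() for a in arrs) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    means = tuple(float(a.mean()) for a in arrs)
    sds = tuple(float(a.std(ddof=1)) for a in arrs)
    ns = tuple(int(a.size) for a in arrs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(group_means=means, group_sds=sds, group_ns=ns,
                       f_value=float(f), p_value=p,
                       df_between=df_between, df_within=df_within)


def pearson_one_tailed(x, y) -> tuple[float, float]:
    """Pearson r with a one-tailed (positive-association) p-value.

    p is the upper tail of Student's t with n-2 degrees of freedom at
    ``t = r sqrt((n-2) / (1-r^2))``.  Requires n >= 3 and nonzero variance
    on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_one_tailed needs paired samples with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return r, 0.0 if r > 0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(sps.t.sf(t, n - 2))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold: ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def build_report(records: pd.DataFrame,
                 measures: list[str] | None = None) -> pd.DataFrame:
    """Condition-wise mean (SD) table with ANOVA columns, one row per measure.

    A row whose measure is missing for a condition (empty cell) is kept but
    flagged, with NaN statistics — cells are never fabricated.
    """
    measures = measures or [m for m in MEASURE_COLUMNS if m in records.columns]
    rows = []
    for m in measures:
        groups = [pd.to_numeric(records.loc[records["condition"] == c, m],
                                errors="coerce").dropna().to_numpy()
                  for c in CONDITIONS]
        if any(g.size < 2 for g in groups):
            rows.append({"measure": m,
                         "mean_original": np.nan, "sd_original": np.nan,
                         "mean_simplified": np.nan, "sd_simplified": np.nan,
                         "f_value": np.nan, "p_value": np.nan,
                         "flag": "insufficient_data"})
            continue
        res = one_way_anova(*groups)
        rows.append({"measure": m,
                     "mean_original": res.group_means[0],
                     "sd_original": res.group_sds[0],
                     "mean_simplified": res.group_means[1],
                     "sd_simplified": res.group_sds[1],
                     "f_value": res.f_value, "p_value": res.p_value,
                     "flag": ""})
    return pd.DataFrame(rows)


def secondary_accuracy(records: pd.DataFrame) -> pd.Series:
    """Per-reading mean accuracy over the with/after-reading items only."""
    cols = [c for c in ACCURACY_COLUMNS if c in records.columns]
    if not cols:
        raise ValueError("no accuracy question columns present")
    return records[cols].astype(float).mean(axis=1)


def demographic_correlations(records: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """One-tailed correlations of accuracy with education and language level.

    Computed overall and within each condition; the Bonferroni threshold
    reported alongside divides ``alpha`` by the four per-condition tests.
    """
    acc = secondary_accuracy(records)
    rows = []
    subsets = [("all", records.index)] + [
        (c, records.index[records["condition"] == c]) for c in CONDITIONS]
    for demo in ("education_level", "language_level"):
        for name, idx in subsets:
            x = records.loc[idx, demo].astype(float)
            y = acc.loc[idx]
            try:
                r, p = pearson_one_tailed(x, y)
            except ValueError:
                r, p = np.nan, np.nan
            rows.append({"demographic": demo, "subset": name,
                         "r": r, "p_one_tailed": p, "n": len(idx)})
    out = pd.DataFrame(rows)
    out["bonferroni_threshold"] = bonferroni_threshold(alpha, 4)
    return out


def per_text_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Mean question accuracy per text and condition (study-overview shape)."""
    acc = secondary_accuracy(records)
    frame = records.assign(accuracy=acc)
    return (frame.pivot_table(index="text_id", columns="condition",
                              values="accuracy", aggfunc="mean")
            .reset_index())
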