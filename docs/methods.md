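# Methods

This note documents the models and procedures implemented in `simpedit`,
the parameters that matter, the numerical choices, and what the synthetic
data does and does not establish.

## Text substrate

Tokenization is rule-based and deterministic: maximal `\w+` runs optionally
glued by internal hyphens/apostrophes are word tokens; any other non-space
run is punctuation. Offsets are half-open `[start, end)` character ranges
and concatenating surfaces with the original inter-token text reproduces
the input exactly — this round-trip invariant is what makes the edit log
sound. Sentences end at `. ! ?` followed by an uppercase-initial (or digit-
initial) token or end of text, with a configurable abbreviation list
(`Dr.`, `e.g.`, …). A trained sentence splitter would be more accurate on
noisy prose; for the encyclopedic register this package targets, the rule
splitter is accurate and, unlike a model, fully reproducible.

Part-of-speech tags come from a small heuristic over closed-class word
lists, derivational suffixes (`-tion/-ment/… → NOUN`, `-ize/-ify/… → VERB`,
`-ous/-ive/… → ADJ`, `-ly → ADV`) and minimal left context, mapped onto six
coarse tags `{NOUN, VERB, ADJ, ADV, OTHER, PUNCT}`. This is deliberately
not a general tagger: it exists to support noun/verb counts and noun
chaining. Counts that depend on it (noun, verb, chain counts) are
tagger-sensitive and should be compared across texts *within* this package,
not against counts produced by other toolchains.

Syllables use the vowel-group heuristic: count maximal `aeiouy` runs,
drop a silent final `e` unless it carries the word's only vowel group,
floor at 1; hyphen/apostrophe parts are counted separately. The
Flesch-Kincaid implementation is the **grade-level** variant
`0.39·(words/sentences) + 11.8·(syllables/word) − 15.59`; it can be
negative for very simple text. Published grade values for a given text vary
by a point or so across tokenizers and syllabifiers; treat cross-tool
comparisons accordingly.

## Difficulty flagging and the two sliders

The editor's two sliders are specified behaviorally (each monotonically
increases what is shown); the concrete semantics here are package design
choices:

- **Simplification level** `s ∈ [0,1]`: the difficulty threshold is the
  `s`-quantile of the frequency lexicon's count distribution. A span is
  flagged iff it has a known substitution and its frequency (minimum token
  frequency for multiword phrases; 0 for out-of-lexicon words) is strictly
  below the threshold. Quantiles are monotone in `s`, and because a
  phrase's frequency is the minimum over its tokens, longest-match
  resolution cannot reduce the flagged count as `s` grows — the monotone
  slider contract holds exactly, not just empirically.
- **Variety level** `v ∈ [0,1]`: the candidate list is truncated to
  `k ∈ {1, 3, 5, 8}` by quartile of `v`, never below 1.

Candidate scores are cosine similarities between a candidate's mean word
vector and the mean vector of the *other* words in the sentence. This
average-context filter is intentionally isolated behind one scoring
function so a stronger contextual model can be swapped in without touching
the engine. Ties and unscorable (out-of-vocabulary) candidates preserve
lexicon order; unscorable candidates sort after scored ones and carry an
absent score rather than a fabricated 0, since cosine 0 is a meaningful
value.

Sentence rules are case-insensitive regular expressions over the sentence
text. A regex cannot express every syntactic construction, but it covers
the catalog shipped here (nominalization, passive voice, literal phrase
patterns) and keeps rule files hand-editable. Rule examples are fixed,
generic strings — they are not adapted to the text's topic.

## Lexical chains

Nouns only, scanned left to right; a token joins the **most recently
updated** chain containing a related member, else opens a new chain —
the standard greedy construction, deterministic by design. Relatedness
widens across three levels: exact (same lemma, after crude
depluralization), synonym (shared synonym-set id), semantic (synonym
criteria or embedding cosine ≥ θ, default θ = 0.6). Only chains with ≥ 2
members are reported; singleton "chains" are not cohesion evidence, and
counting them would roughly triple chain counts on typical prose. Two
chains *cross* iff their spans interleave without nesting:
`min(A) < min(B) ≤ max(A) < max(B)`. Since every relation that holds at a
stricter level holds at looser ones, member pairs chained at EXACT remain
chained at SYNONYM and SEMANTIC (given θ ≤ 1), which the tests enforce as
a property.

## Text statistics and the comparison report

Average word frequency is the mean corpus count over **in-lexicon** word
tokens; out-of-lexicon tokens are excluded rather than counted as zero
(zeros would make the statistic measure lexicon coverage, not word
difficulty), and coverage is always reported alongside. Percent changes
are `(simplified − original)/original × 100`, rounded half-away-from-zero
to one decimal — the convention used when such tables are printed — and
reported as absent when the original value is zero.

## Recall metrics

All metrics lowercase and strip punctuation; no stemming or stopword
removal by default (both available as switches). The participant's answer
is the candidate and the stimulus text is the reference, so a short but
accurate answer scores high precision and low recall — the regime these
measures are designed to show for free recall against a full text. ROUGE-N
uses clipped n-gram counts; ROUGE-L uses the token-level longest common
subsequence. Degenerate inputs (empty answer) yield an all-zero score with
an explicit flag instead of an exception, because empty recalls are real
data. The word-proportion metrics use a similarity threshold τ (default
0.5) on the maximum cosine between an answer word and any text word;
`prop_similar ≥ prop_matching` holds by construction. Cosine values depend
heavily on preprocessing and embedding choice, so absolute cosines are
comparable only within one configuration.

## Study analysis

One reading (participant × text) is the unit of observation. Readings
faster than 60 s are excluded *per text* — a strict `< 60` cutoff, so a
reading at exactly one minute is retained — and records with missing
timing are routed to the excluded set flagged `missing_timing` rather than
silently dropped or analysed unverified. Each dependent measure gets a
one-way fixed-effects ANOVA over the two text versions; between/within
sums of squares are computed directly and the p-value is the upper tail of
the F distribution (via scipy's regularized-incomplete-beta machinery).
For two groups, F equals the squared pooled two-sample t statistic; the
test suite enforces agreement to 1e-9 against an independent
implementation. Degenerate data are defined, not crashed: zero within-group
variance gives F = 0, p = 1 when means agree and F = ∞, p = 0 when they do
not.

Repeated measures per participant are treated as independent observations.
This matches the analysis the pipeline is built to reproduce, but it is a
real caveat: within-participant correlation would make the nominal p-values
anticonservative on data with strong participant effects. The synthetic
generator draws readings independently, which is why the type-I calibration
below comes out at the nominal level.

Secondary analyses use one-tailed Pearson correlations (positive
association; p from the upper tail of t with n−2 df) between question
accuracy and two documented ordinal codings: education level 1–6 (less
than high school … doctorate) and English-at-home level 1–5 (never …
only). Accuracy averages the items answered **with or after** the text —
the 2 while-reading multiple-choice, 5 after-reading true/false and 4
after-reading multiple-choice items — excluding the 5 before-reading items,
which measure prior knowledge, not reading outcome. With four per-condition
correlation tests, the Bonferroni threshold at family α = 0.05 is 0.0125.

## Synthetic generator

The generator emulates the structure of a two-condition reading study so
the pipeline can be exercised and calibrated offline:

- 49 participants × 4 texts, 2 original + 2 simplified each, assigned by
  the 6 counterbalancing combinations (C(4,2) ways of choosing which two
  texts are original), text order randomized per participant.
- Perceived difficulty: a 4-point Likert item drawn from a discretized
  normal (bins at 1.5/2.5/3.5, tails absorbed), latent mean 2.28 for
  original text, +0.27 under simplification, latent SD 0.70. The exact
  population mean of the discretized distribution is available
  (`likert_population_mean`), so effect-recovery tests compare estimates
  against the generator's true discretized effect (≈ 0.264 at the default
  parameters) instead of the latent 0.27.
- Question correctness: Bernoulli per item with per-question baseline
  accuracies (defaults in the 0.33–0.93 range, matching the spread real
  comprehension items show between floor and ceiling) and per-question
  simplified-condition probabilities.
- Recall metrics and expert scores: clipped normals with condition-specific
  means/SDs; expert scales discretized to their 0–4 ranges.
- Reading time: 20.9% of readings uniform below the 60 s cutoff, the rest
  lognormal (median 160 s) floored at 60 s.

`zero_effect_config` removes every condition effect for type-I-error
calibration. Over 2000 null seeds the perceived-difficulty ANOVA rejects at
≈ 0.044 (the acceptance checks use 500 seeds for a stable estimate inside
a sensible runtime); the small shortfall from 0.05 reflects seed-level
variation in retained sample size, not a biased test — the same ANOVA on
fixed-size categorical draws rejects at 0.050 over 20 000 replicates.

What the synthetic data does **not** establish: it contains no actual
language in the response fields (recall metrics are drawn, not computed
from generated answers, except for the separate toy answers corpus), no
participant random effects, and no ordering/fatigue effects. Passing
calibration tests on it therefore validates the *pipeline arithmetic*, not
conclusions about real readers.

## Embedding fixtures

Synthetic embeddings reserve one coordinate axis per designed synonym
group and per designed distractor word. Group members are the group axis
plus a small random perturbation (norm 0.08, zeroed on all reserved axes),
renormalized — guaranteeing within-group cosine ≥ 0.98 and
group-to-distractor cosine ≤ 0.08 by construction, not by luck of the
seed. Remaining vocabulary receives seeded random unit vectors with no
geometric guarantees. Default dimension is 32; real studies use
300-dimensional pretrained embeddings, which the resource reader accepts
in the standard word2vec text format.

## Problem sizes and determinism

All stochastic checks are seeded and deterministic. The acceptance script
uses 500 null-generator seeds for the type-I rate, 60 seeds for effect
recovery, 100 random datasets for the ANOVA/t² cross-check, and 100 random
token pairs (in the tests) for the ROUGE-vs-oracle comparison; these sizes
put Monte-Carlo error well below the decision thresholds while keeping the
whole run around ten seconds.

## Known limitations

- The POS tagger and syllabifier are heuristics; tag- and
  syllable-dependent statistics are internally consistent but not
  interchangeable with other tools' outputs.
- The context filter is a mean-of-embeddings model; it cannot
  disambiguate senses and degrades when most sentence words are
  out-of-vocabulary.
- Sentence rules are surface patterns; they miss constructions that need
  parse structure and can over-fire inside quotations.
- The ANOVA ignores the repeated-measures structure (documented above).
- The substitution lexicons and frequency list shipped as fixtures are
  tiny and synthetic; production use requires real resources in the same
  formats.
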