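# simpedit

A text-simplification editor engine for consumer health text, together with
the measurement pipeline used to evaluate whether simplification actually
helps readers.

Health materials are routinely written above the recommended 6th–8th grade
reading level, and a writer who wants to fix that gets little concrete help
from readability formulas alone. `simpedit` implements the engine behind a
human-in-the-loop simplification editor — the algorithms that tell a writer
*where* a text is hard and *what* to do about it — plus everything needed to
evaluate the result, both at the text level (readability and cohesion
statistics) and at the reader level (comprehension-study analysis).

## What it does

**Editor engine**

- **Difficult word/phrase detection.** A span is flagged when a substitution
  is known for it and its corpus frequency falls below a threshold set by
  the *simplification level* slider — interpreted as a quantile of the
  frequency lexicon's count distribution, so the flagged-span count is
  monotone in the slider. Multiword phrases use their minimum token
  frequency; matching is leftmost-longest.
- **Context-filtered substitution ranking.** Each candidate *c* for a
  flagged span is scored by cosine(v_c, v_ctx), where v_c is the mean word
  embedding of the candidate and v_ctx the mean embedding of the other
  words in the sentence. The *variety level* slider controls how many
  ranked candidates are shown (1, 3, 5 or 8).
- **Sentence-structure rules.** A rule catalog (pattern, guidance, fixed
  generic example) flags constructions such as nominalizations
  ("utilization of …" → "using …"), passives, and vague duration phrases.
- **Lexical chains.** Threads of related nouns at three widening match
  levels — exact lemma, shared synonym set, embedding cosine ≥ θ — with
  chain statistics including the number of *crossing* chain pairs
  (interleaved-but-not-nested spans), a known difficulty signal.
- **Statistics tab.** Word/sentence/noun/verb counts, average word
  frequency, exact-chain count and the Flesch-Kincaid grade
  `0.39·W/S + 11.8·Syl/W − 15.59`, plus an original-vs-simplified report
  with one-decimal percent changes.
- **Edit log.** Every replacement is an append-only, version-hashed event;
  replaying the log over the original text reproduces the final text
  exactly.

**Evaluation pipeline**

- **Free-recall scoring**: ROUGE-1/2/L precision/recall/F (answer =
  candidate, stimulus text = reference), mean-embedding cosine similarity,
  and the proportions of answer words matching or semantically similar to
  the text.
- **Study analysis**: per-text exclusion of readings under 60 s, one-way
  ANOVA by text version (original vs simplified) for every measure,
  one-tailed Pearson correlations of question accuracy with education and
  home-language level, Bonferroni thresholds, and report tables in the
  shape of a two-condition results table.
- **Synthetic data**: seeded generators for tiny embeddings with designed
  geometry, lexicons, rule catalogs, a toy original/simplified text pair,
  and counterbalanced participant responses (49 participants × 4 texts by
  default) with injectable condition effects — so the whole stack runs and
  is testable offline.

## Worked example

Generate the synthetic resources and compare the toy original text with its
simplified counterpart:

```bash
simpedit fixtures --seed 1 --out fx
simpedit simplify fx/texts/toy_original.txt \
    --freq fx/frequencies.tsv --subs fx/substitutions.tsv \
    --emb fx/embeddings.txt --rules fx/rules.tsv --level 0.5 --variety 1.0
```

```
[54:61] 'utilize' -> use
[87:95] 'commence' -> start, begin
[99:108] 'physician' -> doctor
[158:168] 'Subsequent' -> following, later, followed by
[245:260] 'adverse effects' -> bad effects, side effects
[141:156] 'months or years' (rule duration-phrase): State the time span directly instead of an open-ended range.
[212:226] 'utilization of' (rule nominalization): Replace the nominalization with the verb it comes from.
[282:292] 'is reduced' (rule passive-voice): Rewrite in active voice: say who does the action.
```

Each line is a flagged character span with its ranked substitutions
(embedding-context order) or the matched sentence rule with its guidance.
Comparing the two text versions:

```bash
simpedit compare fx/texts/toy_original.txt fx/texts/toy_simplified.txt \
    --freq fx/frequencies.tsv
```

reports, among other fields, `avg_word_frequency: +12.6%` (the simplified
text uses more common words) and `flesch_kincaid_grade: 8.67 → 5.29
(−39.0%)` — the signature expected of a successful simplification.

Running the study pipeline end to end on synthetic responses:

```bash
simpedit analyze-study fx/responses.csv
```

filters out the fast readings, prints the per-measure mean (SD) table with
F and p per measure, the demographic correlations with their Bonferroni
threshold (0.0125 for four post-hoc tests), and per-text accuracies.

## Layout

| Module | Role |
| --- | --- |
| `simpedit.core_text` | tokenization, sentences, POS, syllables, Flesch-Kincaid |
| `simpedit.resources` | frequency/substitution lexicons, word2vec-text embeddings, rule catalogs |
| `simpedit.engine` | span flagging, candidate ranking, rules, edits, event log |
| `simpedit.chains` | lexical chains and crossing statistics |
| `simpedit.text_stats` | statistics tab and comparison report |
| `simpedit.recall_metrics` | ROUGE-1/2/L, embedding cosine, word proportions |
| `simpedit.study_analysis` | filtering, ANOVA, correlations, report tables |
| `simpedit.fixtures` | seeded synthetic resources and responses |
| `simpedit.cli` | `simpedit` command-line entry point |

See `docs/methods.md` for the models, parameter choices and limitations.
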