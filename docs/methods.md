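# Methods

## The rubric and its assumptions

`nmp_tsat` operationalizes a Tier-1 study-quality screening rubric for
nano- and microplastic (NMP) toxicity studies. Each criterion captures one
reporting/QA-QC element of a study and is scored ordinally: 0 (inadequate),
1 (adequate with restrictions), 2 (adequate). Scores are assigned by human
raters reading the study; the package validates, merges, aggregates and
classifies them — it never scores papers itself.

All criteria carry equal weight. The total assessment score (TAS) is the
plain sum, so its maximum is twice the criterion count: 52 for the in vivo
registry (26 criteria: 8 particle characterization, 13 study design, 5 risk
assessment) and 46 in vitro (23: 8 + 11 + 4). The equal-weight assumption
means TAS is a reporting-completeness index, not a validity judgement; the
red-criteria gate exists precisely because ranking by TAS alone would let
broad-but-shallow reporting outrank studies that nail the critical items.

### The shipped registries

The exact criterion wording of the original tool's guidance tables is not
publicly printed, so the shipped defaults reconstruct the roster from the
narrative descriptions of the three assessment areas, constrained to the
known 26/23 totals and with level guidance written from the same
descriptions (e.g. level 2 on dose-response requires at least three
concentration doses plus control with a ≥ 3× concentration range; level 2
on exposure verification requires quantified tissue burdens rather than
histological impressions). Registries are plain YAML/JSON documents;
users are expected to edit them — the file format, the validator and the
red-set logic treat the defaults as just another registry.

The default red set is the four particle-characterization criteria (size,
shape, polymer, source) plus the risk-assessment criteria on endpoints and
dose-response, and additionally effect thresholds in vivo. The gate level
(`red_min_level`, default 1) and the whole red set are configurable because
the appropriate critical set depends on the screening purpose (e.g.
point-of-departure derivation vs mechanistic weight-of-evidence).

## Consensus

Studies are scored by at least two raters. No published reconciliation rule
exists, so three are offered:

* `min` (default) — pointwise minimum. Conservative: a criterion is only as
  adequate as the most skeptical rater found it. Chosen as default because
  Tier-1 screening is a gate, and gates should not pass on the optimistic
  reading.
* `mode` — per-criterion majority, ties broken to the lower level (again
  conservative).
* `strict` — any disagreement is an error; for audited workflows where
  raters must reconcile manually.

Disagreements are always recorded per criterion with each rater's level,
regardless of rule. Inter-rater statistics (kappa etc.) are deliberately
out of scope.

## Percent conversion

Integer percent-of-maximum uses round-half-away-from-zero, implemented in
exact integer arithmetic (`(200·t + m) // (2m)`). This is the only integer
rounding rule consistent with all five canonical TAS/percent pairs
(44/52 → 85, 37/52 → 71, 34/46 → 74, 12/52 → 23, 16/46 → 35). Corpus mean
TAS is kept unrounded and its percent is computed from the unrounded mean;
display rounding happens only in reports.

## Classification schemes

* **Red gate / Tier-1**: pass iff every red criterion ≥ `red_min_level`.
  Prioritized studies are exactly the red-pass studies.
* **Reliability classes**: the published cut-offs ("> 85 %", "61–85 %",
  "< 61 %") are applied strictly above 0.85 and inclusively at 0.61 and
  0.85. The default basis is the *fraction of criteria at the maximum
  score* (the cut-offs were formulated for a 0/1 rubric, where "questions
  receiving the maximum score" is the natural quantity); a TAS-percent
  basis is offered because on a 0-2 rubric the two framings diverge — an
  all-ones study has TAS at 50 % of maximum but no criterion at the
  maximum, and is not reliable under either basis. Neither basis is
  asserted as canonical.
* **Adequacy**: no criterion at 0. With `red_min_level = 1` this implies
  the red gate, and any non-"not reliable" class implies the red gate;
  both implications are property-tested.

There is no "not applicable" level in the shipped registries: the fixed
maxima (52/46) imply every criterion always applies.

## Synthetic corpus generation

The fixture generator produces multi-rater corpora whose min-consensus TAS
equals prescribed targets exactly — including the 15-study prioritized
in vivo corpus with the published TAS column (44, 37, 37, 34 ×4, 31, 30 ×2,
27 ×4, 23) and its study metadata (exposure route, material class, polymer,
shape). Composition: red criteria are floored at the gate level when the
study must pass the gate; remaining points are added one at a time to
uniformly drawn criteria below the cap of 2 (always feasible within the
validated target range, so no rejection is needed). An anchor rater carries
the composed scores; each additional rater deviates by one level per
criterion with probability `rater_noise` (default 0.1, two raters), with
deviations clamped to [base, 2] so the pointwise minimum — and hence the
min-consensus TAS — is invariant while discordance still occurs. Generation
is deterministic given the seed; cross-seed corpora differ in composition
but not in TAS.

What the generator does *not* emulate: correlated criterion quality within
a study (real studies that characterize particles well tend to score well
across the particle block), rater bias, and any relationship between
metadata and scores. Passing tests therefore demonstrate correctness of
scoring, screening and aggregation arithmetic on realistic score *totals*,
not realism of score *patterns*; per-criterion distribution analytics on
synthetic corpora are structural checks only.

## Numerical and degenerate-input choices

* Reliability cut-off comparisons are float comparisons against exact
  fractions (n_max / n); at the printed boundaries (0.85, 0.61) both sides
  round to the same double, so inclusivity behaves as specified.
* Screening output order: prioritized first, TAS descending, then study_id
  ascending — input-order invariant. The prioritization table uses the same
  TAS/study_id tie-break.
* Empty corpus: distributions return an empty list; the corpus summary
  raises (there is nothing to summarize); Tier-1 screening returns an
  empty list.
* A registry without red criteria is flagged by the validator and is a
  hard error for the red gate.
* Evaluation sheets are read with the stdlib csv module so malformed rows
  can be reported with line numbers; duplicates and unknown criterion ids
  are collected and reported together rather than failing on the first.

## Problem sizes

The randomized sweeps use 500 brute-force oracle corpora (up to 26 criteria
x 5 studies), 300 implication/monotonicity draws, and 200 random fixture
specifications; the full suite and the acceptance script each run in a few
seconds on one CPU.

## Known limitations

* The shipped criterion wording is a reconstruction; counts, categories,
  red flags and maxima are faithful, label text is paraphrase.
* Corpus counts are whatever the input contains; the package does not try
  to reproduce any particular published corpus census.
* No automated extraction of scores from papers, no Tier-2 elicitation
  workflow, no weighting schemes, no NOAEL/LOAEL/BMD computation — the
  effect-threshold criterion records whether a threshold is derivable, not
  its value.
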