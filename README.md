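# nmp-tsat

Screening and prioritization of nano- and microplastic (NMP) toxicity
studies for human health risk assessment.

The peer-reviewed literature on NMP health effects is growing far faster
than regulators can evaluate it, and almost none of it comes from
standardized test guidelines. `nmp_tsat` implements a Tier-1 screening
rubric for that literature: a configurable registry of QA/QC criteria
covering **particle characterization**, **study design** and
**applicability for risk assessment**, scored per criterion as adequate (2),
adequate with restrictions (1) or inadequate (0) by one or more human
raters. The library validates and merges rater scores, aggregates them, and
classifies every study under three screening schemes so that risk assessors
can prioritize studies for Tier-2 expert elicitation. It is aimed at risk
assessors, systematic reviewers and researchers who need a transparent,
reproducible evidence-appraisal pipeline rather than ad-hoc spreadsheets.

## The scoring model

For a registry of $n$ criteria with per-rater scores
$s_i \in \{0, 1, 2\}$, the **total assessment score** is the equal-weight sum

$$\mathrm{TAS} = \sum_{i=1}^{n} s_i, \qquad
  \mathrm{TAS}_{\max} = 2n,$$

giving $\mathrm{TAS}_{\max} = 52$ for the shipped in vivo registry
($n = 26$) and $46$ in vitro ($n = 23$). The integer percent of maximum
uses round-half-away-from-zero. Multi-rater score maps are merged by a
consensus rule (`min` by default — the pointwise minimum — with `strict`
and `mode` available), and every disagreement is recorded.

Three screening schemes are computed per study:

* **Red-criteria Tier-1 gate** — pass iff every *red* (critical) criterion
  scores ≥ 1, regardless of TAS. The default red set is particle size,
  shape, polymer type and particle source, plus the risk-assessment
  criteria on endpoints and dose-response (and, in vivo, effect
  thresholds); it is fully configurable.
* **Reliability classes** (after Fernández-Cruz-style cut-offs) —
  *reliable* if > 85 % of criteria are at the maximum score and the red
  criteria are met; *reliable with restrictions* for 61–85 %; otherwise
  *not reliable*.
* **Adequacy** (after de Ruijter-style screening) — adequate iff no
  criterion scores 0.

Corpus-level analytics produce per-criterion score distributions stratified
by (study system, exposure route, material class), TAS league statistics,
particle-metadata summaries, and a markdown/CSV prioritization report.

## Worked example

```sh
tsat fixtures --table1 --seed 7 -o table1.csv   # synthesize the corpus
tsat screen table1.csv | head -4
```

```
study_id,study_system,tas,tas_max,tas_percent,max_score_fraction,red_pass,failing_red,fernandez_class,de_ruijter_adequate,tier1_prioritized
ong_2020,in_vivo,44,52,85,0.7307692307692307,True,,reliable_with_restrictions,False,True
lim_2021,in_vivo,37,52,71,0.5769230769230769,True,,not_reliable,False,True
mahock_2012,in_vivo,37,52,71,0.5384615384615384,True,,not_reliable,False,True
```

The `fixtures --table1` command synthesizes the 15 prioritized in vivo
studies with their published TAS column (44, 37, 37, 34 ×4, 31, 30 ×2,
27 ×4, 23 of 52) recovered exactly under min-consensus; `screen` shows that
every study passes the red gate (`red_pass=True`, `tier1_prioritized=True`)
— they were prioritized precisely because the critical criteria are met —
while the top study reaches 44/52 (85 %) with 73 % of criteria at the
maximum score. From Python the same pipeline is
`generate_fixture` → `consensus` → `summarize` → `tier1_screen`
(see `examples/screen_prioritized_corpus.py`, which prints the
prioritization table above; `examples/score_single_study.py` and
`examples/rubric_helpers.py` cover single-study scoring and the advisory
dose-response / particle-size helpers).

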