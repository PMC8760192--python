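"""Score one study rated by two assessors and summarize the consensus.

Builds two slightly disagreeing 0/1/2 score maps over the default in vivo
registry (26 criteria, max TAS 52), merges them with the conservative
minimum rule, and prints the category subtotals, the total assessment score
(TAS) and its percent of the maximum.
"""

from nmp_tsat import (
    StudyEvaluation,
    consensus,
    default_registry,
    summarize,
)

reg = default_registry("in_vivo")

# rater 1: reds adequate-with-restrictions, most study design adequate
scores_r1 = {cid: 1 for cid in reg.ids}
for cid in reg.ids:
    if cid.startswith("sd_"):
        scores_r1[cid] = 2
scores_r1["pc_microbial_contamination"] = 0

# rater 2 agrees except on two criteria
scores_r2 = dict(scores_r1, sd_stability=1, ra_statistics=2)

evals = [
    StudyEvaluation("example_2024", f"rater_{i}", reg.name, s)
    for i, s in enumerate((scores_r1, scores_r2), start=1)
]
merged = consensus(evals, "min")
summary = summarize(merged, reg)

print(f"criteria with rater disagreement: {[cid for cid, _ in merged.discordant]}")
for cat, subtotal in summary.subtotals.items():
    print(f"subtotal {cat.value}: {subtotal}")
print(f"TAS: {summary.tas} / {summary.tas_max} ({summary.tas_percent}%)")
print(f"criteria at maximum score: {summary.max_score_fraction:.0%}; zeros: {summary.n_zero}")
# The minimum rule keeps the lower of any disagreeing pair, so the consensus
# TAS is a floor on what either rater alone would have awarded.
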