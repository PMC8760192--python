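"""Advisory rubric helpers: dose-response score suggestion and particle-size
absorption context.

These helpers encode the quantitative parts of the scoring guidance.  They
annotate reports and assist raters; they never overwrite an assigned score.
"""

from nmp_tsat import particle_size_context, suggest_dose_response_score

designs = [
    (3, True, 3.0),   # three doses + control, 3x range: adequate
    (2, True, 10.0),  # only two doses: adequate with restrictions
    (1, False, None), # single dose, no control: inadequate
]
for n_doses, has_control, ratio in designs:
    level = suggest_dose_response_score(n_doses, has_control, ratio)
    print(f"doses={n_doses} control={has_control} range={ratio}: suggest score {level}")

for size_um in (200.0, 50.0, 1.0):
    print(f"median size {size_um:g} um: {particle_size_context(size_um).value}")
# Particles above 150 um are unlikely to be absorbed after oral exposure
# (local intestinal effects only); below 1.5 um they can cross the epithelium
# and may act systemically.
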