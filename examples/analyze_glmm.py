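"""Fit the binomial GLMMs with the study's model-reduction rules.

For each response (approached; eaten; eaten restricted to approached
trials) the analysis starts from the full factorial model
trial x pattern x contrast plus a batch main effect, with a per-chick
random intercept, then (1) pools over batches if batch is non-
significant and (2) drops the three-way interaction only if that lowers
AIC.  Wald chi-square statistics test each fixed term.
"""

from apostim import (
    BehaviorParams,
    DesignSpec,
    analysis_report,
    report_to_text,
    simulate_cohort,
)

records = simulate_cohort(DesignSpec(), BehaviorParams(seed=42))
report = analysis_report(records)
print(report_to_text(report))
print(
    "\nRead the contrast row of each Wald table: with the default synthetic "
    "effect sizes the high-vs-low contrast effect is the dominant term, the "
    "trial effect appears for eating but not approaching, and batch is "
    "pooled away — the qualitative structure the experiment reported."
)
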