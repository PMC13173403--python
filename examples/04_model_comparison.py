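"""Paired two-model cohort comparison with Wilcoxon signed-rank tests.

Model A and model B share the same per-patient geometric error amplitude
but model B's folds disagree four times less (epistemic_amp 0.25 vs 1.0)
— the situation where one architecture is more *reliable* without being
more *accurate*.  The comparison should flag mutual information and
ensemble variance as significantly lower for B while Dice stays
non-significant.  A small cohort keeps the run short.
"""

import warnings

from segcal.cohort import compare_models, evaluate_cohort, render_report
from segcal.synthetic import EnsembleSpec, generate_two_model_cohort

spec_a = EnsembleSpec(epistemic_amp=1.0, shared_amp=0.5)
spec_b = EnsembleSpec(epistemic_amp=0.25, shared_amp=0.5)
cohort = generate_two_model_cohort(8, spec_a, spec_b, seed=0)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    records_a = evaluate_cohort(cohort, "model_a")
    records_b = evaluate_cohort(cohort, "model_b")

comparisons = compare_models(records_a, records_b)
print(f"{'structure':16s} {'metric':8s} {'median A':>10s} {'median B':>10s} {'p':>8s}  sig")
for c in comparisons:
    print(
        f"{c.structure:16s} {c.metric:8s} {c.median_a:10.3g} {c.median_b:10.3g} "
        f"{c.p_value:8.3g}  {'*' if c.significant else ''}"
    )

render_report(comparisons, "scratch/example_report")
print(
    "\n'*' marks p < 0.05 (two-sided exact paired Wilcoxon). Uncertainty\n"
    "metrics separate the models; geometry does not. Full table written to\n"
    "scratch/example_report/report.md"
)
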