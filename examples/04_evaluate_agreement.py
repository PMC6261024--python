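"""Method-comparison study on a synthetic cohort.

Generates 200 patients (400 epochs), runs all five predictors against the
noisy "measured" final sodium, and summarizes agreement per predictor with
Bland-Altman bias/SD/limits of agreement and Percentage Similarity, overall
and by enrollment natremia subgroup. Also writes diagnostic plots.
"""

from natribalance import (
    CohortSpec,
    PredictorConfig,
    evaluate_cohort,
    generate_cohort,
    reports_to_csv,
    summary_text,
)
from natribalance.agreement import _series_for_predictor, agreement_plots

epochs = generate_cohort(CohortSpec(n_patients=200, seed=3))
config = PredictorConfig()
reports = evaluate_cohort(epochs, config)

print(summary_text([r for r in reports if r.subgroup == "all"]))
print()
print(summary_text([r for r in reports if r.predictor == "mass_balance"]))

reports_to_csv(reports, "agreement_report.csv")
series = {p: _series_for_predictor(epochs, p, config)[0] for p in config.predictors}
written = agreement_plots(reports, series, "agreement_plots")
print(f"\nreport table -> agreement_report.csv; {len(written)} plots -> agreement_plots/")

print(
    "\nThe mass-balance predictor shows near-zero bias with an SD near the "
    "2 mmol/L measurement noise (it generated the truth); the comparators "
    "show structured bias because each neglects part of the recorded fluid "
    "chart (e.g. Adrogue-Madias ignores urinary losses). Negative bias means "
    "under-prediction of the measured sodium."
)
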