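"""Generate a synthetic surgical cohort and run the cleaning pipeline.

Draws a registry-like cohort (~5.5% thirty-day readmission, hematocrit
mean ~39.7), removes patients who died without readmission, drops the
nearly-all-missing lab, imputes the rest, and prints the variables that
differ most between readmitted and non-readmitted patients.
"""

import readmit_rx as rx
from readmit_rx.pipeline import PreprocessConfig, preprocess_cohort

table, truth = rx.generate_cohort(rx.SyntheticSpec(n=8000), seed=7)
print(f"generated {table.n} surgeries, "
      f"{sum(c == 'pre_op' for c in table.var_class.values())} pre-operative "
      f"and {sum(c == 'post_op' for c in table.var_class.values())} "
      f"post-operative variables")
print(f"readmission rate: {100 * table.outcome.mean():.2f}%  "
      f"(generator target 5.49%)")

clean = preprocess_cohort(table, PreprocessConfig(), seed=0)
print(f"after cleaning: {clean.n} patients, {len(clean.var_names)} variables "
      f"(deaths without readmission excluded, sparse lab dropped, "
      f"missing values imputed)")

comparison = rx.cohort_comparison(clean)
print("\nmost significant readmitted vs non-readmitted differences "
      "(Welch t-test):")
cols = ["var_name", "mean_readmitted", "mean_non_readmitted", "p_two_tailed"]
print(comparison[cols].head(8).to_string(index=False,
                                         float_format=lambda v: f"{v:.4g}"))
print("\nlower hematocrit and higher morbidity probability among readmitted "
      "patients mirror the cohort facts the generator encodes.")
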