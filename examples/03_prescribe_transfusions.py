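"""Recommend pre-operative transfusions with P-SVM and a prescriptive tree.

Both methods consider patients with pre-operative hematocrit below 30 and
may raise it by 3 points per bag, up to 3 bags.  P-SVM fixes a sparse
linear risk score and enumerates the four doses per patient against a
penalty; the prescriptive tree learns per-leaf treatment arms from the
assumed baseline factuals.
"""

import readmit_rx as rx
from readmit_rx.pipeline import PreprocessConfig, preprocess_cohort

table, _ = rx.generate_cohort(rx.SyntheticSpec(n=8000), seed=7)
clean = preprocess_cohort(table, PreprocessConfig(), seed=0)
pre, _ = rx.partition_variables(clean)
hct = pre.data["HCT"].to_numpy()
candidates = hct < 30
print(f"{candidates.sum()} of {pre.n} patients are transfusion candidates "
      f"(HCT < 30)")

# --- P-SVM: sparse score + exact per-patient dose enumeration -----------
scaler = rx.fit_scaler(pre)
X = scaler.transform(pre.data)
base = rx.train_slsvm(X, pre.outcome, sparsity=8)
rule = rx.calibrate_threshold(base.score(X), pre.outcome)
policy = rx.train_psvm(base, scaler, lam_rx=0.001, rule=rule, hct_col="HCT")
psvm_bags = policy.prescribe(pre.data)
print(f"\nP-SVM: average {psvm_bags[candidates].mean():.2f} bags per "
      f"candidate; {(psvm_bags > 0).sum()} patients treated "
      f"(those whose readmission prediction a dose can flip)")

# --- prescriptive tree on baseline factuals -----------------------------
factuals = rx.assign_baseline_factuals(pre.data["HCT"], pre.data["TRANSFUS"])
# at ~5% outcome prevalence, thin treatment arms with zero observed events
# would otherwise win every leaf; n_arm_min makes them inherit the parent
# arm estimate instead
tree = rx.train_opt(pre.data, pre.outcome, factuals, max_depth=2,
                    min_leaf=300, alpha=0.5, seed=0, n_arm_min=75,
                    hct_col="HCT")
opt_bags = tree.prescribe(pre.data)
print(f"\nprescriptive tree (average {opt_bags[candidates].mean():.2f} bags "
      f"per candidate):")
print(tree.render_text())
print("\neach leaf shows the treatment arm with the lowest estimated "
      "readmission rate among its factual patients; candidates outside "
      "the leaf's arm still receive 0 bags when HCT >= 30.")
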