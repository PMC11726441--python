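"""Random-forest cross-LODO validation of the diet signal, with its
label-permutation negative control.

Cross-LODO runs repeated stratified CV inside each target cohort while
adding every other cohort's samples to the training folds as support; test
folds never leave the target cohort.  With strong planted signatures the
mean AUC approaches 1; permuting the labels must collapse it to ~0.5.
"""

from dietbiome import SimulationConfig, run_diet_classification, simulate_cohorts
from dietbiome.ml_validation import RFSpec

cfg = SimulationConfig(
    cohort_sizes=(250, 250, 250), n_features=120, n_signature_features=8,
    planted_smd=1.5, seed=3,
)
table, metadata, _, _ = simulate_cohorts(cfg)

kw = dict(scheme="cross_lodo", rf=RFSpec(n_trees=100), n_repeats=2, n_folds=4, seed=0)
real = run_diet_classification(table, metadata, ("omnivore", "vegan"), **kw)
null = run_diet_classification(table, metadata, ("omnivore", "vegan"),
                               permute_labels=True, **kw)

print(f"planted signal: mean AUC = {real.mean_auc:.3f} "
      f"(per cohort: { {c: round(a, 3) for c, a in real.cohort_mean_aucs.items()} })")
print(f"permuted labels: mean AUC = {null.mean_auc:.3f}")
print(
    "\nThe gap between the two is the evidence that the classifier reads "
    "diet-associated microbiome structure rather than leakage or cohort "
    "artifacts."
)
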