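"""Simulate a small multi-cohort dataset and score the healthful plant-based
diet index (hPDI) from its food-frequency table.

Each participant's 18 food-group intakes are quintile-scored 1-5 (healthy
plant groups positively, animal and less-healthy plant groups reversed) and
summed, so the index spans 18-90.  Because the generator couples intakes to
the diet label, vegans should score visibly higher than omnivores.
"""

from dietbiome import SimulationConfig, compute_hpdi, simulate_cohorts

cfg = SimulationConfig(cohort_sizes=(300, 300), n_features=80, seed=1)
table, metadata, ffq, truth = simulate_cohorts(cfg)

scores = compute_hpdi(ffq, cohorts=metadata.data["cohort"])
by_diet = scores.scores.groupby(metadata.data["diet"]).agg(["mean", "std", "count"])

print("hPDI by diet pattern (18 groups, score range 18-90):")
print(by_diet.round(1))
print(
    "\nA higher mean for vegans than omnivores reflects the planted "
    "diet-intake coupling; the spread within each diet is the quintile "
    "scoring's granularity."
)
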