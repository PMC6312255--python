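"""Separate dose effects from age effects, protein by protein.

Plants a proteome in which some proteins respond to dose, some to age,
some to both and some to nothing, then runs the backward stepwise AIC
regression (on Box-Cox transformed abundances) and compares the recovered
categories with the planted truth.
"""

import pandas as pd

from domix.deconvolution import deconvolve_matrix
from domix.simulate import simulate_cohort, simulate_proteome

metadata = simulate_cohort(seed=2)
abundance, truth = simulate_proteome(
    metadata,
    n_features=200,
    category_proportions={"dose_only": 0.35, "age_only": 0.25, "dose_age": 0.15, "none": 0.25},
    effect_size=3.0,
    seed=2,
)

table, counts = deconvolve_matrix(abundance, metadata)
print("recovered category counts:", counts)

merged = truth.merge(table, on="feature_id")
confusion = pd.crosstab(merged["true_category"], merged["category"])
print("\nplanted (rows) vs recovered (columns):")
print(confusion)
print(
    "\n-> despite dose and age being rank-correlated at ~0.7, the stepwise "
    "model attributes most planted dose effects to dose, not to age."
)
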