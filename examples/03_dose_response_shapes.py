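"""Classify dose-response patterns, including non-monotone shapes.

Runs Kruskal-Wallis screening with Storey's q-values, Dunnett many-to-one
comparisons against the unexposed controls, and the shape rule that
separates monotone up/down responses from U-shaped and cap-shaped (rise
then fall) ones.
"""

import numpy as np

from domix.dose_response import dose_response_table, summarize_dose_sets
from domix.io import RunConfig
from domix.simulate import simulate_cohort, simulate_proteome

metadata = simulate_cohort(seed=3)
abundance, truth = simulate_proteome(
    metadata,
    n_features=150,
    category_proportions={"dose_only": 0.4, "cap_shape": 0.15, "u_shape": 0.15, "none": 0.3},
    effect_size=3.0,
    seed=3,
)

table = dose_response_table(abundance, metadata, RunConfig(seed=3))
print("shape counts:", table["shape"].value_counts().to_dict())
print(f"pi0 estimate (fraction of null proteins): {table.attrs['pi0_hat']:.2f}")

summary = summarize_dose_sets(table)
print("per-group significant counts:", summary["per_group"])

cap = table[table["shape"] == "cap_shape"].iloc[0]
vals = abundance.values.loc[cap["feature_id"]]
means = np.log(vals).groupby(metadata.dose_group).mean()
print(f"\nexample cap-shaped protein {cap['feature_id']} group means (log scale):")
print(means.reindex(["control", "low", "medium", "high"]).round(2).to_string())
print(
    "-> the abundance rises at low/medium doses and drops below the control "
    "level at high doses: invisible to a linear dose model, caught here."
)
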