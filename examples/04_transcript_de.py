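"""Two-vs-two negative-binomial differential expression.

Simulates a 2-control vs 2-high-dose count matrix with planted fold
changes, then runs the count filter, median-of-ratios normalization,
trended dispersion estimation and the NB Wald test.
"""

import numpy as np

from domix.simulate import (
    simulate_cohort,
    simulate_feature_map,
    simulate_proteome,
    simulate_transcriptome,
)
from domix.transcript_de import replicate_correlation, run_de

metadata = simulate_cohort(seed=4)
_, truth = simulate_proteome(metadata, n_features=150, seed=4)
feature_map = simulate_feature_map(truth, 3000, seed=4)
counts, truth = simulate_transcriptome(
    metadata, feature_map, truth, n_genes=3000, depth=1e6, fold=4.0, seed=4
)

ctrl = [s for s in counts.sample_ids if metadata.dose_group[s] == "control"]
corr = replicate_correlation(counts, ctrl)
print(f"control replicate correlation: {corr['correlation'].iloc[0]:.3f}")

groups = metadata.subset(counts.sample_ids).dose_group.to_numpy()
table, removed = run_de(counts, groups, min_total=15, reference="control")
tested = table[~table["filtered"]]
sig = tested[tested["bh_adjusted_p"] <= 0.05]
print(f"{len(removed)} genes dropped (<15 total counts), {len(tested)} tested")
print(f"significant at BH 0.05: {(sig['log2_fold_change'] > 0).sum()} up, "
      f"{(sig['log2_fold_change'] < 0).sum()} down")

planted = {g for g in truth["paired_gene"] if g}
recall = sig.loc[sig['gene_id'].isin(planted)].shape[0] / len(planted)
print(f"planted genes recovered: {recall:.0%} "
      f"(median |log2FC| among planted: "
      f"{np.median(np.abs(tested.set_index('gene_id').loc[sorted(planted), 'log2_fold_change'])):.2f}, planted value 2.0)")
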