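"""Proteome-transcriptome integration by Fisher's combined probability test.

For every protein with a mapped, tested transcript, the high-dose-vs-control
p-values from the two omics layers are combined as -2(ln p1 + ln p2), which
is chi-square with 4 degrees of freedom under independent nulls; the
combined p-values receive one Benjamini-Hochberg correction. The
"restrictive" comparator instead demands each layer pass 0.05 on its own.
Direction coherence (protein and transcript moving the same way) is tracked
per pair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix, FeatureMap, RunConfig, SampleMetadata, ValidationError
from .transcript_de import bh_adjust

__all__ = [
    "protein_high_vs_control_p",
    "map_features",
    "fisher_combine",
    "bh_adjust",
    "integrate",
    "restrictive_intersection",
    "coherence_report",
]


def protein_high_vs_control_p(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of high-dose vs control, per protein.

    The exact null distribution is used whenever the combined sample size
    is <= ``exact_max_n`` and there are no ties; direction is the sign of
    the difference of group medians. Proteins with fewer than two
    non-missing values in either group are skipped.
    """
    meta = metadata.subset(abundance.sample_ids)
    controls = meta.group_samples("control")
    highs = meta.group_samples("high")
    rows = []
    for fid, series in abundance.values.iterrows():
        a = series[highs].to_numpy(float)
        b = series[controls].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p, u, direction = 1.0, len(a) * len(b) / 2.0, 0
        else:
            method = "exact" if len(a) + len(b) <= exact_max_n else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
            direction = int(np.sign(np.median(a) - np.median(b)))
        rows.append({"protein_id": fid, "protein_p": p, "U": u, "protein_direction": direction})
    return pd.DataFrame(rows)


def fisher_combine(p1: float, p2: float) -> tuple[float, float]:
    """Fisher's combination of two p-values.

    stat = -2 (ln p1 + ln p2); the combined p is the chi-square(4 df)
    survival at stat, which in closed form is exp(-stat/2) (1 + stat/2).
    Zero inputs are clamped to 1e-300 with a warning (discrete tests can
    emit exact zeros at machine precision).
    """
    ps = []
    for p in (p1, p2):
        if not np.isfinite(p) or p < 0 or p > 1:
            raise ValidationError(f"p-values must lie in (0, 1], got {p}")
        if p == 0:
            warnings.warn("p-value of 0 clamped to 1e-300 before Fisher combination")
            p = 1e-300
        ps.append(p)
    stat = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    combined = float(np.exp(-stat / 2.0) * (1.0 + stat / 2.0))
    return float(stat), min(combined, 1.0)


def map_features(
    protein_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    feature_map: FeatureMap,
) -> tuple[pd.DataFrame, list[str]]:
    """Match each tested protein with its minimum-p mapped, tested gene.

    Where several genes map to one protein the gene with the smallest
    p-value wins, ties broken by lexicographic gene id. Returns the matched
    pair table and the ids of tested proteins that had no tested mapped
    gene.
    """
    genes = gene_table.dropna(subset=["wald_p"]).set_index("gene_id")
    pairs = feature_map.pairs
    matched = []
    unmapped = []
    for _, prow in protein_table.iterrows():
        pid = prow["protein_id"]
        cand = pairs.loc[pairs["protein_id"] == pid, "gene_id"]
        cand = [g for g in cand if g in genes.index]
        if not cand:
            unmapped.append(pid)
            continue
        best = min(cand, key=lambda g: (genes.loc[g, "wald_p"], g))
        grow = genes.loc[best]
        matched.append(
            {
                "protein_id": pid,
                "chosen_gene_id": best,
                "protein_p": prow["protein_p"],
                "gene_p": float(grow["wald_p"]),
                "protein_direction": int(prow["protein_direction"]),
                "gene_direction": int(np.sign(grow["log2_fold_change"])),
            }
        )
    return pd.DataFrame(matched), unmapped


def integrate(matched: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine each matched pair and BH-correct across pairs."""
    if matched.empty:
        return matched.assign(
            fisher_stat=[], combined_p=[], bh_adjusted_combined_p=[], coherent=[]
        )
    stats_p = [fisher_combine(r.protein_p, r.gene_p) for r in matched.itertuples()]
    out = matched.copy()
    out["fisher_stat"] = [s for s, _ in stats_p]
    out["combined_p"] = [p for _, p in stats_p]
    out["bh_adjusted_combined_p"] = bh_adjust(out["combined_p"].to_numpy())
    out["coherent"] = (
        out["protein_direction"] * out["gene_direction"] > 0
    )
    return out


def restrictive_intersection(
    matched: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Pairs independently significant at ``alpha`` in both layers,
    partitioned by direction agreement (up/up, down/down, discordant)."""
    both = matched[(matched["protein_p"] <= alpha) & (matched["gene_p"] <= alpha)]
    up = both[(both["protein_direction"] > 0) & (both["gene_direction"] > 0)]
    down = both[(both["protein_direction"] < 0) & (both["gene_direction"] < 0)]
    discordant = both.drop(index=up.index.union(down.index))
    return {"up": up, "down": down, "discordant": discordant}


def coherence_report(records: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of BH-significant integrated pairs whose protein and
    transcript move in the same direction; NaN when nothing is significant."""
    sig = records[records["bh_adjusted_combined_p"] <= alpha]
    if sig.empty:
        return float("nan")
    return float(sig["coherent"].mean())
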