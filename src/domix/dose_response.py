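"""Group-wise differential analysis and non-monotone shape filtration.

Proteins are screened across the four dose groups with the Kruskal-Wallis
test under Storey's q-value FDR; significant proteins are then compared
many-to-one against the unexposed controls with Dunnett's test, and the
pattern of significant directions classifies each protein as up, down, or
non-monotone (U-shape: high at the extremes; cap-shape: high at
intermediate doses).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import DOSE_GROUPS, AbundanceMatrix, RunConfig, SampleMetadata, ValidationError
from .preprocess import boxcox_mle

__all__ = [
    "kruskal_wallis",
    "storey_qvalues",
    "dunnett_vs_control",
    "classify_shape",
    "dose_response_table",
    "summarize_dose_sets",
    "SHAPES",
]

SHAPES = ("up", "down", "u_shape", "cap_shape", "flat")


def _kw_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H for one label assignment."""
    ranks = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def _exact_kw_p(values: np.ndarray, labels: np.ndarray, observed: float) -> float:
    """Exact permutation p-value: enumerate all assignments of the pooled
    observations to groups of the given sizes."""
    groups, sizes = np.unique(labels, return_counts=True)
    idx = np.arange(len(values))
    count = 0
    total = 0

    def recurse(remaining: np.ndarray, gi: int, assignment: np.ndarray):
        nonlocal count, total
        if gi == len(groups) - 1:
            assignment[remaining] = gi
            total += 1
            if _kw_statistic(values, assignment) >= observed - 1e-12:
                count += 1
            return
        for combo in combinations(range(len(remaining)), sizes[gi]):
            sel = remaining[list(combo)]
            rest = np.delete(remaining, list(combo))
            assignment[sel] = gi
            recurse(rest, gi + 1, assignment)

    recurse(idx, 0, np.empty(len(values), int))
    return count / total


def kruskal_wallis(values, labels, exact_max_n: int = 10) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and its p-value.

    The p-value comes from the chi-square approximation with g-1 degrees of
    freedom, except for small samples (total n <= ``exact_max_n``) where the
    exact permutation distribution is enumerated instead.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups, sizes = np.unique(labels, return_counts=True)
    if len(groups) < 2 or (sizes < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h = _kw_statistic(values, labels)
    if len(values) <= exact_max_n:
        codes = np.searchsorted(groups, labels)
        return h, _exact_kw_p(values, codes, h)
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return h, p


def storey_qvalues(pvalues, lam: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0_hat = min(1, #{p > lambda} / (m (1 - lambda))); q-values are the
    step-up cumulative minimum of pi0_hat * m * p_(j) / j. When pi0_hat
    caps at 1 the q-values coincide with Benjamini-Hochberg adjusted p.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValidationError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


@dataclass(frozen=True)
class DunnettResult:
    """Many-to-one comparison outcome per treatment group."""

    groups: tuple[str, ...]
    statistic: np.ndarray
    pvalue: np.ndarray  # family-wise adjusted, two-sided
    direction: np.ndarray  # sign of (treatment mean - control mean)


def dunnett_vs_control(
    control,
    treatments: dict[str, np.ndarray],
    seed: int = 0,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparisons against a shared control.

    Family-wise adjusted p-values are obtained from the k-variate t
    distribution with the standard Dunnett correlation structure, evaluated
    by seeded quasi-Monte-Carlo integration. The adjusted p-values are
    reproducible for a fixed seed.
    """
    control = np.asarray(control, float)
    names = tuple(treatments)
    arrays = [np.asarray(treatments[g], float) for g in names]
    if len(control) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("control and every treatment group need >= 2 values")
    pooled_df = len(control) - 1 + sum(len(a) - 1 for a in arrays)
    ss = np.var(control, ddof=1) * (len(control) - 1) + sum(
        np.var(a, ddof=1) * (len(a) - 1) for a in arrays
    )
    if ss == 0:
        raise ValidationError("zero pooled variance: all observations identical within groups")
    res = stats.dunnett(
        *arrays,
        control=control,
        alternative="two-sided",
        random_state=np.random.default_rng(seed),
    )
    direction = np.sign([a.mean() - control.mean() for a in arrays])
    return DunnettResult(names, np.asarray(res.statistic), np.asarray(res.pvalue), direction)


def classify_shape(
    q_value: float,
    dunnett: DunnettResult,
    group_means: dict[str, float],
    fdr_level: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> str:
    """Classify a protein's dose-response pattern.

    flat: not significant at the group-wise FDR level. up / down: at least
    one Dunnett comparison significant and all significant comparisons
    share the corresponding direction. Everything else is non-monotone and
    is subtyped by the quadratic contrast (1, -1, -1, 1) over the ordered
    dose-group means: positive curvature = U-shape (high at the extremes),
    negative = cap-shape (high at intermediate doses).
    """
    if q_value > fdr_level:
        return "flat"
    sig = dunnett.pvalue <= posthoc_alpha
    if sig.any():
        dirs = dunnett.direction[sig]
        if np.all(dirs > 0):
            return "up"
        if np.all(dirs < 0):
            return "down"
    means = [group_means[g] for g in DOSE_GROUPS if g in group_means]
    if len(means) == 4:
        curvature = means[0] - means[1] - means[2] + means[3]
    else:  # degenerate designs: fall back to endpoints vs middle
        curvature = means[0] + means[-1] - 2.0 * float(np.mean(means[1:-1]))
    return "u_shape" if curvature > 0 else "cap_shape"


def dose_response_table(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    config: RunConfig | None = None,
    transform: bool = True,
) -> pd.DataFrame:
    """Full per-feature dose-response analysis.

    Per protein: tie-corrected Kruskal-Wallis across the dose groups,
    Storey q-values over all proteins, Dunnett comparisons of each exposed
    group against the controls, and the shape class. Group means for the
    shape contrast are taken on the Box-Cox transformed scale (or raw scale
    with ``transform=False``). Missing values are dropped pairwise; a
    protein is tested only if every group keeps >= 2 values.
    """
    config = config or RunConfig()
    abundance.check_samples(metadata)
    meta = metadata.subset(abundance.sample_ids)
    group_of = meta.dose_group
    treat_groups = [g for g in DOSE_GROUPS if g != "control"]

    records = []
    for fid, series in abundance.values.iterrows():
        vals = series.to_numpy(float)
        mask = np.isfinite(vals)
        labels = group_of[series.index[mask]].to_numpy()
        y = vals[mask]
        ok = all((labels == g).sum() >= 2 for g in DOSE_GROUPS)
        rec = {"feature_id": fid, "tested": ok}
        if not ok:
            rec.update({"kw_H": np.nan, "kw_p": np.nan})
            records.append(rec)
            continue
        if transform and np.ptp(y) > 0:
            y = boxcox_mle(y).transformed_values
        h, p = kruskal_wallis(y, labels)
        rec["kw_H"], rec["kw_p"] = h, p
        control = y[labels == "control"]
        try:
            dn = dunnett_vs_control(
                control,
                {g: y[labels == g] for g in treat_groups},
                seed=config.seed,
            )
        except ValidationError:
            dn = DunnettResult(
                tuple(treat_groups),
                np.full(3, np.nan),
                np.ones(3),
                np.zeros(3),
            )
        for i, g in enumerate(treat_groups):
            rec[f"dunnett_p_{g}"] = dn.pvalue[i]
            rec[f"direction_{g}"] = int(dn.direction[i])
        rec["_dunnett"] = dn
        rec["_means"] = {g: float(y[labels == g].mean()) for g in DOSE_GROUPS}
        records.append(rec)

    table = pd.DataFrame(records)
    tested = table["tested"].to_numpy()
    q = np.full(len(table), np.nan)
    if tested.any():
        q_vals, pi0 = storey_qvalues(table.loc[tested, "kw_p"].to_numpy(), config.storey_lambda)
        q[tested] = q_vals
        table.attrs["pi0_hat"] = pi0
    table["q_value"] = q
    shapes = []
    for _, row in table.iterrows():
        if not row["tested"]:
            shapes.append("flat")
            continue
        shapes.append(
            classify_shape(
                row["q_value"],
                row["_dunnett"],
                row["_means"],
                config.fdr_level,
                config.posthoc_alpha,
            )
        )
    table["shape"] = shapes
    return table.drop(columns=["_dunnett", "_means"])


def summarize_dose_sets(
    table: pd.DataFrame, posthoc_alpha: float = 0.05, fdr_level: float = 0.05
) -> dict:
    """Per-group up/down counts and Venn-cell overlaps of significant sets.

    A feature belongs to a group's up (down) set when its Dunnett
    comparison for that group is significant with positive (negative)
    direction and the feature is not itself shape-classified. Shape counts
    are reported separately.
    """
    treat_groups = [g for g in DOSE_GROUPS if g != "control"]
    sets: dict[str, dict[str, set]] = {"up": {}, "down": {}}
    monotone = table[table["shape"].isin(["up", "down"])]
    for g in treat_groups:
        sig = monotone[f"dunnett_p_{g}"] <= posthoc_alpha
        direction = monotone[f"direction_{g}"]
        sets["up"][g] = set(monotone.loc[sig & (direction > 0), "feature_id"])
        sets["down"][g] = set(monotone.loc[sig & (direction < 0), "feature_id"])

    def venn(cells: dict[str, set]) -> dict[str, int]:
        out = {}
        names = list(cells)
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inter = set.intersection(*(cells[c] for c in combo))
                excl = inter - set.union(set(), *(cells[c] for c in names if c not in combo))
                out["&".join(combo)] = len(excl)
        return out

    summary = {
        "per_group": {
            d: {g: len(sets[d][g]) for g in treat_groups} for d in ("up", "down")
        },
        "venn": {d: venn(sets[d]) for d in ("up", "down")},
        "shape_counts": table["shape"].value_counts().to_dict(),
        "n_significant": int((table["q_value"] <= fdr_level).sum()),
    }
    return summary
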