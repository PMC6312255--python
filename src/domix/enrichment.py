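"""Gene-set over-representation by Fisher's exact (hypergeometric) test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .transcript_de import bh_adjust

__all__ = ["fisher_enrich", "compare_term_sets"]


def fisher_enrich(
    selected,
    universe,
    collection: GeneSetCollection,
    min_overlap_with_universe: int = 2,
) -> pd.DataFrame:
    """One-sided over-representation test of ``selected`` within each set.

    Every set is first intersected with the universe (the features actually
    tested in the originating stage); sets sharing fewer than
    ``min_overlap_with_universe`` features with the universe are skipped.
    The p-value is the upper hypergeometric tail P(X >= overlap); the odds
    ratio is the sample odds ratio of the 2x2 table. BH adjustment runs
    across the tested sets and results are sorted by p.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValidationError("empty universe")
    if not selected <= universe:
        raise ValidationError("selected features must be a subset of the universe")
    n_universe = len(universe)
    n_selected = len(selected)
    rows = []
    for name, members in collection.items():
        in_universe = members & universe
        if len(in_universe) < min_overlap_with_universe:
            continue
        k = len(in_universe & selected)
        K = len(in_universe)
        # P(X >= k) for X ~ Hypergeom(N=n_universe, K, n=n_selected)
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_selected))
        a, b = k, n_selected - k
        c, d = K - k, n_universe - K - (n_selected - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "selected_size": n_selected,
                "universe_size": n_universe,
                "odds_ratio": odds,
                "exact_p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(bh_adjusted_p=[])
    table["bh_adjusted_p"] = bh_adjust(table["exact_p"].to_numpy())
    return table.sort_values(["exact_p", "set_name"], kind="mergesort").reset_index(drop=True)


def compare_term_sets(terms_restrictive, terms_integrative) -> dict:
    """Cardinalities and intersection of two enriched-term lists obtained at
    the same threshold."""
    r, i = set(terms_restrictive), set(terms_integrative)
    return {
        "n_restrictive": len(r),
        "n_integrative": len(i),
        "n_common": len(r & i),
        "common": sorted(r & i),
    }
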