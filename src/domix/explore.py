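"""Covariate correlation and sample clustering.

Dose and age are checked for rank correlation (they are badly confounded in
an occupational cohort: older workers accumulated more dose), and samples
are clustered hierarchically with one-minus-Spearman-correlation distance
over a chosen feature subset — the standard way to visualise whether
dose-responsive features separate high-dose samples from controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import AbundanceMatrix, ValidationError

__all__ = [
    "spearman_correlation",
    "spearman_distance_matrix",
    "hierarchical_cluster",
    "ClusterResult",
]


def spearman_correlation(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation, except for n <= ``exact_max_n``
    where the exact permutation distribution of rho is enumerated.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("need paired vectors with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact permutation null of rho given the observed (tied) ranks
        perms = np.array(list(permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        null = (rx_c[perms] * ry_c[None, :]).sum(axis=1) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def spearman_distance_matrix(abundance: AbundanceMatrix) -> pd.DataFrame:
    """Sample-by-sample distance d(i, j) = 1 - Spearman rho over the given
    features. Symmetric with a zero diagonal; a constant sample profile is
    rejected by name."""
    vals = abundance.values.to_numpy(float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValidationError("need >= 2 features and >= 2 samples")
    for sid, col in zip(abundance.sample_ids, vals.T):
        if np.ptp(col[np.isfinite(col)]) == 0:
            raise ValidationError(f"sample {sid!r} has a constant profile")
    rho = stats.spearmanr(vals, nan_policy="omit").statistic
    if np.isscalar(rho):  # two samples: spearmanr returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - np.asarray(rho)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=abundance.sample_ids, columns=abundance.sample_ids)


@dataclass
class ClusterResult:
    """Agglomerative clustering output: scipy linkage matrix, dendrogram
    leaf order, and the sample ids in input order."""

    linkage: np.ndarray
    leaf_order: list[str]
    sample_ids: list[str]

    def cut(self, k: int) -> pd.Series:
        if k > len(self.sample_ids):
            raise ValidationError(f"cannot cut {len(self.sample_ids)} samples into {k} clusters")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of a symmetric distance matrix.

    ``linkage`` is one of {average, complete, ward}. Merging is
    deterministic (ties resolved by the smallest index pair, as in the
    underlying nearest-neighbour chain implementation).
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    d = distances.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    if d.shape[0] == 1:
        return ClusterResult(np.empty((0, 4)), list(distances.index), list(distances.index))
    condensed = squareform(d, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(z)
    ids = list(distances.index)
    return ClusterResult(z, [ids[i] for i in order], ids)
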