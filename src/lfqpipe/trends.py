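"""Trend clustering of significant proteins across ordered groups.

Profiles (per-protein group means of log2 fractions, in group order) are
clustered two ways — agglomerative clustering on Pearson-correlation
distance, and K-means on z-scored profiles — and labelled by a rule-based
trend classifier over three ordered groups: monotone up, monotone down,
biphasic up-then-down / down-then-up, or flat/mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

TREND_LABELS = ("up", "down", "up_down", "down_up", "flat_mixed")

_MIRROR = {"up": "down", "down": "up", "up_down": "down_up",
           "down_up": "up_down", "flat_mixed": "flat_mixed"}


@dataclass(frozen=True)
class ClusteringParams:
    """K-means / hierarchical clustering parameters.

    ``k`` defaults to 3 (the injury phase); the repair phase uses 4.
    ``trend_tolerance`` is the trend rule's epsilon, relative to the
    profile's range.
    """

    k: int = 3
    linkage: str = "average"
    n_restarts: int = 10
    trend_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.trend_tolerance < 0:
            raise ValueError("trend_tolerance must be >= 0")


def pearson_distance(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson-correlation distance, d = 1 - r.

    Returns the symmetric distance matrix (range [0, 2], zero diagonal)
    and a per-profile flag marking constant profiles, whose correlation
    is undefined and whose off-diagonal distances are set to 1.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    if profiles.shape[1] < 3:
        raise ValueError("profiles need >= 3 points for a meaningful correlation")
    x = profiles.to_numpy(dtype=float)
    constant = pd.Series(np.isclose(x.std(axis=1), 0.0), index=profiles.index, name="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    undef = np.isnan(d)
    d[undef] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index), constant


def hierarchical_cluster(
    distances: pd.DataFrame, k: int, linkage_method: str = "average"
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering on a precomputed distance matrix.

    Returns flat cluster labels (1..k) from cutting the tree at ``k``
    clusters, plus the linkage matrix.  Ties are broken by lowest index
    (scipy's deterministic merge order on equal heights).
    """
    n = len(distances)
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles n={n}")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    z = linkage(condensed, method=linkage_method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=distances.index, name="hier_cluster"), z


def z_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize profiles to mean 0, SD 1; constant rows become 0."""
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def kmeans_trends(profiles: pd.DataFrame, params: ClusteringParams = ClusteringParams()) -> pd.Series:
    """K-means on z-scored profiles with seeded restarts (best inertia kept)."""
    if len(profiles) < params.k:
        raise ValueError(f"need >= k={params.k} profiles, got {len(profiles)}")
    z = z_profiles(profiles)
    if len(np.unique(z.to_numpy(), axis=0)) < params.k:
        import warnings

        warnings.warn("fewer distinct profiles than k; clusters may be degenerate", stacklevel=2)
    km = KMeans(n_clusters=params.k, n_init=params.n_restarts, random_state=params.seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=profiles.index, name="kmeans_cluster")


def classify_trend(means, tolerance: float = 0.05) -> str:
    """Rule-based trend label for exactly three ordered group means.

    The consecutive differences d1, d2 are compared against
    ``eps = tolerance * (max - min)``: both above eps -> ``up``; both
    below -eps -> ``down``; d1 above and d2 below -> ``up_down``; the
    reverse -> ``down_up``; anything else (including constant profiles)
    -> ``flat_mixed``.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (3,):
        raise ValueError(f"classify_trend needs exactly 3 ordered means, got shape {means.shape}")
    rng_ = means.max() - means.min()
    if rng_ == 0:
        return "flat_mixed"
    eps = tolerance * rng_
    d1, d2 = means[1] - means[0], means[2] - means[1]
    if d1 > eps and d2 > eps:
        return "up"
    if d1 < -eps and d2 < -eps:
        return "down"
    if d1 > eps and d2 < -eps:
        return "up_down"
    if d1 < -eps and d2 > eps:
        return "down_up"
    return "flat_mixed"


def mirror_label(label: str) -> str:
    """Trend label of the sign-flipped profile."""
    return _MIRROR[label]


def trend_profiles(
    group_means: pd.DataFrame, params: ClusteringParams = ClusteringParams()
) -> pd.DataFrame:
    """Full per-protein trend table for one 3-group phase.

    ``group_means`` is an accession x ordered-group matrix.  Returns the
    z-profile columns plus ``kmeans_cluster`` and ``trend_label``.
    """
    out = z_profiles(group_means).add_prefix("z_")
    out["kmeans_cluster"] = kmeans_trends(group_means, params)
    out["trend_label"] = [
        classify_trend(row, params.trend_tolerance) for row in group_means.to_numpy()
    ]
    return out
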