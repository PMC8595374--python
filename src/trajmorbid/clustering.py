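"""Ward clustering of MDS scores, cluster-count selection, bootstrap
stability, and a surrogate decision tree for external replication.

Clusters are formed on the retained MDS dimensions (not on the raw
dissimilarity matrix) with Ward's minimum-variance criterion on
Euclidean score distances.  The R^2 profile — between-cluster sum of
squares over total — guides the choice of cluster count via an elbow
rule; bootstrap Jaccard coefficients quantify how reproducible each
cluster is under resampling; and a depth-limited CART tree on
interpretable diagnosis features gives a portable approximation of the
clustering (agreement summarized by the Rand index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from sklearn.metrics import rand_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClusterResult",
    "ClusterStability",
    "SurrogateTree",
    "ward_cluster",
    "select_k",
    "bootstrap_jaccard",
    "surrogate_tree",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1..k, relabeled by descending cluster size
    k: int
    linkage: np.ndarray
    r2_profile: np.ndarray  # R^2 at k = 1..len(profile)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[x] for x in labels])


def _r2(scores: np.ndarray, labels: np.ndarray) -> float:
    grand = scores.mean(axis=0)
    sst = ((scores - grand) ** 2).sum()
    if sst == 0:
        return 0.0
    ssw = sum(((scores[labels == c] - scores[labels == c].mean(axis=0)) ** 2).sum()
              for c in np.unique(labels))
    return 1.0 - ssw / sst


def ward_cluster(scores, k: int, k_max: int = 13) -> ClusterResult:
    """Ward's agglomerative clustering of the score matrix into ``k``
    groups, with the R^2 profile for k = 1..k_max from the same tree."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    Z = linkage(scores, method="ward")
    k_max = min(max(k_max, k), n)
    ks = list(range(1, min(k_max, n - 1) + 1))
    cuts = cut_tree(Z, n_clusters=ks)
    if k_max == n:  # scipy's cut_tree mishandles n_clusters == n
        cuts = np.column_stack([cuts, np.arange(n)])
    profile = np.array([_r2(scores, cuts[:, i]) for i in range(k_max)])
    labels = _relabel_by_size(cuts[:, k - 1] + 1)
    return ClusterResult(labels, k, Z, profile)


def select_k(r2_profile, frac: float = 0.25) -> int:
    """Elbow rule on the R^2 profile: the smallest k (>= 3) whose marginal
    gain has dropped to at most ``frac`` of the previous gain.  A profile
    with no such level-off (linear or flat) returns 1 with a warning."""
    r2 = np.asarray(r2_profile, dtype=float)
    gains = np.diff(r2)  # gains[i] = gain moving to k = i + 2
    tol = 1e-12
    for i in range(1, len(gains)):
        if gains[i - 1] > tol and gains[i] <= frac * gains[i - 1] + tol:
            return i + 2
    warnings.warn("R^2 profile shows no elbow; returning k=1")
    return 1


@dataclass
class ClusterStability:
    jaccard_mean: np.ndarray  # per original cluster
    n_resamples: int

    @property
    def overall_mean(self) -> float:
        return float(np.nanmean(self.jaccard_mean))


def bootstrap_jaccard(scores, k: int, n_resamples: int = 100,
                      seed: int | None = 0) -> ClusterStability:
    """Cluster-wise bootstrap stability.

    Each resample re-clusters a bootstrap sample of the scores; every
    original cluster is matched to its best-Jaccard counterpart among the
    bootstrap clusters (index sets compared on the resampled points), and
    the per-cluster coefficients are averaged over resamples.
    """
    if n_resamples < 20:
        raise ValueError("need at least 20 bootstrap resamples")
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    base = ward_cluster(scores, k).labels
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_resamples, k))
    orig_sets = [set(np.flatnonzero(base == c + 1)) for c in range(k)]
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        boot_labels = ward_cluster(scores[idx], k).labels
        boot_sets = []
        for c in range(1, k + 1):
            members = set(idx[boot_labels == c])
            boot_sets.append(members)
        sampled = set(uniq)
        for c in range(k):
            a = orig_sets[c] & sampled
            if not a:
                acc[b, c] = np.nan
                continue
            best = max(len(a & bs) / len(a | bs) if (a | bs) else 0.0
                       for bs in boot_sets)
            acc[b, c] = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(acc, axis=0)
    if np.any(np.isnan(means)):
        warnings.warn("some clusters were empty in every resample; excluded")
    return ClusterStability(means, n_resamples)


@dataclass
class SurrogateTree:
    tree: DecisionTreeClassifier
    rand_index: float
    feature_names: list[str]

    def predict(self, features) -> np.ndarray:
        return self.tree.predict(np.asarray(features, dtype=float))


def surrogate_tree(features, labels, max_depth: int = 4,
                   feature_names=None, seed: int = 0) -> SurrogateTree:
    """Depth-limited CART (Gini) approximation of a clustering from
    interpretable per-person features; agreement with the input labels is
    reported as the Rand index."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if feature_names is None:
        feature_names = (list(features.columns)
                         if hasattr(features, "columns")
                         else [f"x{i}" for i in range(X.shape[1])])
    if np.unique(y).size < 2:
        warnings.warn("single-class labels: surrogate tree is trivial")
    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                  random_state=seed)
    tree.fit(X, y)
    ri = float(rand_score(y, tree.predict(X)))
    return SurrogateTree(tree, ri, list(feature_names))
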