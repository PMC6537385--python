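"""Two-step clustering: Ward AHC over SOM codebooks and majority-rule k.

The SOM acts as a pre-clustering stage; its stabilized codebook vectors are
then merged by agglomerative hierarchical clustering with Ward's minimum
variance linkage (Ward.D2 on Euclidean distances between concatenated
per-layer codebooks).  The number of clusters is chosen by majority vote
over a battery of internal validity indices evaluated on the Ward partitions
of the codebooks, and neuron clusters are projected onto samples through
their BMU.

Implemented indices: Calinski-Harabasz, average silhouette, Davies-Bouldin,
Dunn, C-index, McClain-Rao, point-biserial (all computable from a single
partition) and Hartigan, Krzanowski-Lai, Ball-Hall (elbow-type, needing the
neighbouring partitions).  Each votes with its standard optimum rule; the
majority (mode, ties to the smallest k) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, NotApplicableError
from .som import SOMModel

PARTITION_INDICES = ("calinski_harabasz", "silhouette", "davies_bouldin",
                     "dunn", "c_index", "mcclain_rao", "point_biserial")
ELBOW_INDICES = ("hartigan", "krzanowski_lai", "ball_hall")
DEFAULT_INDICES = PARTITION_INDICES + ELBOW_INDICES

# optimum direction of the single-partition indices
INDEX_DIRECTION = {
    "calinski_harabasz": "max",
    "silhouette": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "mcclain_rao": "min",
    "point_biserial": "max",
}


# ---------------------------------------------------------------------------
# Partition bookkeeping
# ---------------------------------------------------------------------------

def _check_partition(points: np.ndarray, labels: np.ndarray,
                     need_k2: bool = True) -> list[np.ndarray]:
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if need_k2 and len(groups) < 2:
        raise NotApplicableError(
            "index requires at least 2 clusters (between/within contrast)")
    return groups


def within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from centroids."""
    w = 0.0
    for idx in _check_partition(points, labels, need_k2=False):
        c = points[idx].mean(axis=0)
        w += float(((points[idx] - c) ** 2).sum())
    return w


def _pair_masks(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask: True where a pair is within-cluster."""
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), 1)
    return same[iu]


# ---------------------------------------------------------------------------
# Single-partition indices
# ---------------------------------------------------------------------------

def _calinski_harabasz(points, labels):
    groups = _check_partition(points, labels)
    n, k = len(points), len(groups)
    if n <= k:
        raise NotApplicableError("need more points than clusters")
    grand = points.mean(axis=0)
    b = sum(len(i) * float(((points[i].mean(axis=0) - grand) ** 2).sum())
            for i in groups)
    w = within_ss(points, labels)
    if w <= 0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def _silhouette(points, labels):
    groups = _check_partition(points, labels)
    D = squareform(pdist(points))
    n = len(points)
    s = np.zeros(n)
    for gi, idx in enumerate(groups):
        for i in idx:
            own = D[i, idx]
            a = own.sum() / (len(idx) - 1) if len(idx) > 1 else 0.0
            b = min(D[i, other].mean()
                    for gj, other in enumerate(groups) if gj != gi)
            denom = max(a, b)
            s[i] = 0.0 if (denom == 0 or len(idx) == 1) else (b - a) / denom
    return float(s.mean())


def _davies_bouldin(points, labels):
    groups = _check_partition(points, labels)
    cents = np.array([points[i].mean(axis=0) for i in groups])
    scatter = np.array([
        float(np.linalg.norm(points[i] - cents[gi], axis=1).mean())
        for gi, i in enumerate(groups)])
    M = squareform(pdist(cents))
    k = len(groups)
    r = np.zeros(k)
    for i in range(k):
        ratios = [(scatter[i] + scatter[j]) / M[i, j]
                  for j in range(k) if j != i and M[i, j] > 0]
        r[i] = max(ratios) if ratios else 0.0
    return float(r.mean())


def _dunn(points, labels):
    groups = _check_partition(points, labels)
    D = squareform(pdist(points))
    k = len(groups)
    max_diam = max((D[np.ix_(i, i)].max() for i in groups), default=0.0)
    if max_diam == 0:
        return np.inf
    min_sep = min(D[np.ix_(groups[a], groups[b])].min()
                  for a in range(k) for b in range(a + 1, k))
    return float(min_sep / max_diam)


def _c_index(points, labels):
    _check_partition(points, labels)
    d = pdist(points)
    within = _pair_masks(labels)
    nw = int(within.sum())
    if nw == 0:
        raise NotApplicableError("no within-cluster pairs")
    sw = float(d[within].sum())
    ds = np.sort(d)
    smin = float(ds[:nw].sum())
    smax = float(ds[-nw:].sum())
    if smax == smin:
        return 0.0
    return (sw - smin) / (smax - smin)


def _mcclain_rao(points, labels):
    _check_partition(points, labels)
    d = pdist(points)
    within = _pair_masks(labels)
    nw, nb = int(within.sum()), int((~within).sum())
    if nw == 0 or nb == 0:
        raise NotApplicableError("needs both within and between pairs")
    return float((d[within].mean()) / (d[~within].mean()))


def _point_biserial(points, labels):
    _check_partition(points, labels)
    d = pdist(points)
    between = (~_pair_masks(labels)).astype(float)
    if d.std() == 0 or between.std() == 0:
        raise NotApplicableError("degenerate distance or pair structure")
    return float(np.corrcoef(d, between)[0, 1])


def _ball_hall(points, labels):
    groups = _check_partition(points, labels, need_k2=False)
    per = [float(((points[i] - points[i].mean(axis=0)) ** 2).sum()) / len(i)
           for i in groups]
    return float(np.mean(per))


_PARTITION_FNS = {
    "calinski_harabasz": _calinski_harabasz,
    "silhouette": _silhouette,
    "davies_bouldin": _davies_bouldin,
    "dunn": _dunn,
    "c_index": _c_index,
    "mcclain_rao": _mcclain_rao,
    "point_biserial": _point_biserial,
    "ball_hall": _ball_hall,
}


def compute_validity_index(points, labels, index_name: str, *,
                           labels_prev=None, labels_next=None) -> float:
    """Evaluate one internal validity index on a partition.

    Elbow-type indices need context: ``hartigan`` requires ``labels_next``
    (the k+1 partition); ``krzanowski_lai`` requires both neighbours.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if index_name in _PARTITION_FNS:
        return _PARTITION_FNS[index_name](points, labels)
    if index_name == "hartigan":
        if labels_next is None:
            raise InputError("hartigan requires labels_next (k+1 partition)")
        return hartigan_index(points, labels, np.asarray(labels_next))
    if index_name == "krzanowski_lai":
        if labels_prev is None or labels_next is None:
            raise InputError("krzanowski_lai requires labels_prev and "
                             "labels_next")
        return krzanowski_lai_index(points, np.asarray(labels_prev), labels,
                                    np.asarray(labels_next))
    raise InputError(f"unknown index {index_name!r}")


def hartigan_index(points, labels_k, labels_k1) -> float:
    """H(k) = (W(k)/W(k+1) - 1)(n - k - 1)."""
    n = len(points)
    k = len(np.unique(labels_k))
    wk = within_ss(points, labels_k)
    wk1 = within_ss(points, labels_k1)
    if wk1 <= 0:
        return 0.0 if wk <= 0 else np.inf
    return (wk / wk1 - 1.0) * (n - k - 1)


def krzanowski_lai_index(points, labels_prev, labels_k, labels_next) -> float:
    """KL(k) = |DIFF(k)| / |DIFF(k+1)| with DIFF(k) = (k-1)^{2/p} W(k-1)
    - k^{2/p} W(k)."""
    p = points.shape[1]
    k = len(np.unique(labels_k))

    def diff(km1_labels, k_labels, kk):
        return ((kk - 1) ** (2.0 / p) * within_ss(points, km1_labels)
                - kk ** (2.0 / p) * within_ss(points, k_labels))

    num = abs(diff(labels_prev, labels_k, k))
    den = abs(diff(labels_k, labels_next, k + 1))
    if den == 0:
        return np.inf
    return num / den


# ---------------------------------------------------------------------------
# Ward AHC over codebooks
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    k: int
    neuron_to_cluster: np.ndarray          # labels 1..k per neuron
    merge_history: np.ndarray              # scipy linkage matrix
    index_votes: dict[str, int] | None = None
    sample_to_cluster: np.ndarray | None = None  # labels 1..k per sample
    neuron_sizes: dict[int, int] = field(default_factory=dict)
    sample_sizes: dict[int, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"cluster": c, "neuron_size": self.neuron_sizes.get(c, 0),
                 "sample_size": self.sample_sizes.get(c, 0)}
                for c in range(1, self.k + 1)]
        return pd.DataFrame(rows)


def ward_labels(points: np.ndarray, k: int,
                Z: np.ndarray | None = None) -> np.ndarray:
    """Ward partition of ``points`` into k clusters, labels 1..k (relabelled
    in order of first appearance for determinism)."""
    if Z is None:
        Z = linkage(points, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    first = {}
    out = np.empty_like(raw)
    nxt = 1
    for i, lab in enumerate(raw):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[i] = first[lab]
    return out


def cluster_codebooks(model: SOMModel, k: int) -> ClusterSolution:
    """Ward AHC over the concatenated codebook vectors, cut at k clusters.

    All neurons are clustered, dead neurons included.
    """
    X = model.codebook_matrix()
    n = X.shape[0]
    if not (1 <= k <= n):
        raise InputError(f"k must be in [1, {n}], got {k}")
    Z = linkage(X, method="ward")
    labels = ward_labels(X, k, Z)
    sizes = {int(c): int((labels == c).sum()) for c in range(1, k + 1)}
    return ClusterSolution(k=k, neuron_to_cluster=labels, merge_history=Z,
                           neuron_sizes=sizes)


def assign_samples(solution: ClusterSolution, bmu_map: np.ndarray
                   ) -> np.ndarray:
    """Project neuron clusters onto samples through BMU composition."""
    bmu_map = np.asarray(bmu_map, dtype=int)
    if len(bmu_map) and (bmu_map.min() < 0
                         or bmu_map.max() >= len(solution.neuron_to_cluster)):
        raise InputError("bmu_map references a neuron outside the solution")
    sample_labels = solution.neuron_to_cluster[bmu_map]
    solution.sample_to_cluster = sample_labels
    solution.sample_sizes = {
        int(c): int((sample_labels == c).sum())
        for c in range(1, solution.k + 1)}
    return sample_labels


# ---------------------------------------------------------------------------
# Majority-rule optimal k
# ---------------------------------------------------------------------------

def majority_k(voted_ks) -> int:
    """Mode of the votes; ties broken by the smallest k."""
    voted_ks = list(voted_ks)
    if not voted_ks:
        raise InputError("no votes to aggregate")
    ks, counts = np.unique(voted_ks, return_counts=True)
    return int(ks[counts == counts.max()].min())


def vote_optimal_k(model_or_points, k_min: int = 2, k_max: int = 6,
                   index_names=DEFAULT_INDICES) -> tuple[int, dict[str, int]]:
    """Each index votes for its optimal k on Ward partitions of the
    codebooks; the majority wins (ties to the smallest k)."""
    if isinstance(model_or_points, SOMModel):
        X = model_or_points.codebook_matrix()
    else:
        X = np.asarray(model_or_points, dtype=float)
    index_names = list(index_names)
    if not index_names:
        raise InputError("index_names must not be empty")
    n = X.shape[0]
    if not (2 <= k_min < k_max <= n - 1):
        raise InputError("need 2 <= k_min < k_max <= n_points - 1")

    Z = linkage(X, method="ward")
    ks_needed = range(max(1, k_min - 1), min(n, k_max + 1) + 1)
    labels_by_k = {k: ward_labels(X, k, Z) for k in ks_needed}
    candidate_ks = list(range(k_min, k_max + 1))

    votes: dict[str, int] = {}
    for name in index_names:
        if name in INDEX_DIRECTION:
            vals = np.array([
                _PARTITION_FNS[name](X, labels_by_k[k]) for k in candidate_ks])
            if INDEX_DIRECTION[name] == "max":
                votes[name] = candidate_ks[int(np.nanargmax(vals))]
            else:
                votes[name] = candidate_ks[int(np.nanargmin(vals))]
        elif name == "hartigan":
            h = np.array([hartigan_index(X, labels_by_k[k], labels_by_k[k + 1])
                          for k in candidate_ks])
            small = np.flatnonzero(h <= 10.0)
            if small.size:
                votes[name] = candidate_ks[int(small[0])]
            else:
                drops = -np.diff(h)
                votes[name] = (candidate_ks[int(drops.argmax()) + 1]
                               if len(drops) else candidate_ks[-1])
        elif name == "krzanowski_lai":
            kl = np.array([
                krzanowski_lai_index(X, labels_by_k[k - 1], labels_by_k[k],
                                     labels_by_k[k + 1])
                for k in candidate_ks])
            votes[name] = candidate_ks[int(np.nanargmax(kl))]
        elif name == "ball_hall":
            bh = np.array([_ball_hall(X, labels_by_k[k])
                           for k in [k_min - 1] + candidate_ks])
            drops = -np.diff(bh)  # drop moving into each candidate k
            votes[name] = candidate_ks[int(drops.argmax())]
        else:
            raise InputError(f"unknown index {name!r}")
    return majority_k(votes.values()), votes


# ---------------------------------------------------------------------------
# External comparison metric
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise InputError("labelings must have equal length")
    n = len(a)
    if n == 0:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    C = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(C, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(C).sum()
    sum_a = comb2(C.sum(axis=1)).sum()
    sum_b = comb2(C.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_idx = (sum_a + sum_b) / 2.0
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))
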