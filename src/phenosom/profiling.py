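"""Cluster characterization.

Given sample-to-cluster assignments, this module answers "what makes each
cluster different": an overall one-way ANOVA per numeric component, a
rank-sum over/under-expression call per (cluster, component) with the usual
significance stars, categorical set-intersection counts (which (cluster,
level) combinations are pure), and a CART-style decision tree that resolves
the clustering into human-readable rules.

The rank-sum test treats the cluster as a size-n1 subset of the total
population and asks whether its rank sum (midranks over the whole
population) is extreme under the uniform-random-subset null.  The null is
computed exactly by dynamic programming when min(n1, n - n1) <= 8 — ties are
handled exactly through midranks — and otherwise by a normal approximation
with tie and continuity corrections.  Under this subset formulation the
cluster-vs-total and cluster-vs-complement comparisons share the same
p-value and differ only in the reference mean used for the over/under call;
the default reference is the total-population mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .errors import InputError, NotApplicableError

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                   (0.05, "*"))


def stars_for_p(p: float) -> str:
    for thr, sym in STAR_THRESHOLDS:
        if p <= thr:
            return sym
    return "ns"


class AnovaResult(NamedTuple):
    F: float
    p: float
    degenerate: bool = False


def anova_overall(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across cluster groups.

    Zero within-group variance is flagged: p is reported as 0 when the group
    means differ (infinitely strong evidence in the model's terms) and 1
    when all values coincide.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise NotApplicableError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("each group needs at least 2 values")
    pooled_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if pooled_within <= 0:
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return AnovaResult(F=0.0, p=1.0, degenerate=True)
        return AnovaResult(F=np.inf, p=0.0, degenerate=True)
    f, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(f), p=float(p), degenerate=False)


# ---------------------------------------------------------------------------
# Subset permutation rank-sum
# ---------------------------------------------------------------------------

def _exact_subset_pvalue(ranks2: np.ndarray, member: np.ndarray) -> float:
    """Exact two-sided p for the sum of member midranks under the
    uniform-random-subset null, via a count DP over doubled midranks."""
    n = len(ranks2)
    n1 = int(member.sum())
    if n1 == 0 or n1 == n:
        return 1.0
    # DP over the smaller side; the statistic is symmetric
    flip = n1 > n - n1
    m = n - n1 if flip else n1
    total2 = int(ranks2.sum())
    obs = int(ranks2[~member].sum()) if flip else int(ranks2[member].sum())
    mean = m * total2 / n  # = m*(n+1) since total2 = n(n+1)
    dev = abs(obs - mean)

    maxs = total2
    dp = np.zeros((m + 1, maxs + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(m, 0, -1):
            dp[j, r:] += dp[j - 1, :maxs + 1 - r]
    dist = dp[m]
    sums = np.arange(maxs + 1)
    tail = dist[np.abs(sums - mean) >= dev - 1e-9].sum()
    return float(min(tail / dist.sum(), 1.0))


def _normal_subset_pvalue(ranks: np.ndarray, member: np.ndarray) -> float:
    n = len(ranks)
    n1 = int(member.sum())
    n2 = n - n1
    w = float(ranks[member].sum())
    mean = n1 * (n + 1) / 2.0
    # tie-corrected variance of a size-n1 subset rank sum
    var = n1 * n2 / (n * (n - 1.0)) * float(((ranks - (n + 1) / 2.0) ** 2).sum())
    if var <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(min(2.0 * stats.norm.sf(z), 1.0))


def rank_sum_subset_test(values: Sequence[float], member_mask,
                         exact_max_n: int = 8) -> tuple[float, float, str]:
    """Rank-sum test of a cluster against the population containing it.

    Returns ``(rank_sum, p_value, method)`` with method ``"exact"`` or
    ``"normal"``.
    """
    values = np.asarray(values, dtype=float)
    member = np.asarray(member_mask, dtype=bool)
    if values.shape != member.shape:
        raise InputError("values and member_mask must align")
    n = len(values)
    n1 = int(member.sum())
    if n1 == 0:
        raise InputError("cluster is empty")
    if n1 == n:
        return float(rankdata(values)[member].sum()), 1.0, "exact"
    ranks = rankdata(values)
    w = float(ranks[member].sum())
    if min(n1, n - n1) <= exact_max_n:
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        return w, _exact_subset_pvalue(ranks2, member), "exact"
    return w, _normal_subset_pvalue(ranks, member), "normal"


# ---------------------------------------------------------------------------
# Expression profile
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Per-(cluster, component) over/under-expression calls plus the overall
    per-component ANOVA."""

    table: pd.DataFrame   # cluster, component, means, p_value, direction, stars
    anova: pd.DataFrame   # component, F, p, degenerate

    def calls(self, cluster: int) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        adj[i] = running
    return adj


def wilcoxon_profile(numeric_df: pd.DataFrame, sample_to_cluster,
                     components: Sequence[str] | None = None,
                     reference: str = "total", alpha: float = 0.05,
                     p_adjust: str = "none") -> ExpressionProfile:
    """Over/under-expression profile of every cluster on every numeric
    component.

    ``reference`` chooses the mean the cluster is compared against for the
    direction call: ``"total"`` (population mean, the default) or
    ``"complement"``; the rank-sum p-value is the same subset test either
    way.  ``p_adjust="bh"`` applies Benjamini-Hochberg across all calls
    (off by default: raw stars are reported).
    """
    labels = np.asarray(sample_to_cluster)
    if components is None:
        components = [c for c in numeric_df.columns if c != "plot_id"]
    if len(labels) != len(numeric_df):
        raise InputError("sample_to_cluster must align with the table rows")
    clusters = [int(c) for c in np.unique(labels)]
    if any((labels == c).sum() == 0 for c in clusters):
        raise InputError("empty cluster in sample_to_cluster")

    rows = []
    anova_rows = []
    for comp in components:
        x = numeric_df[comp].to_numpy(dtype=float)
        res = anova_overall([x[labels == c] for c in clusters]) \
            if all((labels == c).sum() >= 2 for c in clusters) and \
            len(clusters) >= 2 else AnovaResult(np.nan, np.nan, False)
        anova_rows.append({"component": comp, "F": res.F, "p": res.p,
                           "degenerate": res.degenerate})
        pop_mean = float(x.mean())
        for c in clusters:
            member = labels == c
            _, p, method = rank_sum_subset_test(x, member)
            ref_mean = (pop_mean if reference == "total"
                        else float(x[~member].mean()))
            rows.append({
                "cluster": c, "component": comp,
                "cluster_mean": float(x[member].mean()),
                "population_mean": ref_mean,
                "p_value": p, "method": method,
            })

    table = pd.DataFrame(rows)
    if p_adjust == "bh":
        table["p_value"] = _bh_adjust(table["p_value"].to_numpy())
    elif p_adjust != "none":
        raise InputError(f"unknown p_adjust {p_adjust!r}")

    def call(row):
        if row["p_value"] > alpha:
            return "ns"
        return "over" if row["cluster_mean"] > row["population_mean"] else \
            ("under" if row["cluster_mean"] < row["population_mean"] else "ns")

    table["direction"] = table.apply(call, axis=1)
    table["stars"] = table["p_value"].map(stars_for_p)
    return ExpressionProfile(table=table, anova=pd.DataFrame(anova_rows))


# ---------------------------------------------------------------------------
# Set-intersection counts
# ---------------------------------------------------------------------------

def intersection_counts(sample_to_cluster, categorical: Sequence[str],
                        pure_threshold: float = 1.0) -> pd.DataFrame:
    """Contingency of clusters x categorical levels with within-cluster
    percentages; flags combinations at/above ``pure_threshold`` purity."""
    labels = np.asarray(sample_to_cluster)
    levels = pd.Series(categorical)
    if len(labels) != len(levels):
        raise InputError("labels and categorical values must align")
    rows = []
    for c in sorted(np.unique(labels)) if len(labels) else []:
        mask = labels == c
        size = int(mask.sum())
        vc = levels[mask].value_counts()
        for level in sorted(levels.unique()):
            count = int(vc.get(level, 0))
            pct = count / size if size else 0.0
            rows.append({"cluster": int(c), "level": level, "count": count,
                         "cluster_size": size, "percent": 100.0 * pct,
                         "pure": pct >= pure_threshold and count > 0})
    return pd.DataFrame(
        rows, columns=["cluster", "level", "count", "cluster_size",
                       "percent", "pure"])


# ---------------------------------------------------------------------------
# CART rule tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    prediction: int
    n: int
    percent: float                 # share of the training samples
    gini: float
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RuleTree:
    root: TreeNode
    feature_names: list[str]
    resubstitution_accuracy: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=int)
        name_to_idx = {n: i for i, n in enumerate(self.feature_names)}
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                j = name_to_idx[node.feature]
                node = node.left if row[j] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: str):
            head = (f"cluster={node.prediction} n={node.n} "
                    f"({node.percent:.1f}%)")
            if node.is_leaf:
                lines.append(f"{indent}leaf: {head}")
            else:
                lines.append(f"{indent}{node.feature} <= "
                             f"{node.threshold:.4g}? {head}")
                walk(node.left, indent + "  ")
                walk(node.right, indent + "  ")

        walk(self.root, "")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def walk(node: TreeNode) -> dict:
            d = {"prediction": int(node.prediction), "n": int(node.n),
                 "percent": node.percent, "gini": node.gini}
            if not node.is_leaf:
                d.update({"feature": node.feature,
                          "threshold": float(node.threshold),
                          "left": walk(node.left), "right": walk(node.right)})
            return d
        return {"tree": walk(self.root),
                "resubstitution_accuracy": self.resubstitution_accuracy}


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                min_leaf: int) -> tuple[int, float, float] | None:
    """Exhaustive (feature, midpoint) search minimizing weighted Gini.

    Ties broken by lowest feature index, then lowest threshold.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best = None
    best_score = parent_gini - 1e-12
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        left = np.zeros(n_classes)
        right = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            score = (nl * _gini(left) + nr * _gini(right)) / n
            if score < best_score - 1e-12:
                best_score = score
                best = (j, (xs[i] + xs[i + 1]) / 2.0, parent_gini - score)
    return best


def fit_rule_tree(encoded_df: pd.DataFrame, sample_to_cluster,
                  max_depth: int = 4, min_leaf: int = 5) -> RuleTree:
    """Greedy CART with Gini impurity over the encoded feature table.

    Numeric splits are placed at midpoints between sorted distinct values
    (one-hot columns behave as level splits at 0.5).  Stopping: purity,
    ``max_depth`` or ``min_leaf``.  Single-class input yields a single leaf
    with accuracy 1.
    """
    feature_names = [c for c in encoded_df.columns if c != "plot_id"]
    X = encoded_df[feature_names].to_numpy(dtype=float)
    labels = np.asarray(sample_to_cluster)
    classes, y = np.unique(labels, return_inverse=True)
    n_total = len(y)
    if n_total == 0:
        raise InputError("cannot fit a tree on an empty table")

    def majority(counts: np.ndarray) -> int:
        return int(classes[int(counts.argmax())])  # argmax -> lowest class

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=len(classes))
        node = TreeNode(prediction=majority(counts), n=len(idx),
                        percent=100.0 * len(idx) / n_total,
                        gini=_gini(counts))
        if node.gini == 0 or depth >= max_depth or len(idx) < 2 * min_leaf:
            return node
        split = _best_split(X[idx], y[idx], len(classes), min_leaf)
        if split is None:
            return node
        j, thr, _ = split
        node.feature = feature_names[j]
        node.threshold = thr
        mask = X[idx, j] <= thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(n_total), 0)
    tree = RuleTree(root=root, feature_names=feature_names,
                    resubstitution_accuracy=0.0)
    acc = float((tree.predict(X) == labels).mean())
    tree.resubstitution_accuracy = acc
    return tree
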