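"""Unsupervised discovery of sepsis response signature (SRS) groups.

Samples are clustered on the most variable fraction of probes by Ward
agglomeration (Euclidean distance), the dendrogram cut is consolidated by
Lloyd k-means started from the hierarchical centroids (no random
restarts, so the whole step is deterministic), and the number of groups
is picked as the smallest k whose within-group sum of squares no longer
drops appreciably. Group 1 ("SRS1") is the cluster in which the majority
of a quick unmoderated differential-expression pass is downregulated —
the immunosuppressed phenotype presents as a broadly repressed program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import ExpressionMatrix

__all__ = [
    "DiscoveryConfig",
    "SrsAssignment",
    "SrsDiscovery",
    "select_variable_probes",
    "ward_cluster",
    "consolidate_kmeans",
    "evaluate_k",
    "orient_labels",
]


@dataclass(frozen=True)
class DiscoveryConfig:
    variance_fraction: float = 0.10
    k_min: int = 2
    k_max: int = 4
    kmeans_max_iter: int = 300
    # a k -> k+1 WSS reduction counts as real only when it exceeds
    # elbow_null_factor times the median reduction seen on permuted data
    # (per-probe sample shuffles), and wss_drop_threshold as an absolute floor
    wss_drop_threshold: float = 0.001
    elbow_null_factor: float = 2.0
    elbow_null_permutations: int = 3
    seed: int = 0  # seeds the permutation null; clustering itself is deterministic

    def __post_init__(self):
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must lie in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class SrsAssignment:
    """Final group labels with the model-selection trace."""

    labels: pd.Series  # sample id -> "SRS1" / "SRS2" / ...
    wss_by_k: dict
    chosen_k: int
    orientation_rule: str
    variable_probes: list = field(default_factory=list)

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        lines = ["SRS group discovery",
                 f"  probes clustered: {len(self.variable_probes)}",
                 f"  chosen k:         {self.chosen_k}"]
        n = len(self.labels)
        for name, c in counts.items():
            lines.append(f"  {name}: {c} ({100 * c / n:.0f}%)")
        lines.append("  WSS by k: " + ", ".join(
            f"{k}:{v:.1f}" for k, v in sorted(self.wss_by_k.items())))
        lines.append(f"  orientation: {self.orientation_rule}")
        return "\n".join(lines)


def select_variable_probes(expr: ExpressionMatrix, fraction: float) -> list:
    """Ids of the ``ceil(fraction * n_probes)`` highest-variance probes.

    Variance is computed across samples with denominator n-1; ties are
    broken by probe id so the selection is independent of input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if expr.n_probes == 0:
        raise ValueError("empty expression matrix")
    n_keep = int(np.ceil(fraction * expr.n_probes))
    var = expr.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"probe_id": expr.probe_ids, "var": var}).sort_values(
        ["var", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return order["probe_id"].head(n_keep).tolist()


def ward_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Ward minimum-variance agglomeration of sample vectors, cut at k groups.

    Uses the Lance-Williams recurrence on Euclidean distances; ties in the
    merge sequence resolve to the smallest cluster-index pair, so the
    partition is deterministic for a given input.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if k == n:
        return np.arange(n)
    Z = linkage(X, method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        block = X[labels == g]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def consolidate_kmeans(X: np.ndarray, initial_labels: np.ndarray,
                       max_iter: int = 300) -> tuple:
    """Lloyd k-means seeded at the centroids of the initial partition.

    An empty cluster is re-seeded at the point farthest from its assigned
    centroid. Returns ``(labels, wss)``; the final WSS never exceeds the
    WSS of the initial labels.
    """
    X = np.asarray(X, float)
    initial_labels = np.asarray(initial_labels)
    groups = np.unique(initial_labels)
    k = len(groups)
    remap = {g: i for i, g in enumerate(groups)}
    labels = np.array([remap[g] for g in initial_labels])
    centroids = np.vstack([X[labels == i].mean(axis=0) for i in range(k)])

    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for i in range(k):
            if not np.any(new_labels == i):  # documented empty-cluster rule
                far = d2[np.arange(len(X)), new_labels].argmax()
                new_labels[far] = i
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centroids = np.vstack([X[labels == i].mean(axis=0) for i in range(k)])
    return labels, _wss(X, labels)


def _null_wss_drops(X: np.ndarray, ks: list, max_iter: int, n_perm: int,
                    seed: int) -> dict:
    """Median relative WSS reduction k -> k+1 on structure-free data.

    Each permutation shuffles every probe's values across samples
    independently, preserving marginal distributions while destroying any
    sample grouping; the resulting reductions measure how much WSS a
    further split of pure noise recovers at this n and dimensionality.
    """
    rng = np.random.default_rng(seed)
    drops = {k: [] for k in ks}
    for _ in range(n_perm):
        Xp = X.copy()
        for j in range(Xp.shape[1]):
            rng.shuffle(Xp[:, j])
        prev = None
        for k in ks + [ks[-1] + 1]:
            if k > Xp.shape[0]:
                break
            _, wss = consolidate_kmeans(Xp, ward_cluster(Xp, k), max_iter)
            if prev is not None and prev[1] > 0:
                drops[prev[0]].append((prev[1] - wss) / prev[1])
            prev = (k, wss)
    return {k: float(np.median(v)) if v else 0.0 for k, v in drops.items()}


def evaluate_k(X: np.ndarray, k_range, max_iter: int = 300,
               drop_threshold: float = 0.001, null_factor: float = 2.0,
               n_perm: int = 3, seed: int = 0) -> tuple:
    """Ward + k-means for each k; pick the smallest k past the WSS elbow.

    ``chosen_k`` is the smallest k whose relative WSS reduction at k+1 is
    no larger than what splitting structure-free (permuted) data recovers
    (times ``null_factor``), with ``drop_threshold`` as an absolute floor;
    if every step still reduces the WSS appreciably, the largest k in
    range is kept.
    """
    ks = sorted(k_range)
    wss_by_k, labels_by_k = {}, {}
    for k in ks:
        labels, wss = consolidate_kmeans(X, ward_cluster(X, k), max_iter)
        wss_by_k[k], labels_by_k[k] = wss, labels
    # evaluate the drop into k+1 even when k+1 is just past the range end
    probe_k = ks[-1] + 1
    if probe_k <= X.shape[0]:
        _, wss_next = consolidate_kmeans(X, ward_cluster(X, probe_k), max_iter)
    else:
        wss_next = wss_by_k[ks[-1]]
    null_drops = _null_wss_drops(X, ks, max_iter, n_perm, seed)
    chosen = ks[-1]
    for i, k in enumerate(ks):
        nxt = wss_by_k[ks[i + 1]] if i + 1 < len(ks) else wss_next
        drop = (wss_by_k[k] - nxt) / wss_by_k[k] if wss_by_k[k] > 0 else 0.0
        if drop < max(drop_threshold, null_factor * null_drops.get(k, 0.0)):
            chosen = k
            break
    return wss_by_k, chosen, labels_by_k


def orient_labels(labels: np.ndarray, values: np.ndarray,
                  p_threshold: float = 0.01) -> tuple:
    """Name the group with the majority-downregulated program "SRS1".

    A quick unmoderated Welch-t pass flags probes at unadjusted
    ``p < p_threshold``; the candidate group in which most of those probes
    have lower expression becomes SRS1. With no informative probes, or an
    exact 50/50 vote, the smaller group is named SRS1 (with a warning).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("orientation is defined for exactly two groups")
    a, b = (values[:, labels == groups[0]], values[:, labels == groups[1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    sig = p < p_threshold
    rule = f"SRS1 = group with majority of DE probes (p<{p_threshold}) downregulated"
    if sig.sum() == 0:
        warnings.warn("no DE probes for orientation; smaller group named SRS1")
        smaller = groups[np.argmin([np.sum(labels == g) for g in groups])]
        return smaller, rule + " [fallback: smaller group]"
    n_down_in_a = int(np.sum(t[sig] < 0))
    n_up_in_a = int(sig.sum()) - n_down_in_a
    if n_down_in_a == n_up_in_a:
        warnings.warn("orientation vote tied; smaller group named SRS1")
        smaller = groups[np.argmin([np.sum(labels == g) for g in groups])]
        return smaller, rule + " [fallback: smaller group]"
    srs1 = groups[0] if n_down_in_a > n_up_in_a else groups[1]
    return srs1, rule


class SrsDiscovery:
    """Discovery model: variable-probe selection, Ward + k-means, naming.

    ``fit()`` returns an :class:`SrsAssignment` whose labels are
    "SRS1"/"SRS2" for two groups (oriented by the downregulation vote) and
    "SRS1"... "SRSk" in cluster-index order otherwise.
    """

    def __init__(self, expr: ExpressionMatrix, config: DiscoveryConfig = DiscoveryConfig()):
        if not config.k_max < expr.n_samples:
            raise ValueError("k_max must be below the number of samples")
        self.expr = expr
        self.config = config

    def fit(self) -> SrsAssignment:
        cfg = self.config
        probes = select_variable_probes(self.expr, cfg.variance_fraction)
        rows = self.expr.probe_index(probes)
        X = self.expr.values[rows].T  # samples x probes
        wss_by_k, chosen_k, labels_by_k = evaluate_k(
            X, range(cfg.k_min, cfg.k_max + 1), cfg.kmeans_max_iter,
            cfg.wss_drop_threshold, cfg.elbow_null_factor,
            cfg.elbow_null_permutations, cfg.seed,
        )
        raw = labels_by_k[chosen_k]
        if chosen_k == 2:
            srs1_group, rule = orient_labels(raw, self.expr.values)
            names = np.where(raw == srs1_group, "SRS1", "SRS2")
        else:
            rule = "k != 2: groups named SRS1..SRSk in cluster-index order"
            names = np.array([f"SRS{g + 1}" for g in raw], dtype=object)
        labels = pd.Series(names, index=self.expr.sample_ids, name="srs")
        return SrsAssignment(labels, wss_by_k, chosen_k, rule, probes)
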