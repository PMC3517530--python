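"""Agglomerative clustering with Ward/average linkage and diagnostic labeling.

Hierarchical clustering is run bottom-up and greedily: starting from
singleton clusters, the pair that minimizes the linkage criterion is merged
at each step.  Ward's criterion is the increase in the error sum of squares
of the merged cluster,

    d_W(A, B) = ESS(A u B) - ESS(A) - ESS(B)
              = |A||B| / (|A|+|B|) * ||mean(A) - mean(B)||^2,

with ESS(C) = sum_{x in C} ||x - mean(C)||^2; average linkage is the mean
pairwise distance between members.  Merge heights are the raw criterion
values (so for two singletons Ward's height is ||x-y||^2 / 2).

For diagnosis, a two-group cut of the dendrogram (removing the root merge)
yields "natural" groupings that receive the majority diagnosis of their
members; held-out subjects are then assigned to the group with the nearer
mean coefficient vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["Dendrogram", "GroupModel", "pairwise_distance",
           "hierarchical_cluster", "cut_two_groups", "cut_k_groups",
           "majority_label", "classify"]

METRICS = ("euclidean", "standardized_euclidean")
LINKAGES = ("average", "ward")


def _feature_scales(x: np.ndarray):
    """Per-feature standard deviations; zero-variance features are dropped
    from the standardized metric (scale set to +inf) with a warning."""
    sd = x.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        log.warning("standardized metric: dropping %d zero-variance features",
                    int(zero.sum()))
        sd = sd.copy()
        sd[zero] = np.inf
    return sd


def pairwise_distance(x, metric: str = "euclidean"):
    """Symmetric distance matrix between subject feature vectors.

    ``standardized_euclidean`` divides every feature by its cohort standard
    deviation first (the metric used when coefficients from several brain
    regions, on different scales, are concatenated).
    """
    x = np.asarray(getattr(x, "values", x), dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D array with >= 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("NaN or infinite feature values")
    if metric == "standardized_euclidean":
        x = x / _feature_scales(x)
    elif metric != "euclidean":
        raise ValueError(f"unknown metric {metric!r} (use one of {METRICS})")
    sq = np.sum(x ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass(frozen=True)
class Dendrogram:
    """Merge sequence of an agglomerative clustering.

    Leaves are 0..n-1; merge k creates cluster id n+k.  ``merges`` rows are
    (left_id, right_id, height); heights are the linkage criterion values
    and are non-decreasing for Ward and average linkage on a metric.
    """

    n_leaves: int
    merges: tuple            # ((left, right, height), ...)
    labels: tuple = ()       # optional leaf names

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def members(self) -> dict:
        """Cluster id -> tuple of leaf indices."""
        out = {i: (i,) for i in range(self.n_leaves)}
        for k, (a, b, _h) in enumerate(self.merges):
            out[self.n_leaves + k] = out[a] + out[b]
        return out

    def leaf_order(self) -> list:
        """Left-to-right leaf order for plotting."""
        if not self.merges:
            return list(range(self.n_leaves))
        mem = self.members()
        return list(mem[self.n_leaves + len(self.merges) - 1])

    def to_newick(self) -> str:
        name = {i: (self.labels[i] if self.labels else str(i))
                for i in range(self.n_leaves)}
        node = dict(name)
        for k, (a, b, h) in enumerate(self.merges):
            node[self.n_leaves + k] = f"({node[a]},{node[b]}):{h:.6g}"
        return node[self.n_leaves + len(self.merges) - 1] + ";"

    def to_json(self) -> str:
        return json.dumps({"n_leaves": self.n_leaves,
                           "labels": list(self.labels),
                           "merges": [list(m) for m in self.merges]})


def hierarchical_cluster(x, metric: str = "euclidean",
                         linkage: str = "ward", labels=None) -> Dendrogram:
    """Greedy agglomerative clustering of subject feature vectors."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r} (use one of {LINKAGES})")
    if hasattr(x, "index") and labels is None:
        labels = [str(i) for i in x.index]
    x = np.asarray(getattr(x, "values", x), dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    if metric == "standardized_euclidean":
        x = x / _feature_scales(x)

    merges = []
    if linkage == "ward":
        means = {i: x[i].copy() for i in range(n)}
        sizes = {i: 1 for i in range(n)}
        active = list(range(n))

        def ward_d(i, j):
            ni, nj = sizes[i], sizes[j]
            diff = means[i] - means[j]
            return ni * nj / (ni + nj) * float(diff @ diff)

        dist = {}
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                dist[(active[ii], active[jj])] = ward_d(active[ii], active[jj])
        next_id = n
        while len(active) > 1:
            best = min((v, k) for k, v in dist.items())
            h, (a, b) = best
            merges.append((a, b, h))
            na, nb = sizes[a], sizes[b]
            means[next_id] = (na * means[a] + nb * means[b]) / (na + nb)
            sizes[next_id] = na + nb
            active = [c for c in active if c not in (a, b)]
            dist = {k: v for k, v in dist.items()
                    if a not in k and b not in k}
            for c in active:
                key = (c, next_id) if c < next_id else (next_id, c)
                dist[key] = ward_d(c, next_id)
            active.append(next_id)
            next_id += 1
    else:  # average linkage
        d0 = pairwise_distance(x, "euclidean")
        sizes = {i: 1 for i in range(n)}
        dist = {(i, j): float(d0[i, j]) for i in range(n) for j in range(i + 1, n)}
        active = list(range(n))
        next_id = n
        while len(active) > 1:
            h, (a, b) = min((v, k) for k, v in dist.items())
            merges.append((a, b, h))
            na, nb = sizes[a], sizes[b]
            sizes[next_id] = na + nb
            active = [c for c in active if c not in (a, b)]
            new = {}
            for c in active:
                ka = (min(a, c), max(a, c))
                kb = (min(b, c), max(b, c))
                new[(c, next_id)] = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            dist = {k: v for k, v in dist.items() if a not in k and b not in k}
            dist.update(new)
            active.append(next_id)
            next_id += 1
    return Dendrogram(n, tuple(merges), tuple(labels or ()))


def cut_k_groups(d: Dendrogram, k: int) -> list:
    """Member sets of the k clusters obtained by undoing the last k-1
    merges; groups are ordered by their smallest member index."""
    if not 1 <= k <= d.n_leaves:
        raise ValueError(f"cannot cut {d.n_leaves}-leaf dendrogram into {k}")
    mem = d.members()
    alive = set(range(d.n_leaves))
    for step in range(len(d.merges) - (k - 1)):
        a, b, _h = d.merges[step]
        alive.discard(a)
        alive.discard(b)
        alive.add(d.n_leaves + step)
    groups = [sorted(mem[c]) for c in alive]
    return sorted(groups, key=lambda g: g[0])


def cut_two_groups(d: Dendrogram) -> list:
    """Remove the root merge and return the two child member sets."""
    return cut_k_groups(d, 2)


@dataclass(frozen=True)
class GroupModel:
    """Two labeled groups with their mean coefficient vectors.

    ``scales`` holds the training-cohort feature standard deviations when
    the standardized metric is used (frozen at training time and reapplied
    to held-out subjects).
    """

    group_labels: tuple      # diagnosis of each group, in group order
    group_members: tuple     # tuple of member-id tuples
    group_means: np.ndarray  # (2, n_features), unscaled feature space
    metric: str = "euclidean"
    scales: np.ndarray | None = None
    ties: tuple = ()         # indices of groups whose majority was tied

    def to_json(self) -> str:
        return json.dumps({
            "group_labels": list(self.group_labels),
            "group_members": [list(m) for m in self.group_members],
            "group_means": self.group_means.tolist(),
            "metric": self.metric,
            "scales": None if self.scales is None else self.scales.tolist(),
            "ties": list(self.ties)})


def majority_label(groups: list, known_labels, x, metric: str = "euclidean") -> GroupModel:
    """Label each group by the majority diagnosis of its members.

    ``groups`` are member index lists (as from :func:`cut_two_groups`),
    ``known_labels`` the per-subject diagnoses and ``x`` the feature matrix
    the clustering ran on.  Ties are broken toward the lexicographically
    first label, with a logged warning.
    """
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    if hasattr(known_labels, "to_numpy"):
        known_labels = known_labels.to_numpy()
    known_labels = np.asarray(known_labels, dtype=object)
    ids = (list(x.index) if hasattr(x, "index")
           else list(range(len(xv))))
    labels, members, means, ties = [], [], [], []
    for gi, g in enumerate(groups):
        lab, counts = np.unique(known_labels[list(g)].astype(str),
                                return_counts=True)
        top = counts.max()
        winners = sorted(lab[counts == top])
        if len(winners) > 1:
            log.warning("majority tie in group %d between %s; using %r",
                        gi, winners, winners[0])
            ties.append(gi)
        labels.append(winners[0])
        members.append(tuple(ids[i] for i in g))
        means.append(xv[list(g)].mean(axis=0))
    scales = _feature_scales(xv) if metric == "standardized_euclidean" else None
    return GroupModel(tuple(labels), tuple(members), np.asarray(means),
                      metric=metric, scales=scales, ties=tuple(ties))


def classify(vector, model: GroupModel):
    """Assign a feature vector to the group with the nearer mean.

    Returns ``(label, distances, tie_flag)``; exact ties go to the
    first-listed group with the flag set.
    """
    v = np.asarray(getattr(vector, "values", vector), dtype=float).ravel()
    if v.shape[0] != model.group_means.shape[1]:
        raise ValueError(
            f"feature dimension {v.shape[0]} != model dimension "
            f"{model.group_means.shape[1]}")
    diffs = model.group_means - v
    if model.scales is not None:
        diffs = diffs / model.scales
    dists = np.linalg.norm(diffs, axis=1)
    best = int(np.argmin(dists))  # argmin resolves exact ties to group 0
    tie = bool(len(dists) == 2 and dists[0] == dists[1])
    return model.group_labels[best], dists, tie
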