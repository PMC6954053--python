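"""Phoneme-pair neural distance geometry: matrix, grouping test, UPGMA.

Each phoneme contributes an instances x electrodes rate matrix (rates in a
150 ms window around each occurrence).  Off-diagonal entries of the distance
matrix are cross-validated signed distances between phonemes; diagonal
entries compare random half-splits of the same phoneme's instances.

The articulatory-grouping test asks whether phonemes sharing a place of
articulation are neurally more similar: the statistic is
mean(within-group distances) - mean(between-group distances), compared
one-sided (lower tail) against a null built by randomly reassigning phonemes
to groups of the same sizes (equivalently, jointly shuffling matrix rows and
columns).  The p-value uses the add-one rule p = (1 + #{null <= obs}) /
(n_perm + 1) so it can never be zero.  Phonemes that are sole members of
their group are excluded from the test.

UPGMA (average-linkage) clustering uses the classical size-weighted update;
negative distances (possible under the cross-validated estimator) are kept
as-is in the grouping statistic but clamped to zero for clustering so merge
heights stay meaningful.  Ties are broken by lexicographic label order and
heights follow the molecular-phylogenetics convention height = distance / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .modulation import cv_distance, within_condition_distance

__all__ = [
    "DistanceMatrix",
    "GroupTestResult",
    "pairwise_distance_matrix",
    "grouping_test",
    "upgma",
    "UPGMATree",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    groups: dict[str, str]            # phoneme -> group id
    M: np.ndarray                     # symmetric signed distances, Hz

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.allclose(self.M, self.M.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        missing = set(self.labels) - set(self.groups)
        if missing:
            raise ValueError(f"groups missing for {sorted(missing)}")


@dataclass
class GroupTestResult:
    statistic: float                  # mean(within) - mean(between)
    null: np.ndarray
    p: float                          # one-sided, lower tail, add-one rule
    n_perm: int
    seed: int


def pairwise_distance_matrix(instances: np.ndarray, labels: np.ndarray,
                             groups: dict[str, str] | None = None,
                             n_splits: int = 20, seed: int = 0,
                             min_instances: int = 4) -> DistanceMatrix:
    """Phoneme x phoneme cross-validated signed distance matrix.

    ``instances`` is instances x electrodes; ``labels`` gives each row's
    phoneme.  Phonemes with fewer than ``min_instances`` occurrences are
    dropped with a warning.
    """
    labels = np.asarray(labels)
    keep, mats = [], {}
    for lab in dict.fromkeys(labels.tolist()):
        x = instances[labels == lab]
        if x.shape[0] < min_instances:
            warnings.warn(f"phoneme {lab!r} has {x.shape[0]} < "
                          f"{min_instances} instances; dropped", RuntimeWarning)
            continue
        keep.append(lab)
        mats[lab] = x
    if len(keep) < 2:
        raise ValueError("fewer than 2 phonemes with enough instances")
    rng = np.random.default_rng(seed)
    n = len(keep)
    M = np.zeros((n, n))
    for i in range(n):
        M[i, i] = within_condition_distance(mats[keep[i]], n_splits, rng)
        for j in range(i + 1, n):
            d = cv_distance(A=mats[keep[i]], B=mats[keep[j]]).d
            M[i, j] = M[j, i] = d
    groups = groups if groups is not None else {lab: lab for lab in keep}
    return DistanceMatrix(labels=list(keep), groups={k: groups[k] for k in keep},
                          M=M)


def grouping_test(D: DistanceMatrix, n_perm: int = 10_000,
                  seed: int = 0) -> GroupTestResult:
    """Permutation test for within-group vs between-group neural distances."""
    # canonical label order makes the null independent of input ordering
    order = np.argsort(np.asarray(D.labels))
    labels = [D.labels[i] for i in order]
    group_vec = np.asarray([D.groups[lab] for lab in labels])
    _, counts = np.unique(group_vec, return_counts=True)
    keep = np.isin(group_vec, np.unique(group_vec)[counts > 1])
    if keep.sum() < 2 or (counts > 1).sum() < 2:
        raise ValueError("need >= 2 non-singleton groups")
    g = group_vec[keep]
    M = D.M[np.ix_(order, order)][np.ix_(keep, keep)]
    n = g.size
    iu, ju = np.triu_indices(n, k=1)
    dvals = M[iu, ju]

    def statistic(gv: np.ndarray) -> float:
        within = gv[iu] == gv[ju]
        return float(dvals[within].mean() - dvals[~within].mean())

    obs = statistic(g)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = statistic(g[rng.permutation(n)])
    p = (1 + int(np.count_nonzero(null <= obs))) / (n_perm + 1)
    return GroupTestResult(statistic=obs, null=null, p=p, n_perm=n_perm,
                           seed=seed)


# ------------------------------------------------------------------ UPGMA

@dataclass
class UPGMATree:
    """Result of average-linkage agglomeration.

    ``merges`` lists (members_left, members_right, height) in merge order,
    members as tuples of leaf labels; heights are distance / 2.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def to_newick(self) -> str:
        height: dict[tuple[str, ...], float] = {(lab,): 0.0 for lab in self.labels}
        rep: dict[tuple[str, ...], str] = {(lab,): lab for lab in self.labels}
        node = None
        for left, right, h in self.merges:
            bl = h - height[left]
            br = h - height[right]
            node = f"({rep[left]}:{bl:.6g},{rep[right]}:{br:.6g})"
            merged = tuple(sorted(left + right))
            rep[merged] = node
            height[merged] = h
        return (node or self.labels[0]) + ";"


def upgma(D: DistanceMatrix | np.ndarray,
          labels: list[str] | None = None) -> UPGMATree:
    """Classical UPGMA on a symmetric distance matrix.

    Repeatedly merges the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted average of its members'
    distances.  Negative input distances are clamped to zero.  Ties are
    broken by the lexicographically smallest (min-label, min-label) pair.
    """
    if isinstance(D, DistanceMatrix):
        M = D.M.copy()
        labels = list(D.labels)
    else:
        M = np.asarray(D, dtype=float).copy()
        if labels is None:
            labels = [f"L{i}" for i in range(M.shape[0])]
    if not np.all(np.isfinite(M)):
        raise ValueError("distance matrix contains non-finite entries")
    M = np.clip(M, 0.0, None)
    np.fill_diagonal(M, 0.0)

    members: dict[int, tuple[str, ...]] = {i: (lab,) for i, lab in enumerate(labels)}
    active = list(members)
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = M[i, j]
                key = tuple(sorted((min(members[i]), min(members[j]))))
                if best is None or d < best[0] - 1e-15 or \
                        (abs(d - best[0]) <= 1e-15 and key < best[1]):
                    best = (d, key, i, j)
        d, _, i, j = best
        si, sj = len(members[i]), len(members[j])
        left, right = sorted((members[i], members[j]), key=min)
        merges.append((left, right, d / 2.0))
        # size-weighted average update, stored in slot i
        for k in active:
            if k not in (i, j):
                M[i, k] = M[k, i] = (si * M[i, k] + sj * M[j, k]) / (si + sj)
        members[i] = tuple(sorted(members[i] + members[j]))
        active.remove(j)
    return UPGMATree(labels=list(labels), merges=merges)
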