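"""Reciprocal monophyly tests and threshold clustering of a taxon.

A taxon is reciprocally monophyletic on an unrooted tree when removing
some edge splits the tips into exactly that taxon's specimens versus
everything else.  Deeply divergent taxa are partitioned into
single-linkage clusters at a distance threshold; a partition of two or
more monophyletic clusters separated by more than the threshold is the
operational signature of a candidate cryptic split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix


def leaf_sets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set below every node (postorder), one per tree edge."""
    sets: dict[int, frozenset[str]] = {}
    out: list[frozenset[str]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.child_nodes()))
        sets[id(node)] = s
        out.append(s)
    return out


def is_reciprocally_monophyletic(tree: dendropy.Tree, tip_set: Iterable[str]) -> bool:
    """True iff some edge bipartition has one side exactly ``tip_set``.

    Singletons and the full tip set are monophyletic by convention.
    """
    tips = frozenset(tip_set)
    if not tips:
        raise ValueError("tip_set must be non-empty")
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = tips - all_tips
    if unknown:
        raise KeyError(f"tip ids not in tree: {sorted(unknown)}")
    for ls in leaf_sets(tree):
        if ls == tips or (all_tips - ls) == tips:
            return True
    return False


@dataclass
class ClusterPartition:
    """Single-linkage partition of one taxon's specimens at a threshold."""

    taxon: str
    groups: list[list[str]]
    monophyletic: list[bool]
    threshold_pct: float
    between_min_pct: float | None = None
    between_max_pct: float | None = None

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def qualifies(self) -> bool:
        """Candidate split: >= 2 monophyletic groups, all separated by
        more than the threshold."""
        return (
            self.n_groups >= 2
            and all(self.monophyletic)
            and self.between_min_pct is not None
            and self.between_min_pct > self.threshold_pct
        )


def split_clusters(
    matrix: DistanceMatrix,
    tree: dendropy.Tree | None,
    members: Iterable[str],
    threshold_pct: float = 2.0,
    taxon: str = "",
) -> ClusterPartition:
    """Partition a taxon's specimens into clusters at a distance threshold.

    Groups are the connected components of the graph on ``members``
    linking pairs at distance <= ``threshold_pct`` (single linkage).
    Each group is annotated with its reciprocal monophyly on ``tree``
    (all flags True when ``tree`` is None).  Between-group divergence is
    summarized by the minimum (used for the qualifying rule — a
    qualifying split has a genuine barcode gap) and the maximum.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    member_set = set(members)
    ordered = [i for i in matrix.ids if i in member_set]
    missing = member_set - set(ordered)
    if missing:
        raise KeyError(f"members absent from matrix: {sorted(missing)}")
    if tree is not None:
        tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        absent = member_set - tree_tips
        if absent:
            raise KeyError(f"members absent from tree: {sorted(absent)}")

    sub = matrix.submatrix(ordered)
    pct = sub.percent
    adj = sub.defined_mask & (pct <= threshold_pct)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )

    # order groups by first appearance for determinism
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for sid, lab in zip(ordered, labels):
        groups[order[lab]].append(sid)

    mono = [
        True if tree is None else is_reciprocally_monophyletic(tree, g)
        for g in groups
    ]

    between_min = between_max = None
    if n_comp >= 2:
        mins, maxs = [], []
        for a in range(n_comp):
            ia = [sub.index_of(s) for s in groups[a]]
            for b in range(a + 1, n_comp):
                ib = [sub.index_of(s) for s in groups[b]]
                block = pct[np.ix_(ia, ib)]
                block = block[np.isfinite(block)]
                if block.size:
                    mins.append(block.min())
                    maxs.append(block.max())
        if mins:
            between_min = float(min(mins))
            between_max = float(max(maxs))

    return ClusterPartition(
        taxon=taxon,
        groups=groups,
        monophyletic=mono,
        threshold_pct=threshold_pct,
        between_min_pct=between_min,
        between_max_pct=between_max,
    )


def qualifying_partition(
    matrix: DistanceMatrix,
    tree: dendropy.Tree,
    members: Iterable[str],
    threshold_pct: float = 2.0,
    taxon: str = "",
) -> ClusterPartition | None:
    """Finest qualifying cluster partition of a taxon at a threshold.

    The split criterion — the taxon contains two or more reciprocally
    monophyletic clusters separated by more than the threshold — is an
    existential statement: a pair of well-separated monophyletic
    clusters read off the tree satisfies it at every threshold below
    their separation.  This search therefore walks the single-linkage
    merge levels upward from ``threshold_pct`` and returns the finest
    partition with >= 2 groups that are all monophyletic (components at
    cut level L are separated by more than L >= threshold by
    construction), or None when no such partition exists.  Unlike the
    partition at the threshold itself, the result is monotone: a split
    found at one threshold is found at every lower threshold.
    """
    member_set = set(members)
    ordered = [i for i in matrix.ids if i in member_set]
    sub = matrix.submatrix(ordered)
    pct = sub.percent
    finite = pct[np.isfinite(pct)]
    levels = sorted({threshold_pct} | {v for v in finite.tolist() if v > threshold_pct})
    for level in levels:
        part = split_clusters(
            matrix, tree, ordered, threshold_pct=level, taxon=taxon
        )
        if part.n_groups < 2:
            return None  # coarser cuts only merge further
        if all(part.monophyletic):
            part.threshold_pct = threshold_pct
            return part
    return None
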