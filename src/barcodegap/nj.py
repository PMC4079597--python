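"""Neighbour-joining tree construction on K2P distance matrices.

Canonical agglomerative NJ: at each step the pair minimizing the
Q-criterion

    Q(i, j) = (n - 2) d(i, j) - R_i - R_j,   R_i = sum_k d(i, k)

is joined, with the standard branch-length formulas.  Determinism is
pinned down: ties on Q are broken by the lowest (row, column) index pair,
and negative intermediate branch lengths are clamped to zero with the
deficit transferred to the sibling branch, so downstream monophyly logic
always sees non-negative lengths.

Trees are :class:`dendropy.Tree` objects (stored arbitrarily rooted;
``is_rooted`` False) with tips labelled by ``sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .distance import DistanceMatrix


def build_nj(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree from a fully defined distance matrix.

    Raises on matrices with masked (undefined) pairs — resolve those
    upstream, e.g. with :meth:`DistanceMatrix.drop_undefined` — and on
    matrices with fewer than two tips.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 tips to build a tree")
    if not matrix.fully_defined:
        raise ValueError(
            "distance matrix has undefined pairs; drop the affected records "
            "first (DistanceMatrix.drop_undefined)"
        )

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for sid in matrix.ids:
        taxon = tns.new_taxon(label=sid)
        leaf = dendropy.Node(taxon=taxon)
        nodes.append(leaf)

    d = matrix.values.astype(float).copy()
    active = list(range(len(matrix)))

    if len(active) == 2:
        root = dendropy.Node()
        half = d[0, 1] / 2.0
        for k in (0, 1):
            nodes[k].edge.length = half
            root.add_child(nodes[k])
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    # map active position -> global node index; d kept square over actives
    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(n, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first occurrence = lowest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])

        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sibling branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        nodes.append(parent)
        gp = len(nodes) - 1

        # distances from the new node to every other active node
        new_row = np.full(len(nodes), np.nan)
        for pos, gk in enumerate(active):
            if pos in (i, j):
                continue
            new_row[gk] = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=np.nan)
        d[gp, : gp] = new_row[:gp]
        d[: gp, gp] = new_row[:gp]
        d[gp, gp] = 0.0

        active = [g for g in active if g not in (gi, gj)] + [gp]

    ga, gb = active
    # root at the internal node created last; attach the other below it
    if nodes[gb].is_leaf() and not nodes[ga].is_leaf():
        root, other = nodes[ga], nodes[gb]
    else:
        root, other = nodes[gb], nodes[ga]
    other.edge.length = max(d[ga, gb], 0.0)
    root.add_child(other)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix of a tree.

    Returned in tree leaf order; values share the branch-length units
    (proportion scale for NJ trees built here).
    """
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    ids = [t.label for t in leaves]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(
                leaves[i], leaves[j]
            )
    return DistanceMatrix(
        ids=ids, values=values, defined_mask=np.ones((n, n), dtype=bool)
    )


def write_newick(tree: dendropy.Tree, destination: str | Path) -> None:
    """Write standard Newick with branch lengths at full precision.

    Tip labels are the sample_ids; labels containing Newick-reserved
    characters are quoted per the standard.
    """
    newick = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        real_value_format_specifier=".17g",
    )
    Path(destination).write_text(newick)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree; tips keyed by their labels."""
    return dendropy.Tree.get(
        path=str(source), schema="newick", preserve_underscores=True
    )
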