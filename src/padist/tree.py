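"""Distance-based tree building (BioNJ) and topology comparison (RF).

BioNJ (Gascuel 1997) is neighbor joining with a variance-weighted matrix
reduction: when clusters i and j are merged into u, the new distances are
``d(u,k) = lam*(d(i,k) - L_i) + (1-lam)*(d(j,k) - L_j)`` where the weight
``lam`` minimizes the variance of the reduced estimates, under the model
that the variance of each distance estimate is proportional to the distance
itself.  On additive (tree-like) matrices it reproduces the generating tree
exactly, like plain NJ; on noisy matrices the weighting improves accuracy.

The Robinson-Foulds distance counts non-trivial bipartitions (splits)
present in exactly one of two unrooted trees; normalized by the total
number of non-trivial splits in both trees, which is ``2(N-3)`` for a pair
of fully resolved binary trees.

Trees are dendropy objects throughout; Newick is the interchange format.
"""

from __future__ import annotations

import os

import dendropy
import numpy as np

from .records import ConsistencyError, DistanceMatrix, PadistError


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                suppress_rooting=True,
            )
        )


# ---------------------------------------------------------------------------
# BioNJ


def bionj(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted BioNJ tree from a distance matrix (N >= 3).

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest cluster labels (a cluster is labelled by its
    smallest member id).  Negative branch-length estimates are clamped to
    zero with the deficit transferred to the sister edge.
    """
    n = len(dm)
    if n < 3:
        raise PadistError(f"BioNJ needs at least 3 taxa, got {n}")
    d = np.array(dm.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise PadistError("distance matrix contains NaN or infinite entries")
    v = d.copy()  # variance estimates, proportional to the distances
    labels = list(dm.ids)  # tie-break key: smallest member id per cluster
    newicks = list(dm.ids)  # growing subtree strings

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(labels) > 3:
        r = len(labels)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = (q,) + tuple(sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)

        others = [k for k in range(r) if k not in (i, j)]
        if v[i, j] > 0:
            lam = 0.5 + (v[j, others] - v[i, others]).sum() / (
                2.0 * (r - 2) * v[i, j]
            )
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        new_d = lam * (d[i, others] - li) + (1.0 - lam) * (d[j, others] - lj)
        new_v = (
            lam * v[i, others]
            + (1.0 - lam) * v[j, others]
            - lam * (1.0 - lam) * v[i, j]
        )

        merged = f"({newicks[i]}:{li:.12g},{newicks[j]}:{lj:.12g})"
        label = min(labels[i], labels[j])
        keep = others
        d = np.vstack([d[np.ix_(keep, keep)], new_d[None, :]])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        v = np.vstack([v[np.ix_(keep, keep)], new_v[None, :]])
        v = np.hstack([v, np.append(new_v, 0.0)[:, None]])
        labels = [labels[k] for k in keep] + [label]
        newicks = [newicks[k] for k in keep] + [merged]

    # Final three clusters joined at a central node (three-point formulas).
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({newicks[0]}:{la:.12g},{newicks[1]}:{lb:.12g},"
        f"{newicks[2]}:{lc:.12g});"
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) matrix of a tree."""
    adj: dict[object, list[tuple[object, float]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))
    leaves = {lf: lf.taxon.label for lf in tree.leaf_node_iter()}
    ids = sorted(leaves.values())
    node_of = {label: lf for lf, label in leaves.items()}
    n = len(ids)
    values = np.zeros((n, n))
    for a, label in enumerate(ids):
        dist = {node_of[label]: 0.0}
        stack = [node_of[label]]
        while stack:
            u = stack.pop()
            for nb, w in adj.get(u, []):
                if nb not in dist:
                    dist[nb] = dist[u] + w
                    stack.append(nb)
        for b in range(n):
            values[a, b] = dist[node_of[ids[b]]]
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids, (values + values.T) / 2.0)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _splits(tree: dendropy.Tree) -> tuple[set[frozenset], int]:
    """Non-trivial bipartitions of an unrooted tree.

    Each split is canonicalized as the side not containing a fixed
    reference leaf, so rooted and unrooted encodings of the same tree give
    identical sets.  Returns (splits, number_of_leaves).
    """
    leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(set(leaf_labels)) != len(leaf_labels):
        raise ConsistencyError("duplicate leaf labels")
    all_leaves = frozenset(leaf_labels)
    ref = leaf_labels[0]
    n = len(leaf_labels)
    splits: set[frozenset] = set()
    below: dict[object, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
            side = below[node]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
    return splits, n


def rf_distance(
    treeA: dendropy.Tree, treeB: dendropy.Tree
) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalized form in [0, 1].

    ``rf`` is the size of the symmetric difference of the two trees'
    non-trivial split sets; the normalization divides by the total number
    of non-trivial splits in both trees (``2(N-3)`` when both are binary).
    """
    sa, na = _splits(treeA)
    sb, nb = _splits(treeB)
    la = {lf.taxon.label for lf in treeA.leaf_node_iter()}
    lb = {lf.taxon.label for lf in treeB.leaf_node_iter()}
    if la != lb:
        raise ConsistencyError(
            f"leaf sets differ: {sorted(la ^ lb)} not shared"
        )
    rf = len(sa ^ sb)
    denom = len(sa) + len(sb)
    return rf, (rf / denom if denom else 0.0)
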