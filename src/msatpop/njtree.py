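"""Neighbour-Joining tree construction (Saitou & Nei) with Newick output.

At each step with ``r`` active nodes the pair minimising
``Q_ij = (r - 2) d_ij - sum_k d_ik - sum_k d_jk`` is joined; branch lengths
are ``v_i = d_ij / 2 + (sum_k d_ik - sum_k d_jk) / (2 (r - 2))`` and the new
node's distances are ``d(u, k) = (d_ik + d_jk - d_ij) / 2``.  The method is
exact on additive distance matrices.  Ties in the argmin are broken by the
lexicographically smallest (min-leaf, min-leaf) label pair, so the result is
deterministic.  Negative branch lengths are kept by default; an optional
clamp zeroes them and transfers the length to the sibling branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neidist import DistanceMatrix

__all__ = ["TreeNode", "PhyloTree", "neighbor_joining", "to_newick"]


@dataclass
class TreeNode:
    """A rooted view of one node of the (unrooted) tree.

    ``name`` is empty for internal nodes; ``children`` pairs each child with
    the length of the connecting edge.
    """

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def min_leaf(self) -> str:
        if self.is_leaf:
            return self.name
        return min(c.min_leaf for c, _ in self.children)

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree, stored rooted at the final join for serialization."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def total_length(self) -> float:
        def walk(node: TreeNode) -> float:
            return sum(length + walk(c) for c, length in node.children)

        return walk(self.root)

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length matrix between all leaf pairs (additivity check)."""
        labels = self.leaf_names
        pos = {lab: i for i, lab in enumerate(labels)}
        k = len(labels)
        D = np.zeros((k, k))

        def walk(node: TreeNode) -> dict[str, float]:
            """Leaf -> distance to ``node``; fills D for pairs meeting here."""
            if node.is_leaf:
                return {node.name: 0.0}
            seen: dict[str, float] = {}
            for child, length in node.children:
                sub = {leaf: d + length for leaf, d in walk(child).items()}
                for leaf_a, da in sub.items():
                    for leaf_b, db in seen.items():
                        i, j = pos[leaf_a], pos[leaf_b]
                        D[i, j] = D[j, i] = da + db
                seen.update(sub)
            return seen

        walk(self.root)
        return DistanceMatrix(labels, D, np.exp(-D))

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions (as the smaller-side leaf sets), for
        topology comparison of unrooted trees."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(below if sorted(below) <= sorted(other) else other)
            return below

        for child, _ in self.root.children:
            walk(child)
        return out

    def newick(self, precision: int = 6) -> str:
        return to_newick(self, precision)


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Build the Neighbour-Joining tree of a distance matrix."""
    d = np.asarray(D.distance, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains masked (NaN) entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.diag(d).any():
        raise ValueError("distance matrix diagonal must be zero")
    n = len(D.labels)
    if n < 2:
        raise ValueError("need >= 2 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    if n == 2:
        half = d[0, 1] / 2.0
        a, b = sorted(nodes, key=lambda t: t.min_leaf)
        return PhyloTree(TreeNode(children=[(a, half), (b, half)]))

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    node_of: dict[int, TreeNode] = dict(enumerate(nodes))

    def dd(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dd(i, k) for k in active) for i in active}
        best = None
        best_key = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dd(i, j) - sums[i] - sums[j]
                key = tuple(sorted((node_of[i].min_leaf, node_of[j].min_leaf)))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and key < best_key):
                    best, best_key, pair = q, key, (i, j)
        i, j = pair
        dij = dd(i, j)
        vi = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        vj = dij - vi
        if clamp_negative:
            vi, vj = _clamp_pair(vi, vj)
        children = sorted(
            [(node_of[i], vi), (node_of[j], vj)], key=lambda cv: cv[0].min_leaf
        )
        new = TreeNode(children=children)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = (dd(i, k) + dd(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = new

    # final three-way join: solve the three branch equations
    i, j, k = active
    vi = (dd(i, j) + dd(i, k) - dd(j, k)) / 2.0
    vj = (dd(i, j) + dd(j, k) - dd(i, k)) / 2.0
    vk = (dd(i, k) + dd(j, k) - dd(i, j)) / 2.0
    if clamp_negative:
        vi, vj, vk = (max(v, 0.0) for v in (vi, vj, vk))
    children = sorted(
        [(node_of[i], vi), (node_of[j], vj), (node_of[k], vk)],
        key=lambda cv: cv[0].min_leaf,
    )
    return PhyloTree(TreeNode(children=children))


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    # zero a negative branch and transfer its length to the sibling
    if vi < 0:
        return 0.0, vj + vi
    if vj < 0:
        return vi + vj, 0.0
    return vi, vj


def to_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize with deterministic child order (by smallest contained leaf)."""

    def quote(name: str) -> str:
        if any(ch in name for ch in " ,():;'[]"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def fmt(node: TreeNode, length: float | None) -> str:
        if node.is_leaf:
            body = quote(node.name)
        else:
            kids = sorted(node.children, key=lambda cv: cv[0].min_leaf)
            body = "(" + ",".join(fmt(c, v) for c, v in kids) + ")"
        if length is None:
            return body
        return f"{body}:{length:.{precision}f}".rstrip()

    return fmt(tree.root, None) + ";"
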