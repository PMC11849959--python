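"""Phylogeny handling: Newick I/O, polytomy resolution, pruning, and indexing.

The working representation for file-level operations is :class:`skbio.TreeNode`.
Downstream numeric code uses :class:`PhyloTree`, an immutable array-backed
index of a strictly binary rooted tree in which the ``p - 1`` internal nodes
are numbered ``1 .. p-1`` in pre-order (root first, left child before right)
so that every internal node's index is smaller than the indices of all
internal nodes in its subtree.
"""

from __future__ import annotations

import io
from collections.abc import Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "PhyloTree",
    "read_newick",
    "has_polytomy",
    "resolve_polytomies",
    "prune_to_taxa",
    "index_nodes",
]


def _leaf_code(leaf_index: int) -> int:
    # children are encoded in a single int array: positive values are internal
    # node ids, negative values encode leaf index j as -(j + 1)
    return -(leaf_index + 1)


def _is_leaf_code(code: int) -> bool:
    return code < 0


def _decode_leaf(code: int) -> int:
    return -code - 1


class PhyloTree:
    """Indexed strictly-binary rooted phylogeny over ``p`` taxa.

    Parameters
    ----------
    taxa
        Leaf names in canonical order; abundance vectors align to this order.
    left, right
        Arrays of length ``p`` where slot ``v`` (``1 <= v <= p-1``) holds the
        child code of internal node ``v`` (positive = internal id, negative =
        encoded leaf index). Slot 0 is unused; the root is node 1.
    parent
        ``parent[v]`` is the parent internal id of node ``v`` (0 for the root).

    Descendant-leaf sets, subtree internal-node sets and root-to-leaf paths
    are cached at construction.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        left: np.ndarray,
        right: np.ndarray,
        parent: np.ndarray,
    ) -> None:
        self.taxa: tuple[str, ...] = tuple(taxa)
        p = len(self.taxa)
        if p < 2:
            raise ValueError("a PhyloTree needs at least 2 leaves")
        self._left = np.asarray(left, dtype=np.int64)
        self._right = np.asarray(right, dtype=np.int64)
        self._parent = np.asarray(parent, dtype=np.int64)
        self._build_caches()

    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_internal(self) -> int:
        return len(self.taxa) - 1

    @property
    def root(self) -> int:
        return 1

    def children(self, v: int) -> tuple[int, int]:
        """Raw child codes ``(left, right)`` of internal node ``v``."""
        return int(self._left[v]), int(self._right[v])

    def parent(self, v: int) -> int:
        return int(self._parent[v])

    def leaf_indices(self, v: int) -> np.ndarray:
        """Indices (into ``taxa``) of the descendant leaves of ``v``."""
        return self._leaf_sets[v]

    def subtree_internal(self, v: int) -> np.ndarray:
        """Internal node ids of the subtree rooted at ``v`` (including v)."""
        return self._subtrees[v]

    def leaf_path(self, j: int) -> list[tuple[int, int]]:
        """Root-to-leaf path for leaf ``j`` as ``(internal id, side)`` pairs.

        ``side`` is 0 if the path continues into the left child, 1 for right.
        """
        return self._paths[j]

    # ------------------------------------------------------------------
    def _build_caches(self) -> None:
        p = self.n_leaves
        leaf_sets: list[np.ndarray | None] = [None] * p
        subtrees: list[np.ndarray | None] = [None] * p
        # pre-order ids guarantee descendants have larger ids, so a single
        # descending sweep resolves children before parents
        for v in range(p - 1, 0, -1):
            leaves: list[np.ndarray] = []
            nodes: list[np.ndarray] = [np.array([v], dtype=np.int64)]
            for code in (self._left[v], self._right[v]):
                code = int(code)
                if _is_leaf_code(code):
                    leaves.append(np.array([_decode_leaf(code)], dtype=np.int64))
                else:
                    leaves.append(leaf_sets[code])
                    nodes.append(subtrees[code])
            leaf_sets[v] = np.concatenate(leaves)
            subtrees[v] = np.concatenate(nodes)
        self._leaf_sets = leaf_sets
        self._subtrees = subtrees

        paths: list[list[tuple[int, int]] | None] = [None] * p
        stack: list[tuple[int, list[tuple[int, int]]]] = [(1, [])]
        while stack:
            v, prefix = stack.pop()
            for side, code in enumerate((self._left[v], self._right[v])):
                code = int(code)
                step = prefix + [(v, side)]
                if _is_leaf_code(code):
                    paths[_decode_leaf(code)] = step
                else:
                    stack.append((code, step))
        self._paths = paths

        # sanity: partition property at the root
        if len(self._leaf_sets[1]) != p:
            raise AssertionError("descendant-leaf cache does not cover all taxa")

    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def render(code: int) -> str:
            if _is_leaf_code(code):
                return self.taxa[_decode_leaf(code)]
            left, right = self.children(code)
            return f"({render(left)},{render(right)})"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(p={self.n_leaves}, internal={self.n_internal})"


# ----------------------------------------------------------------------
# TreeNode-level operations
# ----------------------------------------------------------------------

def read_newick(path) -> TreeNode:
    """Read a rooted tree from a Newick file.

    The returned tree may still contain polytomies; branch lengths are
    retained but ignored downstream. Raises ``ValueError`` on duplicate leaf
    labels or files containing more than one tree.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    trees = [chunk for chunk in text.split(";") if chunk.strip()]
    if len(trees) != 1:
        raise ValueError(
            f"expected exactly one rooted tree, found {len(trees)} in input"
        )
    tree = TreeNode.read(io.StringIO(trees[0] + ";"), format="newick")
    seen: set[str] = set()
    for tip in tree.tips():
        if tip.name is None:
            raise ValueError("unnamed leaf in Newick input")
        if tip.name in seen:
            raise ValueError(f"duplicate leaf label: {tip.name!r}")
        seen.add(tip.name)
    return tree


def has_polytomy(tree: TreeNode) -> bool:
    return any(
        len(node.children) > 2 for node in tree.traverse(include_self=True)
    )


def resolve_polytomies(tree: TreeNode, seed: int) -> TreeNode:
    """Return a strictly binary copy of ``tree``.

    Each polytomy of k children is resolved by a seeded shuffle of the
    children followed by laddering, inserting exactly ``k - 2`` internal
    nodes with zero-length branches. Binary input is returned unchanged
    (topologically).
    """
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    for node in list(tree.traverse(include_self=True)):
        kids = list(node.children)
        if len(kids) <= 2:
            continue
        order = rng.permutation(len(kids))
        kids = [kids[i] for i in order]
        for child in kids:
            node.remove(child)
        current = kids[0]
        for child in kids[1:-1]:
            joint = TreeNode(length=0.0)
            joint.append(current)
            joint.append(child)
            current = joint
        node.append(current)
        node.append(kids[-1])
    return tree


def prune_to_taxa(tree: TreeNode, taxa: Sequence[str]) -> TreeNode:
    """Restrict ``tree`` to the given taxa, suppressing unary nodes."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    present = {tip.name for tip in tree.tips()}
    missing = [t for t in taxa if t not in present]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    pruned = tree.shear(taxa)
    while len(pruned.children) == 1:  # defensive: unary root
        pruned = pruned.children[0]
        pruned.parent = None
    return pruned


def index_nodes(
    tree: TreeNode, leaf_order: Sequence[str] | None = None
) -> PhyloTree:
    """Index a strictly binary ``TreeNode`` into a :class:`PhyloTree`.

    Internal nodes are numbered 1..p-1 in pre-order with the left child
    visited before the right, so ancestors always precede descendants.
    ``leaf_order`` fixes the canonical taxon order (e.g. the abundance-table
    header); by default the tree's own left-to-right tip order is used.
    """
    for node in tree.traverse(include_self=True):
        if not node.is_tip() and len(node.children) != 2:
            raise ValueError(
                f"tree is not strictly binary: node with "
                f"{len(node.children)} children"
            )
    tip_names = [tip.name for tip in tree.tips()]
    if len(set(tip_names)) != len(tip_names):
        raise ValueError("duplicate leaf labels")
    if leaf_order is None:
        leaf_order = tip_names
    elif set(leaf_order) != set(tip_names) or len(leaf_order) != len(tip_names):
        raise ValueError("leaf_order must be a permutation of the tree's tips")
    leaf_pos = {name: j for j, name in enumerate(leaf_order)}

    p = len(tip_names)
    ids: dict[int, int] = {}
    next_id = 1
    order: list[TreeNode] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_tip():
            continue
        ids[id(node)] = next_id
        next_id += 1
        order.append(node)
        # reversed so the left child is processed first (LIFO stack)
        stack.extend(reversed(node.children))

    left = np.zeros(p, dtype=np.int64)
    right = np.zeros(p, dtype=np.int64)
    parent = np.zeros(p, dtype=np.int64)
    for node in order:
        v = ids[id(node)]
        codes = []
        for child in node.children:
            if child.is_tip():
                codes.append(_leaf_code(leaf_pos[child.name]))
            else:
                u = ids[id(child)]
                parent[u] = v
                codes.append(u)
        left[v], right[v] = codes
    return PhyloTree(list(leaf_order), left, right, parent)
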