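"""Fully synthetic benchmark data: random phylogeny, counts, binary trait.

The trait signal is concentrated in the leaves of a few designated clades:
positive samples multiply those leaves' composition by a fold-change and
renormalize, so the signal has exactly the phylogenetically localized
structure that subtree-exchange augmentation can exploit. ``effect_size=1``
yields a null dataset (labels carry no information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .datasets import LabeledDataset
from .tree import PhyloTree, index_nodes

__all__ = ["SimConfig", "random_binary_tree", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    p: int = 200
    n: int = 100
    n_signal_subtrees: int = 4
    effect_size: float = 4.0
    depth_range: tuple[int, int] = (1000, 5000)
    base_concentration: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 4:
            raise ValueError("p must be >= 4")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid depth_range")


def random_binary_tree(p: int, seed: int) -> PhyloTree:
    """Random binary topology over leaves t1..tp by random sequential joins."""
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{j + 1}") for j in range(p)]
    while len(nodes) > 1:
        a = int(rng.integers(len(nodes)))
        left = nodes.pop(a)
        b = int(rng.integers(len(nodes)))
        right = nodes.pop(b)
        joint = TreeNode()
        joint.append(left)
        joint.append(right)
        nodes.append(joint)
    return index_nodes(nodes[0])


def _pick_signal_clades(
    tree: PhyloTree, k: int, rng: np.random.Generator
) -> list[int]:
    """Choose k non-overlapping internal nodes with mid-sized clades."""
    p = tree.n_leaves
    if k > tree.n_internal:
        raise ValueError(
            f"n_signal_subtrees={k} exceeds the {tree.n_internal} internal nodes"
        )
    lo = max(2, p // 50)
    hi = max(lo + 1, p // 5)
    candidates = [
        v
        for v in range(1, p)
        if lo <= len(tree.leaf_indices(v)) <= hi
    ]
    chosen: list[int] = []
    taken = np.zeros(p, dtype=bool)
    for v in rng.permutation(candidates):
        v = int(v)
        leaves = tree.leaf_indices(v)
        if taken[leaves].any():
            continue
        chosen.append(v)
        taken[leaves] = True
        if len(chosen) == k:
            break
    if len(chosen) < k:
        # fall back to any remaining internal nodes, overlap allowed
        rest = [v for v in range(1, p) if v not in chosen]
        for v in rng.permutation(rest):
            chosen.append(int(v))
            if len(chosen) == k:
                break
    return chosen


def simulate_dataset(
    config: SimConfig,
) -> tuple[PhyloTree, LabeledDataset, list[dict]]:
    """Simulate (tree, labeled count table, ground-truth signal clades).

    Per sample: baseline composition ~ Dirichlet(base_concentration) iid per
    taxon; positive samples multiply signal-clade leaves by effect_size and
    renormalize; depth ~ uniform integer in depth_range; counts ~
    multinomial(depth, composition). With effect_size=1 the classes are
    identically distributed.
    """
    rng = np.random.default_rng(config.seed)
    tree = random_binary_tree(config.p, config.seed)
    signal_nodes = _pick_signal_clades(tree, config.n_signal_subtrees, rng)
    signal_leaves = np.unique(
        np.concatenate([tree.leaf_indices(v) for v in signal_nodes])
    )

    n_pos = int(round(config.n * config.class_balance))
    n_pos = min(max(n_pos, 1), config.n - 1)
    y = np.zeros(config.n)
    y[rng.permutation(config.n)[:n_pos]] = 1.0

    lo, hi = config.depth_range
    alpha = np.full(config.p, config.base_concentration)
    X = np.empty((config.n, config.p))
    for i in range(config.n):
        composition = rng.dirichlet(alpha)
        if y[i] == 1.0:
            composition = composition.copy()
            composition[signal_leaves] *= config.effect_size
            composition /= composition.sum()
        depth = int(rng.integers(lo, hi + 1))
        X[i] = rng.multinomial(depth, composition)

    dataset = LabeledDataset(
        X=X,
        y=y,
        taxa=tree.taxa,
        sample_ids=tuple(f"S{i}" for i in range(config.n)),
        mode="count",
    )
    truth = [
        {"node": v, "leaves": [tree.taxa[j] for j in tree.leaf_indices(v)]}
        for v in signal_nodes
    ]
    return tree, dataset, truth
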