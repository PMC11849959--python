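"""Probabilistic phylogenetic profiles.

A profile encodes a sample as (i) its total abundance and (ii), for every
internal node of a binary phylogeny, the fraction of that node's abundance
falling into its left vs. right child subtree. Relative abundances are
recovered by multiplying the branch-side probabilities along each
root-to-leaf path; absolute abundances allocate the stored total along the
same paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree

__all__ = [
    "PhyloProfile",
    "build_profile",
    "reconstruct_relative",
    "allocate_relative",
    "reconstruct_absolute",
]


@dataclass
class PhyloProfile:
    """Total abundance plus one left-branch probability per internal node.

    ``left_probs`` has length ``p`` with slot ``v`` (1-based internal id)
    holding ``l_v``; the right probability is ``1 - l_v``. Slot 0 is unused.
    """

    total: float
    left_probs: np.ndarray

    def probs(self, v: int) -> tuple[float, float]:
        lv = float(self.left_probs[v])
        return lv, 1.0 - lv

    def copy(self) -> "PhyloProfile":
        return PhyloProfile(self.total, self.left_probs.copy())


def build_profile(x: np.ndarray, tree: PhyloTree) -> PhyloProfile:
    """Encode an abundance vector (aligned to ``tree.taxa``) as a profile.

    Nodes whose whole subtree has zero abundance get probability (0.5, 0.5);
    an ancestor factor of zero makes the choice immaterial on reconstruction.
    """
    x = np.asarray(x, dtype=float)
    p = tree.n_leaves
    if x.shape != (p,):
        raise ValueError(f"abundance vector has shape {x.shape}, expected ({p},)")
    if np.any(x < 0):
        raise ValueError("negative abundance")

    sums = np.zeros(p)  # subtree sums, slot v for internal node v
    left_sums = np.zeros(p)
    for v in range(p - 1, 0, -1):  # children before parents (pre-order ids)
        lc, rc = tree.children(v)
        ls = x[-lc - 1] if lc < 0 else sums[lc]
        rs = x[-rc - 1] if rc < 0 else sums[rc]
        sums[v] = ls + rs
        left_sums[v] = ls
    left_probs = np.full(p, 0.5)
    nz = sums > 0
    nz[0] = False
    left_probs[nz] = left_sums[nz] / sums[nz]
    return PhyloProfile(total=float(x.sum()), left_probs=left_probs)


def _check(profile: PhyloProfile, tree: PhyloTree) -> None:
    if profile.left_probs.shape[0] != tree.n_leaves:
        raise ValueError("profile does not cover all internal nodes of the tree")


def reconstruct_relative(profile: PhyloProfile, tree: PhyloTree) -> np.ndarray:
    """Relative abundances via root-to-leaf path products."""
    _check(profile, tree)
    p = tree.n_leaves
    rel = np.empty(p)
    for j in range(p):
        prob = 1.0
        for v, side in tree.leaf_path(j):
            lv = profile.left_probs[v]
            prob *= lv if side == 0 else 1.0 - lv
        rel[j] = prob
    return rel


def allocate_relative(profile: PhyloProfile, tree: PhyloTree) -> np.ndarray:
    """Relative abundances via recursive top-down mass allocation.

    Independent route kept alongside :func:`reconstruct_relative`: the root
    starts with mass 1 and every internal node splits its mass between its
    children by (l_v, r_v).
    """
    _check(profile, tree)
    p = tree.n_leaves
    rel = np.empty(p)
    mass = np.zeros(p)
    mass[1] = 1.0
    for v in range(1, p):  # ascending pre-order ids: parents before children
        lv = profile.left_probs[v]
        for code, share in ((tree.children(v)[0], mass[v] * lv),
                            (tree.children(v)[1], mass[v] * (1.0 - lv))):
            if code < 0:
                rel[-code - 1] = share
            else:
                mass[code] = share
    return rel


def reconstruct_absolute(
    profile: PhyloProfile, tree: PhyloTree, rounding: str = "none"
) -> np.ndarray:
    """Allocate the profile's total along the tree; optionally round half-up."""
    if rounding not in ("none", "nearest"):
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    if profile.total == 0:
        return np.zeros(tree.n_leaves)
    abs_ = reconstruct_relative(profile, tree) * profile.total
    if rounding == "nearest":
        abs_ = np.floor(abs_ + 0.5)
    return abs_
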