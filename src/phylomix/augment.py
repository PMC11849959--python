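"""Synthetic sample generation.

Two augmenters share the same pairing and mixing-weight machinery:

* phylogeny-guided subtree exchange — a Beta(alpha, alpha) weight ``lam``
  decides how many internal nodes to take from the partner sample; whole
  subtrees are swapped in the probabilistic profile until roughly
  ``(1 - lam)`` of the internal nodes come from the partner, and abundances
  are rebuilt at the base sample's sequencing depth;
* vanilla mixup — elementwise convex combination of the two feature vectors.

Both mix labels as ``lam * y_i + (1 - lam) * y_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .profile import (
    PhyloProfile,
    build_profile,
    reconstruct_absolute,
    reconstruct_relative,
)
from .tree import PhyloTree

__all__ = [
    "AugmentConfig",
    "SyntheticSample",
    "draw_mixing_weight",
    "sample_exchange_set",
    "phylomix_pair",
    "phylomix_augment",
    "vanilla_mixup",
]


@dataclass(frozen=True)
class AugmentConfig:
    alpha: float = 2.0
    ratio: float = 3.0
    seed: int = 0
    mode: str = "count"
    rounding: str = "none"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if self.mode not in ("count", "relative"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.rounding not in ("none", "nearest"):
            raise ValueError(f"unknown rounding: {self.rounding!r}")


@dataclass(frozen=True)
class SyntheticSample:
    abundance: np.ndarray
    label: float
    i: int
    j: int
    lam: float
    exchanged: frozenset[int] = field(default_factory=frozenset)


def draw_mixing_weight(alpha: float, rng: np.random.Generator) -> float:
    """One draw from Beta(alpha, alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(rng.beta(alpha, alpha))


def sample_exchange_set(
    tree: PhyloTree, lam: float, rng: np.random.Generator
) -> set[int]:
    """Draw-and-exchange: accumulate whole subtrees of internal nodes.

    Internal nodes are drawn uniformly from those not yet exchanged; each
    draw contributes the node plus all its not-yet-exchanged descendant
    internal nodes. Drawing stops as soon as the set reaches
    ``ceil((1 - lam) * (p - 1))`` nodes; the final draw may overshoot and is
    kept in full.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    n_internal = tree.n_internal
    target = math.ceil((1.0 - lam) * n_internal)
    exchanged: set[int] = set()
    if target == 0:
        return exchanged
    remaining = np.ones(n_internal + 1, dtype=bool)
    remaining[0] = False
    while len(exchanged) < target:
        pool = np.flatnonzero(remaining)
        v = int(pool[rng.integers(len(pool))])
        new = [int(u) for u in tree.subtree_internal(v) if remaining[u]]
        exchanged.update(new)
        remaining[new] = False
    return exchanged


def _mix_profiles(
    base: PhyloProfile, partner: PhyloProfile, exchanged: set[int]
) -> PhyloProfile:
    mixed = base.copy()
    if exchanged:
        idx = np.fromiter(exchanged, dtype=np.int64)
        mixed.left_probs[idx] = partner.left_probs[idx]
    return mixed


def _materialize(
    mixed: PhyloProfile, tree: PhyloTree, config: AugmentConfig
) -> np.ndarray:
    if config.mode == "relative":
        return reconstruct_relative(mixed, tree)
    return reconstruct_absolute(mixed, tree, rounding=config.rounding)


def phylomix_pair(
    xi: np.ndarray,
    yi: float,
    xj: np.ndarray,
    yj: float,
    tree: PhyloTree,
    config: AugmentConfig,
    rng: np.random.Generator,
    lam: float | None = None,
) -> SyntheticSample:
    """Mix one sample pair by subtree exchange on their profiles.

    The mixed profile is the base sample's profile with the partner's
    (l_v, r_v) substituted at every exchanged node; abundances are rebuilt
    at the base sample's total. ``lam`` can be forced for testing.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.shape != (tree.n_leaves,):
        raise ValueError("sample vectors are not aligned to the tree leaves")
    if lam is None:
        lam = draw_mixing_weight(config.alpha, rng)
    profile_i = build_profile(xi, tree)
    profile_j = build_profile(xj, tree)
    exchanged = sample_exchange_set(tree, lam, rng)
    mixed = _mix_profiles(profile_i, profile_j, exchanged)
    if config.mode == "relative":
        mixed.total = 1.0
    abundance = _materialize(mixed, tree, config)
    label = lam * float(yi) + (1.0 - lam) * float(yj)
    return SyntheticSample(abundance, label, -1, -1, lam, frozenset(exchanged))


def _pairing(
    n: int, n_synth: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Base index cycles through the training set; partner drawn uniformly.

    A partner equal to its base is redrawn once to avoid pure duplicates.
    """
    bases: list[int] = []
    full, rem = divmod(n_synth, n)
    for _ in range(full):
        bases.extend(range(n))
    if rem:
        bases.extend(int(b) for b in rng.permutation(n)[:rem])
    pairs = []
    for i in bases:
        j = int(rng.integers(n))
        if j == i:
            j = int(rng.integers(n))
        pairs.append((i, j))
    return pairs


def phylomix_augment(
    dataset: LabeledDataset, tree: PhyloTree, config: AugmentConfig
) -> LabeledDataset:
    """Generate ``ceil(ratio * n)`` synthetic samples by subtree exchange.

    Returns only the synthetic part; provenance records (i, j, lam,
    exchanged set) per row. Deterministic under ``config.seed``.
    """
    n = dataset.n
    if n < 2:
        raise ValueError("need at least 2 samples to augment")
    if dataset.taxa != tree.taxa:
        raise ValueError("dataset taxa do not match tree leaf order")
    rng = np.random.default_rng(config.seed)
    n_synth = math.ceil(config.ratio * n)
    profiles = [build_profile(dataset.X[i], tree) for i in range(n)]
    rows = np.empty((n_synth, dataset.p))
    labels = np.empty(n_synth)
    provenance: list[SyntheticSample] = []
    for k, (i, j) in enumerate(_pairing(n, n_synth, rng)):
        lam = draw_mixing_weight(config.alpha, rng)
        exchanged = sample_exchange_set(tree, lam, rng)
        mixed = _mix_profiles(profiles[i], profiles[j], exchanged)
        if config.mode == "relative":
            mixed.total = 1.0
        rows[k] = _materialize(mixed, tree, config)
        labels[k] = lam * dataset.y[i] + (1.0 - lam) * dataset.y[j]
        provenance.append(
            SyntheticSample(rows[k], float(labels[k]), i, j, lam,
                            frozenset(exchanged))
        )
    return LabeledDataset(
        X=rows,
        y=labels,
        taxa=dataset.taxa,
        sample_ids=tuple(f"synth{k}" for k in range(n_synth)),
        mode=dataset.mode,
        provenance=provenance,
    )


def vanilla_mixup(
    dataset: LabeledDataset, config: AugmentConfig
) -> LabeledDataset:
    """Elementwise convex combination baseline, same pairing/lambda machinery."""
    n = dataset.n
    if n < 2:
        raise ValueError("need at least 2 samples to augment")
    rng = np.random.default_rng(config.seed)
    n_synth = math.ceil(config.ratio * n)
    rows = np.empty((n_synth, dataset.p))
    labels = np.empty(n_synth)
    provenance: list[SyntheticSample] = []
    for k, (i, j) in enumerate(_pairing(n, n_synth, rng)):
        lam = draw_mixing_weight(config.alpha, rng)
        rows[k] = lam * dataset.X[i] + (1.0 - lam) * dataset.X[j]
        labels[k] = lam * dataset.y[i] + (1.0 - lam) * dataset.y[j]
        provenance.append(
            SyntheticSample(rows[k], float(labels[k]), i, j, lam)
        )
    return LabeledDataset(
        X=rows,
        y=labels,
        taxa=dataset.taxa,
        sample_ids=tuple(f"synth{k}" for k in range(n_synth)),
        mode=dataset.mode,
        provenance=provenance,
    )
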