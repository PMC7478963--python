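"""Enumeration and ranking of subclone phylogenies.

Subclones are identified by their prevalence peaks, sorted descending.  A
rooted tree over them is valid when

* the root is the founder clone (the peak equal to the tumor purity),
* every parent's prevalence is at least its child's (children inherit the
  parent's SNVs, so fewer cells can carry the child's private mutations), and
* every node's own population fraction phi_j = rho_j - sum(children's rho)
  is non-negative (a clone's descendants live inside it).

All parent assignments satisfying these rules are enumerated exhaustively;
the descending chain is always among them.  Candidate trees are ranked by a
sign score rewarding edges whose child carries more SNVs than its parent
(mutation rates tend to accelerate as genome-stability pathways break down),
with deterministic tie-breaks: deeper trees first, then enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np

__all__ = [
    "MAX_SUBCLONES",
    "PhylogenyTree",
    "enumerate_trees",
    "chain_tree",
    "rank_trees",
    "ancestor_matrix",
]

#: enumeration is factorial in the clone count; real tumors stay well below this
MAX_SUBCLONES = 8

_PHI_TOL = 1e-9


@dataclass(frozen=True)
class PhylogenyTree:
    """Rooted subclone tree: ``parent[j]`` indexes j's parent (-1 at the root).

    ``rho`` are the subclone peak prevalences (descending), ``phi`` the
    per-node population fractions; phi sums to the tumor purity.
    """

    parent: tuple[int, ...]
    rho: tuple[float, ...]
    phi: tuple[float, ...]
    rank_score: float = 0.0

    @property
    def n_subclones(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.parent.index(-1)

    def children(self, node: int) -> list[int]:
        return [j for j, p in enumerate(self.parent) if p == node]

    def depth(self) -> int:
        """Longest root-to-leaf path length in edges."""
        depths = [0] * self.n_subclones
        for j in range(self.n_subclones):  # parents precede children (parent[j] < j)
            if self.parent[j] >= 0:
                depths[j] = depths[self.parent[j]] + 1
        return max(depths)


def _build_tree(parents: Sequence[int], rho: Sequence[float]) -> PhylogenyTree | None:
    child_sum = [0.0] * len(rho)
    for j, p in enumerate(parents):
        if p >= 0:
            child_sum[p] += rho[j]
    phi = [r - s for r, s in zip(rho, child_sum)]
    if any(f < -_PHI_TOL for f in phi):
        return None
    return PhylogenyTree(
        parent=tuple(parents),
        rho=tuple(float(r) for r in rho),
        phi=tuple(max(f, 0.0) for f in phi),
    )


def enumerate_trees(peaks: Sequence[float]) -> list[PhylogenyTree]:
    """All valid rooted trees over the subclone peaks (descending order).

    Each non-root node may attach to any node of larger prevalence, i.e. any
    lower index; candidate parent functions violating the non-negative
    population fraction constraint are excluded.
    """
    rho = [float(p) for p in peaks]
    C = len(rho)
    if C == 0:
        raise ValueError("cannot build a phylogeny without subclones")
    if C > MAX_SUBCLONES:
        raise ValueError(
            f"refusing to enumerate trees over {C} subclones (cap {MAX_SUBCLONES})"
        )
    if any(rho[i] <= rho[i + 1] for i in range(C - 1)):
        raise ValueError("peaks must be sorted strictly descending")

    if C == 1:
        return [PhylogenyTree(parent=(-1,), rho=(rho[0],), phi=(rho[0],))]

    trees: list[PhylogenyTree] = []
    for choice in product(*(range(i) for i in range(1, C))):
        tree = _build_tree((-1, *choice), rho)
        if tree is not None:
            trees.append(tree)
    return trees


def chain_tree(peaks: Sequence[float]) -> PhylogenyTree:
    """The descending chain, valid for any peak configuration."""
    rho = [float(p) for p in peaks]
    tree = _build_tree([-1] + list(range(len(rho) - 1)), rho)
    assert tree is not None
    return tree


def rank_trees(
    trees: Sequence[PhylogenyTree], snv_support: Sequence[int]
) -> list[PhylogenyTree]:
    """Order candidate trees, best first.

    Score = sum over edges of sign(snvs(child) - snvs(parent)): clones with
    more SNVs are expected lower in the hierarchy.  Ties prefer the deeper
    tree (the chain), then the original enumeration order.
    """
    support = np.asarray(snv_support, dtype=int)
    scored = []
    for order, tree in enumerate(trees):
        score = 0
        for j, p in enumerate(tree.parent):
            if p >= 0:
                score += int(np.sign(support[j] - support[p]))
        scored.append((-score, -tree.depth(), order, replace(tree, rank_score=float(score))))
    scored.sort(key=lambda item: item[:3])
    return [item[3] for item in scored]


def ancestor_matrix(tree: PhylogenyTree) -> np.ndarray:
    """Strict-ancestry indicator: A[i, j] = 1 iff i is an ancestor of j."""
    C = tree.n_subclones
    A = np.zeros((C, C), dtype=float)
    for j in range(C):
        p = tree.parent[j]
        while p >= 0:
            A[p, j] = 1.0
            p = tree.parent[p]
    return A
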