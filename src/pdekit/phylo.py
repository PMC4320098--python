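"""Desk-scale clade analysis on spacer-profile feature distances.

Instead of aligning hundreds of database sequences, subclass separability is
checked in the feature space the classifier actually uses: Euclidean distance
over the four variable inter-motif spacers (plus an optional weighted length
term), neighbor joining on the resulting matrix, and a purity score counting
how many subclasses come out monophyletic.

Neighbor joining is the classic Saitou-Nei agglomeration with deterministic
tie-breaking on the smallest (row, column) index pair; negative branch
lengths are clamped to zero as is standard practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .errors import InputError
from .motifs import SpacerProfile

VARIABLE_SPACERS = (1, 2, 3, 4)


def spacer_distance(
    a: SpacerProfile, b: SpacerProfile, length_weight: float = 0.1
) -> float:
    """Euclidean distance on the four variable spacers plus
    length_weight x |difference in sequence length|."""
    sq = sum(
        (a.spacers[i] - b.spacers[i]) ** 2 for i in VARIABLE_SPACERS
    )
    return math.sqrt(sq) + length_weight * abs(a.sequence_length - b.sequence_length)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", m)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if m.shape != (n, n):
            raise InputError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise InputError("duplicate labels")
        if not np.allclose(m, m.T):
            raise InputError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise InputError("diagonal must be zero")
        if np.any(m < -1e-12):
            raise InputError("distances must be non-negative")


def profile_distance_matrix(
    profiles: dict[str, SpacerProfile], length_weight: float = 0.1
) -> DistanceMatrix:
    """Pairwise spacer distances over a labelled set of profiles."""
    labels = tuple(profiles)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = spacer_distance(
                profiles[labels[i]], profiles[labels[j]], length_weight
            )
    return DistanceMatrix(labels, m)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) on a distance matrix.

    Returns an unrooted tree represented by a trifurcating root (standard
    unrooted-newick convention).  Ties in the Q criterion are broken on the
    smallest (i, j) pair in the current working order, so the result is
    deterministic.  Negative branch-length estimates are clamped to 0.
    """
    n = len(matrix.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")

    d = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in matrix.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        limb_i = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        limb_j = d[i, j] - limb_i
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(limb_i, 0.0)
        nodes[j].length = max(limb_j, 0.0)

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join: branch lengths solve the three-point equations
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = max(length, 0.0)
    return TreeNode(children=[a, b, c])


def tree_splits(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf-name sets under each edge of the (unrooted) tree, including the
    trivial single-leaf splits."""
    splits = []
    for node in tree.postorder(include_self=False):
        splits.append(frozenset(leaf.name for leaf in node.tips(include_self=True)))
    return splits


def cluster_purity(tree: TreeNode, labels: dict[str, str]) -> float:
    """Fraction of subclasses forming a monophyletic group in the tree.

    A subclass is monophyletic if some edge splits exactly its leaves from
    the rest (either side of the split counts, the tree being unrooted); a
    subclass covering all leaves or a single leaf is trivially monophyletic.
    """
    leaves = {leaf.name for leaf in tree.tips()}
    unlabeled = leaves - set(labels)
    if unlabeled:
        raise InputError(f"unlabeled leaves: {sorted(unlabeled)}")
    groups: dict[str, set[str]] = {}
    for leaf, lab in labels.items():
        if leaf in leaves:
            groups.setdefault(lab, set()).add(leaf)
    splits = {frozenset(s) for s in tree_splits(tree)}
    all_leaves = frozenset(leaves)
    mono = 0
    for members in groups.values():
        fs = frozenset(members)
        if len(fs) <= 1 or fs == all_leaves or fs in splits or (all_leaves - fs) in splits:
            mono += 1
    return mono / len(groups)
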