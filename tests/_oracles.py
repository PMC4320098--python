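"""Independent reference implementations used as test oracles.

Deliberately naive: exhaustive enumeration and least-squares topology search,
sharing no code with the package's scanner or NJ implementation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from pdekit.motifs import SignatureDefinition, interval_distance


def brute_force_scan(seq: str, signature: SignatureDefinition, max_spacer: int):
    """All minimal-penalty ordered placements by full enumeration.

    Returns a sorted list of (positions, penalty) exactly mirroring the
    scanner's contract.
    """
    seq = seq.upper()
    lens = signature.element_lengths
    occ = []
    for el in signature.elements:
        hits = [
            p
            for p in range(len(seq) - el.length + 1)
            if any(seq[p : p + el.length] == alt for alt in el.alternatives)
        ]
        occ.append(hits)
    results = []

    def recurse(i, positions):
        if i == 7:
            penalty = 0.0
            for t in range(6):
                spacer = positions[t + 1] - (positions[t] + lens[t])
                penalty += interval_distance(spacer, signature.spacer_bounds[t])
            results.append((tuple(positions), penalty))
            return
        for p in occ[i]:
            if positions:
                spacer = p - (positions[-1] + lens[i - 1])
                if spacer < 0:
                    continue
                if i - 1 in (0, 5):
                    if spacer != 1:
                        continue
                elif spacer > max_spacer:
                    continue
            recurse(i + 1, positions + [p])

    recurse(0, [])
    if not results:
        return []
    best = min(pen for _, pen in results)
    keep = sorted(
        [(pos, pen) for pos, pen in results if abs(pen - best) < 1e-9]
    )
    return keep


# ---------------------------------------------------------------------------
# unrooted-topology enumeration and least-squares branch fits


def enumerate_topologies(labels: list[str]):
    """Yield every unrooted binary topology over the labels as a networkx
    graph (leaves carry their label as node name; internal nodes are ints)."""
    n = len(labels)
    assert n >= 3
    base = nx.Graph()
    center = 0
    base.add_edges_from((center, lab) for lab in labels[:3])
    trees = [base]
    next_internal = 1
    for k in range(3, n):
        new_trees = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                inner = ("i", next_internal, k, u, v)
                t2.remove_edge(u, v)
                t2.add_edges_from([(u, inner), (inner, v), (inner, labels[k])])
                new_trees.append(t2)
        trees = new_trees
    yield from trees


def tree_split_set(graph: nx.Graph, labels: list[str]) -> frozenset:
    """Non-trivial bipartitions of a tree graph, each normalized to the side
    not containing labels[0]."""
    splits = set()
    n = len(labels)
    for u, v in graph.edges():
        g = graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(l for l in labels if l in comp)
        if labels[0] in side:
            side = frozenset(labels) - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return frozenset(splits)


def ls_topology_rss(graph: nx.Graph, labels: list[str], d: np.ndarray) -> float:
    """Residual of the best least-squares branch-length fit of matrix ``d``
    onto a fixed topology (branch lengths unconstrained)."""
    edges = list(graph.edges())
    eidx = {frozenset(e): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        path = nx.shortest_path(graph, labels[i], labels[j])
        for u, v in zip(path, path[1:]):
            A[row, eidx[frozenset((u, v))]] = 1.0
        y[row] = d[i, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


def best_ls_topology(labels: list[str], d: np.ndarray) -> frozenset:
    """Split set of the topology minimizing the least-squares residual."""
    best = None
    for g in enumerate_topologies(labels):
        rss = ls_topology_rss(g, labels, d)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, tree_split_set(g, labels))
    return best[1]


def random_additive_matrix(rng: np.random.Generator, labels: list[str]):
    """A random unrooted binary tree with branch lengths in [0.1, 1] and its
    exact leaf-to-leaf distance matrix; returns (split set, matrix)."""
    # random topology by random leaf insertion
    g = nx.Graph()
    g.add_edges_from((0, lab) for lab in labels[:3])
    next_internal = 1
    for k in range(3, len(labels)):
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        inner = ("i", next_internal)
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edges_from([(u, inner), (inner, v), (inner, labels[k])])
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nx.shortest_path_length(
                g, labels[i], labels[j], weight="weight"
            )
    return tree_split_set(g, labels), d


def skbio_split_set(tree, labels: list[str]) -> frozenset:
    """Non-trivial splits of a scikit-bio TreeNode, normalized as above."""
    n = len(labels)
    splits = set()
    for node in tree.postorder(include_self=False):
        side = frozenset(t.name for t in node.tips(include_self=True))
        if labels[0] in side:
            side = frozenset(labels) - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return frozenset(splits)
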