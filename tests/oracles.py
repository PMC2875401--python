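"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: brute-force
enumeration for Fitch parsimony and tree topologies, closed-form distance
evaluation, and direct path-length computation on trees.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# Simple independent tree structure (nested tuples; leaves are strings)
# ---------------------------------------------------------------------------


def brute_force_fitch(topology, leaf_states: dict[str, str], alphabet) -> int:
    """Minimum number of state changes over all internal labelings.

    ``topology`` is a nested tuple; internal nodes are tuples of children.
    """
    internals = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)

    collect(topology)

    edges = []  # (parent index or leaf name pairs)
    index = {id(n): i for i, n in enumerate(internals)}

    def edge_list(node):
        if isinstance(node, tuple):
            for c in node:
                edges.append((index[id(node)], c if isinstance(c, str) else index[id(c)]))
                edge_list(c)

    edge_list(topology)

    best = math.inf
    for labeling in itertools.product(alphabet, repeat=len(internals)):
        changes = 0
        for parent, child in edges:
            p_state = labeling[parent]
            c_state = leaf_states[child] if isinstance(child, str) else labeling[child]
            if p_state != c_state:
                changes += 1
        best = min(best, changes)
    return int(best)


def random_topology(labels, rng) -> tuple:
    """Random rooted binary topology over labels as nested tuples."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


# ---------------------------------------------------------------------------
# Unrooted topology enumeration + least-squares fit (NJ oracle)
# ---------------------------------------------------------------------------


class _N:
    __slots__ = ("name", "adj")

    def __init__(self, name=None):
        self.name = name
        self.adj: list["_N"] = []


def _link(a: _N, b: _N) -> None:
    a.adj.append(b)
    b.adj.append(a)


def _unlink(a: _N, b: _N) -> None:
    a.adj.remove(b)
    b.adj.remove(a)


def _copy_graph(nodes: list[_N]) -> list[_N]:
    clones = {id(n): _N(n.name) for n in nodes}
    for n in nodes:
        c = clones[id(n)]
        c.adj = [clones[id(m)] for m in n.adj]
    return list(clones.values())


def enumerate_unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies over the taxa, as (nodes, edges) graphs.

    Yields lists of `_N` nodes; edges are implicit in adjacency.
    """
    assert len(taxa) >= 3

    def build(current_nodes: list[_N], remaining: list[str]):
        if not remaining:
            yield current_nodes
            return
        label = remaining[0]
        # every edge = unordered adjacent pair
        edges = []
        seen = set()
        for n in current_nodes:
            for m in n.adj:
                key = frozenset({id(n), id(m)})
                if key not in seen:
                    seen.add(key)
                    edges.append((n, m))
        for a, b in edges:
            mid = _N()
            leaf = _N(label)
            _unlink(a, b)
            _link(a, mid)
            _link(mid, b)
            _link(mid, leaf)
            yield from build(current_nodes + [mid, leaf], remaining[1:])
            _unlink(a, mid)
            _unlink(mid, b)
            _unlink(mid, leaf)
            _link(a, b)

    center = _N()
    leaves = [_N(t) for t in taxa[:3]]
    for l in leaves:
        _link(center, l)
    for nodes in build([center] + leaves, list(taxa[3:])):
        yield _copy_graph(nodes)


def graph_bipartitions(nodes: list[_N]) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted graph, as frozensets of the
    side not containing the alphabetically smallest taxon."""
    taxa = sorted(n.name for n in nodes if n.name)
    ref = taxa[0]
    out = set()

    def leaves_beyond(n: _N, came_from: _N) -> set[str]:
        if n.name:
            return {n.name}
        acc = set()
        for m in n.adj:
            if m is not came_from:
                acc |= leaves_beyond(m, n)
        return acc

    for n in nodes:
        for m in n.adj:
            side = leaves_beyond(m, n)
            if len(side) < 2 or len(taxa) - len(side) < 2:
                continue
            if ref in side:
                side = set(taxa) - side
            out.add(frozenset(side))
    return out


def least_squares_fit(nodes: list[_N], dist: dict[frozenset, float]) -> float:
    """Non-negative least-squares branch-length fit; returns SSE."""
    edges = []
    seen = set()
    for n in nodes:
        for m in n.adj:
            key = frozenset({id(n), id(m)})
            if key not in seen:
                seen.add(key)
                edges.append((n, m))
    edge_index = {frozenset({id(a), id(b)}): k for k, (a, b) in enumerate(edges)}
    leaves = [n for n in nodes if n.name]

    def path_edges(a: _N, b: _N):
        # DFS path in a tree
        stack = [(a, None, [])]
        while stack:
            cur, prev, path = stack.pop()
            if cur is b:
                return path
            for m in cur.adj:
                if m is not prev:
                    stack.append(
                        (m, cur, path + [edge_index[frozenset({id(cur), id(m)})]])
                    )
        raise RuntimeError("no path")

    rows, target = [], []
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            row = np.zeros(len(edges))
            for e in path_edges(u, v):
                row[e] = 1.0
            rows.append(row)
            target.append(dist[frozenset({u.name, v.name})])
    A = np.array(rows)
    y = np.array(target)
    x, _ = nnls(A, y)
    resid = A @ x - y
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# Closed-form K2P evaluated via an independent expression
# ---------------------------------------------------------------------------


def k2p_reference(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    # algebraically equivalent but different evaluation path
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_variance(p: float, q: float, n: int) -> float:
    """Kimura (1980) sampling variance of the distance estimate."""
    c1 = 1.0 / (1.0 - 2.0 * p - q)
    c2 = 0.5 * (c1 + 1.0 / (1.0 - 2.0 * q))
    return (c1 * c1 * p + c2 * c2 * q - (c1 * p + c2 * q) ** 2) / n


# ---------------------------------------------------------------------------
# Path lengths on GeneTree objects (independent of tree_build internals)
# ---------------------------------------------------------------------------


def leaf_path_lengths(tree) -> dict[frozenset, float]:
    """All leaf-pair path lengths computed from scratch via root paths."""
    paths = {}

    def walk(node, acc):
        acc = acc + [(node, node.length or 0.0)]
        if node.is_leaf:
            paths[node.label] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    out = {}
    labels = list(paths)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pa, pb = paths[a], paths[b]
            shared = 0
            while (
                shared < len(pa) and shared < len(pb)
                and pa[shared][0] is pb[shared][0]
            ):
                shared += 1
            dist = sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])
            out[frozenset({a, b})] = dist
    return out
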