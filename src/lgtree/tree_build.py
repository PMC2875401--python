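"""Distance-based gene-tree construction.

Kimura two-parameter distances, Saitou-Nei neighbor joining with
deterministic tie-breaking, nonparametric bootstrap supports, and rooting
(as-given / midpoint / outgroup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import GeneTree, TreeNode

__all__ = [
    "AlignedPair",
    "DistanceMatrix",
    "SaturationError",
    "UndefinedDistanceError",
    "k2p_distance",
    "k2p_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_tree",
    "midpoint_root",
    "outgroup_root",
]

_NUCS = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance undefined: substitution saturation (log argument <= 0)."""


class UndefinedDistanceError(ValueError):
    """No comparable sites between the two sequences."""


@dataclass(frozen=True)
class AlignedPair:
    """Transition/transversion summary of one aligned sequence pair.

    Sites where either sequence carries a gap or ambiguity code are excluded
    (pairwise deletion).  P and Q are the proportions of compared sites that
    differ by a transition and a transversion, respectively.
    """

    p: float
    q: float
    sites: int

    def __post_init__(self) -> None:
        if self.sites < 0:
            raise ValueError("site count must be non-negative")
        if self.p < 0 or self.q < 0 or self.p + self.q > 1 + 1e-12:
            raise ValueError("P and Q must be non-negative with P + Q <= 1")

    @classmethod
    def from_sequences(cls, a: str, b: str) -> "AlignedPair":
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        sites = ts = tv = 0
        for x, y in zip(a.upper(), b.upper()):
            if x not in _NUCS or y not in _NUCS:
                continue
            sites += 1
            if x == y:
                continue
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
        if sites == 0:
            return cls(0.0, 0.0, 0)
        return cls(ts / sites, tv / sites, sites)


def k2p_distance(pair: AlignedPair) -> float:
    """Kimura (1980) two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    Raises :class:`SaturationError` when either log argument is non-positive
    and :class:`UndefinedDistanceError` when no sites were compared.
    """
    if pair.sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    w1 = 1.0 - 2.0 * pair.p - pair.q
    w2 = 1.0 - 2.0 * pair.q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitutions saturated (1-2P-Q={w1:.4g}, 1-2Q={w2:.4g})"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return max(d, 0.0)


class DistanceMatrix:
    """Symmetric non-negative distance matrix keyed by taxon names."""

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = len(taxa)
        if matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if len(set(taxa)) != n:
            raise ValueError("duplicate taxon names")
        if np.isnan(matrix).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")
        self.taxa = list(taxa)
        self.matrix = matrix

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def k2p_matrix(
    names: Sequence[str], seqs: Sequence[str], complete_deletion: bool = False
) -> DistanceMatrix:
    """Pairwise K2P distances for an alignment.

    With ``complete_deletion`` set, columns containing any gap/ambiguity in
    any sequence are dropped globally before the pairwise counts; the default
    is pairwise deletion.
    """
    seqs = [s.upper() for s in seqs]
    if complete_deletion:
        keep = [
            i for i in range(len(seqs[0])) if all(s[i] in _NUCS for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(AlignedPair.from_sequences(seqs[i], seqs[j]))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(names, mat)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> GeneTree:
    """Saitou & Nei (1987) neighbor joining.

    Deterministic: Q-criterion ties are broken by the lexicographically
    smallest (taxon, taxon) name pair, each cluster represented by its
    smallest member name.  Negative branch lengths are clamped to zero with
    the deficit moved to the sister branch unless ``clamp_negative`` is off.
    Output is unrooted (top-level trifurcation) for >= 3 taxa.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.taxa]
    reps: list[str] = list(dm.taxa)  # smallest leaf name per cluster, for ties
    d = dm.matrix.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key)
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the new cluster
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = ln
        root.add_child(nodes[idx])
    tree = GeneTree(root, rooted=False)
    tree.validate()
    return tree


def _nj_from_alignment(names: Sequence[str], seqs: Sequence[str]) -> GeneTree:
    return neighbor_joining(k2p_matrix(names, seqs))


def _canonical_splits(tree: GeneTree) -> set[frozenset[str]]:
    """Nontrivial splits, each named by the side not containing the smallest leaf."""
    all_leaves = sorted(tree.leaf_labels())
    ref = all_leaves[0]
    out = set()
    for bp in tree.bipartitions():
        for side in bp:
            if ref not in side:
                out.add(side)
    return out


def bootstrap_support(
    names: Sequence[str],
    seqs: Sequence[str],
    replicates: int = 100,
    seed: int | None = None,
) -> GeneTree:
    """NJ tree with bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal edge of the reference NJ tree is the percentage of
    replicate trees containing the same bipartition.  Deterministic for a
    fixed seed.
    """
    if len(names) < 4:
        raise ValueError("bootstrap support requires at least 4 sequences")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    length = len(seqs[0])
    if length == 0:
        raise ValueError("alignment has zero columns")
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")

    reference = _nj_from_alignment(names, seqs)
    counts: dict[frozenset[str], int] = {s: 0 for s in _canonical_splits(reference)}

    rng = np.random.default_rng(seed)
    arr = np.array([list(s.upper()) for s in seqs])
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        rep_seqs = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = _nj_from_alignment(names, rep_seqs)
        except (SaturationError, UndefinedDistanceError):
            continue  # replicate uninformative; counts unchanged
        for split in _canonical_splits(rep_tree):
            if split in counts:
                counts[split] += 1

    all_leaves = sorted(reference.leaf_labels())
    ref_leaf = all_leaves[0]
    for node in reference.postorder():
        if node.is_leaf or node.is_root:
            continue
        side = frozenset(node.leaf_labels())
        if ref_leaf in side:
            side = frozenset(all_leaves) - side
        if len(side) < 2 or len(frozenset(all_leaves) - side) < 2:
            continue
        node.support = 100.0 * counts.get(side, 0) / replicates
    return reference


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def _reroot_at_edge(tree: GeneTree, child: TreeNode, dist_from_child: float) -> GeneTree:
    """Place a new root on the edge above ``child``, ``dist_from_child`` away
    from it.  Supports travel with their edges (a support annotates the
    bipartition induced by the edge above the node carrying it).
    """
    old_parent = child.parent
    if old_parent is None:
        raise ValueError("cannot reroot on the root's (non-existent) edge")
    edge_len = child.length
    edge_sup = child.support if not child.is_leaf else None

    old_parent.remove_child(child)
    new_root = TreeNode()
    child.length = dist_from_child
    new_root.add_child(child)

    # Walk up from old_parent to the old root, flipping parent links.
    node = old_parent
    # length/support of the edge between `node` and the new root side
    carry_len = None if edge_len is None else edge_len - dist_from_child
    carry_sup = edge_sup
    attach_to = new_root
    while node is not None:
        next_parent = node.parent
        next_len = node.length
        next_sup = node.support
        if next_parent is not None:
            next_parent.remove_child(node)
        node.length = carry_len
        node.support = carry_sup
        attach_to.add_child(node)
        attach_to = node
        node = next_parent
        carry_len, carry_sup = next_len, next_sup

    # Suppress any unifurcation left where the old root used to be.
    changed = True
    while changed:
        changed = False
        for n in list(new_root.postorder()):
            if n.is_leaf or n.is_root or len(n.children) != 1:
                continue
            only = n.children[0]
            parent = n.parent
            if only.length is not None or n.length is not None:
                only.length = (only.length or 0.0) + (n.length or 0.0)
            if only.support is None:
                only.support = n.support
            n.remove_child(only)
            idx = parent.children.index(n)
            parent.remove_child(n)
            parent.children.insert(idx, only)
            only.parent = parent
            changed = True
    result = GeneTree(new_root, rooted=True)
    result.validate()
    return result


def _leaf_depths(tree: GeneTree) -> dict[str, float]:
    depths: dict[str, float] = {}

    def walk(node: TreeNode, acc: float) -> None:
        acc += node.length or 0.0
        if node.is_leaf:
            depths[node.label] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, -(tree.root.length or 0.0))
    return depths


def _path_between(a: TreeNode, b: TreeNode) -> list[TreeNode]:
    seen = {id(a)}
    up_a = [a]
    node = a
    while node.parent is not None:
        node = node.parent
        up_a.append(node)
        seen.add(id(node))
    up_b = [b]
    node = b
    while id(node) not in seen:
        node = node.parent
        up_b.append(node)
    lca = node
    path = up_a[: [id(x) for x in up_a].index(id(lca)) + 1]
    path += list(reversed(up_b[:-1]))
    return path


def midpoint_root(tree: GeneTree) -> GeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    work = tree.copy()
    leaves = work.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")

    # pairwise distances via two passes would do; tree sizes here are small
    best = (-1.0, None, None)
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            path = _path_between(u, v)
            dist = 0.0
            for k in range(len(path) - 1):
                lower = path[k] if path[k].parent is path[k + 1] else path[k + 1]
                dist += lower.length or 0.0
            if dist > best[0]:
                best = (dist, u, v)
    diameter, u, v = best
    target = diameter / 2.0
    path = _path_between(u, v)
    acc = 0.0
    for k in range(len(path) - 1):
        a, b = path[k], path[k + 1]
        lower = a if a.parent is b else b
        seg = lower.length or 0.0
        if acc + seg >= target - 1e-12:
            within = target - acc
            # `lower` is the child side of the edge; we entered the edge at
            # `a`'s end, so the midpoint is `within` past `a`.
            if lower is a:
                dfc = within
            else:
                dfc = seg - within
            return _reroot_at_edge(work, lower, dfc)
        acc += seg
    # numerical fallthrough: root on the last edge
    lower = path[-2] if path[-2].parent is path[-1] else path[-1]
    return _reroot_at_edge(work, lower, (lower.length or 0.0) / 2.0)


def outgroup_root(tree: GeneTree, outgroup: str) -> GeneTree:
    """Root on the outgroup leaf's edge (split at its midpoint)."""
    work = tree.copy()
    try:
        leaf = work.find_leaf(outgroup)
    except KeyError:
        raise ValueError(f"outgroup taxon {outgroup!r} is not a leaf of the tree")
    half = (leaf.length or 0.0) / 2.0
    return _reroot_at_edge(work, leaf, half)


def root_tree(tree: GeneTree, policy: str = "midpoint") -> GeneTree:
    """Apply a rooting policy: ``as-given``, ``midpoint`` or ``outgroup:<taxon>``."""
    if policy == "as-given":
        out = tree.copy()
        out.rooted = True
        return out
    if policy == "midpoint":
        return midpoint_root(tree)
    if policy.startswith("outgroup:"):
        return outgroup_root(tree, policy.split(":", 1)[1])
    raise ValueError(f"unknown rooting policy {policy!r}")
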