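"""Synthetic alignments with known true trees (JC69 evolution).

Every other module is testable without external data: a root sequence is
drawn i.i.d. uniform over {A,C,G,T} and evolved down a tree under the
Jukes–Cantor model, where a branch of length ``t`` expected substitutions
per site changes each site independently with probability

    p_change = (3/4) (1 - exp(-4 t / 3)),

the changed site moving to one of the three other bases uniformly.  The
expected p-distance between two leaves at path length ``t`` is the same
closed form — the calibration the tests check.

``caterpillar_tree`` builds the ladder shape ((((1,2),3),4),...) that the
empirical MHC trees approximate; ``random_rooted_tree`` gives arbitrary
binary shapes for property tests; ``additive_distance_matrix`` turns any
tree with branch lengths into the exactly additive matrix NJ must invert.
"""

from __future__ import annotations

import itertools

import numpy as np

from .alignment import Alignment
from .distance import DistanceMatrix
from .errors import ValidationError
from .tree import Node, Tree

_BASES = "ACGT"


def caterpillar_tree(
    n_leaves: int,
    internal_len: float = 0.05,
    terminal_len: float = 0.05,
    names=None,
) -> Tree:
    """Rooted ladder topology ((((1,2),3),4),...) on ``n_leaves`` leaves."""
    if n_leaves < 4:
        raise ValidationError("caterpillar needs at least 4 leaves")
    if names is None:
        names = [f"t{i}" for i in range(1, n_leaves + 1)]
    names = list(names)
    if len(names) != n_leaves:
        raise ValidationError("names length does not match n_leaves")
    node = Node(children=[
        Node(names[0], length=terminal_len),
        Node(names[1], length=terminal_len),
    ])
    for name in names[2:-1]:
        node.length = internal_len
        node = Node(children=[node, Node(name, length=terminal_len)])
    node.length = internal_len
    root = Node(children=[node, Node(names[-1], length=terminal_len)])
    return Tree(root, rooted=True)


def random_rooted_tree(
    names,
    rng: np.random.Generator,
    min_len: float = 0.05,
    max_len: float = 1.0,
) -> Tree:
    """Random rooted binary tree by random sequential pair joins."""
    names = list(names)
    if len(names) < 3:
        raise ValidationError("random tree needs at least 3 leaves")
    clusters = [Node(name) for name in names]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(int(j))
        a = clusters.pop(int(i))
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        clusters.append(Node(children=[a, b]))
    return Tree(clusters[0], rooted=True)


def simulate_alignment(tree: Tree, n_sites: int, seed: int = 0) -> Alignment:
    """Evolve a JC69 alignment down ``tree``; deterministic given ``seed``.

    Taxa appear in the tree's preorder leaf order.  All branch lengths must
    be nonnegative; length ``None`` is treated as 0.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be at least 1")
    for node in tree.iter_nodes():
        if node.length is not None and node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} in simulation tree"
            )
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    names: list[str] = []
    rows: list[str] = []

    def evolve(node: Node, seq: np.ndarray) -> None:
        t = node.length or 0.0
        if node is not tree.root and t > 0:
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            mask = rng.random(n_sites) < p_change
            n_hit = int(mask.sum())
            if n_hit:
                seq = seq.copy()
                seq[mask] = (
                    seq[mask] + rng.integers(1, 4, size=n_hit, dtype=np.int8)
                ) % 4
        if node.is_leaf:
            names.append(node.name)
            rows.append("".join(_BASES[b] for b in seq))
            return
        for child in node.children:
            evolve(child, seq)

    evolve(tree.root, root_seq)
    return Alignment(tuple(names), tuple(rows))


def additive_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Exact leaf-to-leaf path-length matrix of a tree with branch lengths."""

    dist: dict[tuple[str, str], float] = {}
    order: list[str] = []

    def rec(node: Node) -> dict[str, float]:
        if node.is_leaf:
            order.append(node.name)
            return {node.name: node.length or 0.0}
        child_maps = [rec(c) for c in node.children]
        for (ma, mb) in itertools.combinations(child_maps, 2):
            for la, da in ma.items():
                for lb, db in mb.items():
                    key = (la, lb) if la < lb else (lb, la)
                    dist[key] = da + db
        merged: dict[str, float] = {}
        for m in child_maps:
            merged.update(m)
        t = node.length or 0.0
        if node is not tree.root and t:
            merged = {k: v + t for k, v in merged.items()}
        return merged

    rec(tree.root)
    n = len(order)
    D = np.zeros((n, n))
    for i, a in enumerate(order):
        for j in range(i + 1, n):
            b = order[j]
            key = (a, b) if a < b else (b, a)
            D[i, j] = D[j, i] = dist[key]
    return DistanceMatrix(tuple(order), D)
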