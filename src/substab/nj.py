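"""Neighbor-joining tree construction (the "NJ" of NJp).

Standard Saitou–Nei agglomeration with the Studier–Keppler criterion
Q(i,j) = (r-2) d(i,j) - R(i) - R(j).  Ties in Q are broken by the
lexicographically smallest pair of active-cluster indices (creation order),
so runs are deterministic across platforms.  Negative estimated branch
lengths are clamped to zero in the returned tree; the topology is whatever
the Q criterion selected.

``nj_topology_ids`` is the hot path used by the bootstrap: it runs the same
core but returns only the canonical split set (frozensets of leaf indices,
each the side not containing index 0), skipping Node construction.
"""

from __future__ import annotations

import numpy as np

from .distance import DistanceMatrix
from .errors import ValidationError
from .tree import Node, Tree, bipartitions

_SYM_TOL = 1e-12


def _check_square_symmetric(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    if not np.isfinite(D).all():
        raise ValidationError("distance matrix contains non-finite values")
    if np.abs(D - D.T).max(initial=0.0) > _SYM_TOL:
        raise ValidationError(
            f"distance matrix asymmetric beyond tolerance {_SYM_TOL}"
        )


def _nj_core(D: np.ndarray):
    """Run the agglomeration; return (joins, final_ids, final_lengths).

    ``joins`` is a list of ``(id_i, id_j, v_i, v_j, new_id)`` in join order;
    original taxa hold ids ``0..n-1`` and new clusters are numbered onward.
    ``final_ids`` are the last three clusters, joined at the center vertex
    with the three-point branch lengths ``final_lengths``.
    """
    n = D.shape[0]
    work = D.astype(float).copy()
    ids = list(range(n))
    nxt = n
    joins = []
    while len(ids) > 3:
        r = len(ids)
        R = work.sum(axis=1)
        Q = (r - 2) * work - R[:, None] - R[None, :]
        iu = np.triu_indices(r, 1)
        # np.argmin returns the first minimum in row-major upper-triangle
        # order, i.e. the lexicographically smallest (i, j) among ties.
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = work[i, j]
        vi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        vj = dij - vi
        joins.append((ids[i], ids[j], vi, vj, nxt))
        new = 0.5 * (work[i, :] + work[j, :] - dij)
        keep = [p for p in range(r) if p != i and p != j]
        nw = np.empty((r - 1, r - 1))
        nw[: r - 2, : r - 2] = work[np.ix_(keep, keep)]
        nw[: r - 2, r - 2] = nw[r - 2, : r - 2] = new[keep]
        nw[r - 2, r - 2] = 0.0
        ids = [ids[p] for p in keep] + [nxt]
        nxt += 1
        work = nw
    d01, d02, d12 = work[0, 1], work[0, 2], work[1, 2]
    final_lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    return joins, tuple(ids), final_lengths


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Unrooted NJ tree on ``dm.taxa`` with estimated branch lengths.

    ``n = 3`` returns the unique star; fewer taxa is an error.
    """
    D = np.asarray(dm.d, dtype=float)
    _check_square_symmetric(D)
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    joins, final_ids, final_lengths = _nj_core(D)
    nodes: dict[int, Node] = {i: Node(name=dm.taxa[i]) for i in range(n)}
    for id_i, id_j, vi, vj, new_id in joins:
        a, b = nodes[id_i], nodes[id_j]
        a.length = max(float(vi), 0.0)
        b.length = max(float(vj), 0.0)
        nodes[new_id] = Node(children=[a, b])
    center = Node()
    for cid, length in zip(final_ids, final_lengths):
        child = nodes[cid]
        child.length = max(float(length), 0.0)
        center.children.append(child)
    return Tree(center, rooted=False)


def nj_topology_ids(D: np.ndarray) -> frozenset[frozenset[int]]:
    """Canonical split set of the NJ tree on a raw distance matrix.

    Each split is represented by its side not containing leaf index 0;
    n < 4 yields the empty set (no internal branches).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 4:
        return frozenset()
    joins, _, _ = _nj_core(D)
    sets: dict[int, frozenset[int]] = {i: frozenset((i,)) for i in range(n)}
    full = frozenset(range(n))
    out = []
    for id_i, id_j, _, _, new_id in joins:
        union = sets[id_i] | sets[id_j]
        sets[new_id] = union
        out.append(union if 0 not in union else full - union)
    return frozenset(out)


def topology_ids_from_tree(tree: Tree, taxa_order) -> frozenset[frozenset[int]]:
    """Canonical split set of an existing tree, in ``taxa_order`` indices.

    Comparable with :func:`nj_topology_ids` output for a distance matrix
    whose rows follow ``taxa_order``.
    """
    taxa_order = list(taxa_order)
    index = {name: i for i, name in enumerate(taxa_order)}
    if tree.leaf_names() != frozenset(taxa_order):
        raise ValidationError("taxa_order does not match the tree's leaves")
    out = set()
    for split in bipartitions(tree):
        side = split.side_a if taxa_order[0] not in split.side_a else split.side_b
        out.add(frozenset(index[t] for t in side))
    return frozenset(out)
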