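"""Independent oracles used by the test suite.

Everything here is deliberately implemented without touching the package's
own inference code paths: a column-by-column p-distance counter, an
exhaustive enumeration of unrooted topologies with a least-squares branch
fit (the gold standard NJ is checked against), and a Robinson–Foulds
comparison through dendropy.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from scipy.optimize import nnls

MISSING = set("-NRYSWKMBDHV")


def brute_p_distance(a: str, b: str) -> tuple[float, int]:
    """Pairwise-deletion p-distance by naive per-column counting."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    diff = m = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        m += 1
        if x != y:
            diff += 1
    return (diff / m if m else float("nan")), m


# ---------------------------------------------------------------------------
# Exhaustive unrooted-topology enumeration + least-squares fit
# ---------------------------------------------------------------------------
# An unrooted binary topology is a nested-tuple structure: the top level is
# a 3-tuple of subtrees, every internal subtree is a 2-tuple, leaves are
# names.

def _insertion_points(subtree, path):
    yield path
    if isinstance(subtree, tuple):
        for i, child in enumerate(subtree):
            yield from _insertion_points(child, path + (i,))


def _replace(tree, path, new):
    if not path:
        return new
    i = path[0]
    return tuple(
        _replace(c, path[1:], new) if j == i else c
        for j, c in enumerate(tree)
    )


def enumerate_unrooted_topologies(names):
    """All (2n-5)!! unrooted binary topologies on ``names``."""
    names = list(names)
    assert len(names) >= 3
    trees = [(names[0], names[1], names[2])]
    for name in names[3:]:
        new_trees = []
        for tree in trees:
            for i, top in enumerate(tree):
                for path in _insertion_points(top, (i,)):
                    old = tree
                    sub = old
                    for p in path:
                        sub = sub[p]
                    new_trees.append(_replace(old, path, (sub, name)))
        trees = new_trees
    return trees


def _edge_leafsets(tree):
    """Leafset below every edge (pendant edges included)."""
    out = []

    def rec(subtree):
        if not isinstance(subtree, tuple):
            leaves = frozenset((subtree,))
        else:
            leaves = frozenset().union(*(rec(c) for c in subtree))
        out.append(leaves)
        return leaves

    for top in tree:
        rec(top)
    out = [s for s in out]
    # the whole-tree set appears once per top-level subtree only if the
    # recursion returned it; top-level calls already exclude the root.
    return out


def topology_splits(tree, names):
    """Canonical nontrivial split set (index form, side without names[0])."""
    index = {t: i for i, t in enumerate(names)}
    full = frozenset(names)
    out = set()
    for s in _edge_leafsets(tree):
        if 2 <= len(s) <= len(full) - 2:
            side = s if names[0] not in s else full - s
            out.add(frozenset(index[t] for t in side))
    return frozenset(out)


def least_squares_residual(tree, names, D):
    """Residual of the best nonnegative least-squares branch fit."""
    names = list(names)
    index = {t: i for i, t in enumerate(names)}
    leafsets = _edge_leafsets(tree)
    pairs = list(itertools.combinations(names, 2))
    A = np.zeros((len(pairs), len(leafsets)))
    for p, (a, b) in enumerate(pairs):
        for e, s in enumerate(leafsets):
            if (a in s) != (b in s):
                A[p, e] = 1.0
    dvec = np.array([D[index[a], index[b]] for a, b in pairs])
    _, resid = nnls(A, dvec)
    return resid


def ls_best_topology(names, D):
    """Split set of the exhaustive least-squares-best unrooted topology."""
    best = None
    best_resid = None
    for tree in enumerate_unrooted_topologies(names):
        resid = least_squares_residual(tree, names, D)
        if best_resid is None or resid < best_resid - 1e-12:
            best_resid = resid
            best = tree
    return topology_splits(best, list(names))


# ---------------------------------------------------------------------------
# Robinson–Foulds through dendropy
# ---------------------------------------------------------------------------

def rf_distance(newick1: str, newick2: str) -> int:
    """Unrooted Robinson–Foulds distance between two Newick strings."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    t2 = dendropy.Tree.get(data=newick2, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)
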