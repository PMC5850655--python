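"""Tree structures and topology algebra.

Trees are leaf-labelled and binary: an unrooted tree is stored with one
degree-3 (or higher, for the 3-leaf star) "center" vertex at the top; a
rooted tree has a degree-2 root.  Branch lengths and internal-node labels
are optional.

Topology identity is split-set identity: every internal branch of an
unrooted binary tree corresponds to exactly one nontrivial bipartition
(:class:`Split`) of the leaf set, and two trees on the same leaves have the
same topology iff their split sets coincide (Robinson–Foulds distance 0).

Newick parsing is delegated to dendropy; writing is done here so that the
annotated "Pb|Ps" dialect and byte-level determinism of the output are under
the package's control.
"""

from __future__ import annotations

import itertools
import re
from collections import defaultdict
from dataclasses import dataclass

import dendropy

from .errors import MissingTaxonError, NewickParseError, ValidationError


class Node:
    """A vertex: leaves carry ``name``, internal nodes may carry ``label``."""

    __slots__ = ("name", "children", "length", "label")

    def __init__(self, name=None, children=None, length=None, label=None):
        self.name = name
        self.children: list[Node] = list(children) if children else []
        self.length = length
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.name, [c.copy() for c in self.children],
                    self.length, self.label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.name!r})"
        return f"Node({len(self.children)} children)"


@dataclass
class Tree:
    """A rooted (degree-2 root) or unrooted (degree->=3 center) binary tree."""

    root: Node
    rooted: bool = False

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def iter_nodes(self):
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_leaves(self):
        for node in self.iter_nodes():
            if node.is_leaf:
                yield node

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.iter_leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.iter_leaves())


@dataclass(frozen=True, order=True)
class Split:
    """A canonical bipartition of the leaf set (smaller-sorting side first)."""

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def of(cls, a, b) -> "Split":
        sa, sb = tuple(sorted(a)), tuple(sorted(b))
        if not sa or not sb:
            raise ValidationError("both sides of a split must be nonempty")
        if set(sa) & set(sb):
            raise ValidationError("split sides must be disjoint")
        if sb < sa:
            sa, sb = sb, sa
        return cls(sa, sb)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def __str__(self) -> str:
        return ",".join(self.side_a) + "|" + ",".join(self.side_b)


def bipartitions(tree: Tree) -> frozenset[Split]:
    """The set of nontrivial splits, one per internal branch.

    An unrooted binary tree on n leaves yields exactly ``n - 3`` splits; a
    rooted one yields the same set (the two root-child edges are the same
    unrooted branch and collapse under canonicalisation).
    """
    names = tree.leaf_names()
    n = len(names)
    out: set[Split] = set()
    if n < 4:
        return frozenset()

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.name,))
        below = frozenset(itertools.chain.from_iterable(rec(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= n - 2:
            out.add(Split.of(below, names - below))
        return below

    rec(tree.root)
    return frozenset(out)


def same_topology(t1: Tree, t2: Tree) -> bool:
    """True iff the two trees share the same unrooted topology.

    Branch lengths, child order and rooting are ignored; leaf sets must be
    identical.
    """
    if t1.leaf_names() != t2.leaf_names():
        raise ValidationError("trees have different leaf sets")
    return bipartitions(t1) == bipartitions(t2)


def _merge_len(a, b):
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _adjacency(tree: Tree):
    """Undirected view: ``(info, adj)`` over integer node ids.

    ``info[id] = (name, label)``; ``adj[id] = [(neighbor_id, edge_length)]``.
    A degree-2 root is suppressed so rooted and unrooted trees map to the
    same underlying graph.
    """
    info: dict[int, tuple] = {}
    adj: dict[int, list] = defaultdict(list)
    counter = itertools.count()

    def rec(node: Node) -> int:
        nid = next(counter)
        info[nid] = (node.name, node.label)
        for child in node.children:
            cid = rec(child)
            adj[nid].append((cid, child.length))
            adj[cid].append((nid, child.length))
        return nid

    rid = rec(tree.root)
    if tree.rooted and len(tree.root.children) == 2:
        (a, la), (b, lb) = adj[rid]
        merged = _merge_len(la, lb)
        adj[a] = [e for e in adj[a] if e[0] != rid] + [(b, merged)]
        adj[b] = [e for e in adj[b] if e[0] != rid] + [(a, merged)]
        del adj[rid]
    return info, adj


def _orient(info, adj, nid: int, parent: int | None) -> Node:
    name, label = info[nid]
    node = Node(name=name, label=label)
    for cid, length in adj[nid]:
        if cid == parent:
            continue
        child = _orient(info, adj, cid, nid)
        child.length = length
        node.children.append(child)
    return node


def root_at(tree: Tree, outgroup: str) -> Tree:
    """Root the tree on the branch leading to the ``outgroup`` leaf.

    The pendant edge is bisected; the returned tree has a degree-2 root
    whose children are the outgroup leaf and the rest of the tree.
    """
    if outgroup not in tree.leaf_names():
        raise MissingTaxonError(f"outgroup {outgroup!r} is not a leaf of the tree")
    if tree.n_leaves < 3:
        raise ValidationError("rooting needs at least 3 leaves")
    info, adj = _adjacency(tree)
    leaf_id = next(
        nid for nid, (name, _) in info.items()
        if name == outgroup and nid in adj and len(adj[nid]) == 1
    )
    nb, length = adj[leaf_id][0]
    half = None if length is None else length / 2.0
    out_leaf = Node(name=outgroup, length=half, label=info[leaf_id][1])
    rest = _orient(info, adj, nb, leaf_id)
    rest.length = half
    return Tree(Node(children=[out_leaf, rest]), rooted=True)


def unroot(tree: Tree) -> Tree:
    """Canonical unrooted form (degree->=3 center vertex)."""
    if not tree.rooted:
        return tree.copy()
    if tree.n_leaves < 3:
        raise ValidationError("unrooted form needs at least 3 leaves")
    info, adj = _adjacency(tree)
    center = next(nid for nid in sorted(adj) if len(adj[nid]) >= 3)
    root = _orient(info, adj, center, None)
    root.length = None
    return Tree(root, rooted=False)


def induced_subtree(tree: Tree, taxa) -> Tree:
    """The unrooted tree restricted to ``taxa``.

    Other leaves are pruned and degree-2 vertices suppressed (their edge
    lengths summed); the resulting split set is the restriction of the
    original split set to ``taxa``.
    """
    keep = set(taxa)
    names = tree.leaf_names()
    missing = keep - names
    if missing:
        raise MissingTaxonError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 3:
        raise ValidationError("induced subtree needs at least 3 taxa")

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, length=node.length)
            return None
        kids = [p for c in node.children if (p := prune(c)) is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            only.length = _merge_len(only.length, node.length)
            return only
        return Node(children=kids, length=node.length, label=node.label)

    top = prune(tree.root)
    while top is not None and len(top.children) == 1:
        top = top.children[0]
    top.length = None
    sub = Tree(top, rooted=(len(top.children) == 2))
    return unroot(sub) if sub.rooted else sub


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (dendropy-backed).

    Internal node labels (e.g. support values or the annotated ``Pb|Ps``
    dialect) are preserved on ``Node.label``.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"invalid newick: {exc}") from None

    def conv(dn) -> Node:
        if not dn.child_nodes():
            name = dn.taxon.label if dn.taxon is not None else dn.label
            node = Node(name=name)
        else:
            node = Node(label=dn.label,
                        children=[conv(c) for c in dn.child_nodes()])
        node.length = dn.edge.length
        return node

    root = conv(dt.seed_node)
    root.length = None
    if root.is_leaf:
        raise NewickParseError("newick describes a single leaf, not a tree")
    return Tree(root, rooted=(len(root.children) == 2))


def _quote(name: str) -> str:
    if name and not _NEEDS_QUOTE.search(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def format_percent(value: float) -> str:
    """Compact display form of a support percentage (97.0 -> ``97``)."""
    return f"{round(value, 6):g}"


def write_newick(
    tree: Tree,
    annotation: str = "none",
    pb: dict | None = None,
    ps: dict | None = None,
) -> str:
    """Serialise the tree to Newick.

    ``annotation='pb'`` writes each internal branch's bootstrap probability
    as the internal-node label; ``'pb_ps'`` writes ``Pb|Ps`` with ``NA``
    where the subtree stability is undefined.  Supports are looked up by the
    node's :class:`Split` in the ``pb``/``ps`` mappings.
    """
    if annotation not in ("none", "pb", "pb_ps"):
        raise ValidationError(f"unknown annotation mode {annotation!r}")
    names = tree.leaf_names()
    n = len(names)
    pb = pb or {}
    ps = ps or {}

    def label_for(below: frozenset[str], node: Node) -> str:
        if annotation == "none":
            return node.label or ""
        if not (2 <= len(below) <= n - 2):
            return node.label or ""
        split = Split.of(below, names - below)
        pbv = pb.get(split)
        if pbv is None:
            return node.label or ""
        if annotation == "pb":
            return format_percent(pbv)
        psv = ps.get(split)
        return format_percent(pbv) + "|" + (
            "NA" if psv is None else format_percent(psv)
        )

    def rec(node: Node) -> tuple[str, frozenset[str]]:
        length = "" if node.length is None else f":{node.length:.10g}"
        if node.is_leaf:
            return _quote(node.name) + length, frozenset((node.name,))
        parts, sets = zip(*(rec(c) for c in node.children))
        below = frozenset(itertools.chain.from_iterable(sets))
        text = "(" + ",".join(parts) + ")"
        label = "" if node is tree.root else label_for(below, node)
        if label:
            text += label if not _NEEDS_QUOTE.search(label) else _quote(label)
        return text + length, below

    text, _ = rec(tree.root)
    return text + ";"
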