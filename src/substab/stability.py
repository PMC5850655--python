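"""Subtree stability (Ps): the clade + closest-outgroup bootstrap.

High branch support (Pb) measures only how often one bipartition recurs;
it says nothing about whether the internal structure of the clade below
that branch is stable.  The subtree stability of a clade asks exactly
that: bootstrap the clade's sequences together with one *closest outgroup*
(a leaf of the clade's sister group), rebuild the NJ tree on that subset
each replicate, and count the replicates whose unrooted subset topology is
identical to the original subtree — the induced subtree of the originally
inferred full tree.  With ``s`` matches out of ``N`` replicates,

    Ps = (s / N) x 100%.

When the sister group offers several outgroup candidates, Ps is computed
once per candidate (with independent, deterministically derived random
streams) and the unweighted arithmetic mean is reported.

Ps is undefined for two-leaf clades (two sequences always produce the same
tree) and for clades whose parent is the root: such a clade corresponds to
the root leaf's pendant edge, which is no interior branch at all, so there
is no closest outgroup to test against ("NA:no-outgroup").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import replicate_rng, stream_tokens
from .alignment import Alignment
from .bootstrap import _replicate_weights, check_replicates
from .distance import DistanceMatrix, SiteData, replicate_distance
from .errors import MissingTaxonError, ValidationError
from .nj import nj_topology_ids, topology_ids_from_tree
from .tree import Node, Split, Tree, induced_subtree

logger = logging.getLogger("substab")

_PS_STREAM_TAG = "ps"


@dataclass(frozen=True)
class CladeRecord:
    """One internal vertex (below the root) of the rooted inferred tree.

    ``sister_taxa`` is the closest-outgroup candidate pool: the leaves of
    the other child of the clade's parent.  It is empty when the parent is
    the root (no interior branch defines such a clade).
    """

    clade_taxa: frozenset[str]
    sister_taxa: frozenset[str]
    defining_branch: Split

    @property
    def ps_eligible(self) -> bool:
        return len(self.clade_taxa) >= 3 and bool(self.sister_taxa)

    @property
    def status(self) -> str:
        if len(self.clade_taxa) < 3:
            return "NA:two-taxa"
        if not self.sister_taxa:
            return "NA:no-outgroup"
        return "ok"


@dataclass(frozen=True)
class OutgroupResult:
    """Ps of one clade tested against one closest-outgroup candidate."""

    outgroup: str
    s: int
    n: int
    ps: float


@dataclass
class StabilityResult:
    """Per-clade stability: one entry per outgroup candidate plus the mean."""

    clade: CladeRecord
    per_outgroup: list[OutgroupResult]
    ps_mean: float | None

    @property
    def n_replicates(self) -> int | None:
        return self.per_outgroup[0].n if self.per_outgroup else None


def enumerate_clades(rooted: Tree) -> list[CladeRecord]:
    """All clades (internal vertices below the root) of a rooted tree.

    Ordered by increasing clade size, then lexicographically by members.
    """
    if not rooted.rooted:
        raise ValidationError(
            "clade enumeration needs a rooted tree; call root_at() first"
        )
    names = rooted.leaf_names()
    if len(names) < 4:
        raise ValidationError("clade enumeration needs at least 4 leaves")
    records: list[CladeRecord] = []

    def leafset(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.name,))
        return frozenset().union(*(leafset(c) for c in node.children))

    def walk(node: Node, parent_is_root: bool, sister: frozenset[str]) -> None:
        below = leafset(node)
        if not node.is_leaf:
            records.append(
                CladeRecord(
                    clade_taxa=below,
                    sister_taxa=frozenset() if parent_is_root else sister,
                    defining_branch=Split.of(below, names - below),
                )
            )
        for child in node.children:
            others = below - leafset(child)
            walk(child, node is rooted.root, others)

    for child in rooted.root.children:
        others = names - leafset(child)
        walk(child, True, others)
    records.sort(key=lambda r: (len(r.clade_taxa), tuple(sorted(r.clade_taxa))))
    return records


def closest_outgroups(rec: CladeRecord) -> list[str]:
    """The clade's closest-outgroup candidates: its sister group's leaves."""
    return sorted(rec.sister_taxa)


def _subset_context(aln: Alignment, full_tree: Tree, rec: CladeRecord,
                    outgroup: str, site_data: SiteData):
    subset = set(rec.clade_taxa) | {outgroup}
    missing = subset - set(aln.taxa)
    if missing:
        raise MissingTaxonError(f"taxa not in alignment: {sorted(missing)}")
    taxa_sub = [t for t in aln.taxa if t in subset]
    rows = [aln.taxa.index(t) for t in taxa_sub]
    reference = induced_subtree(full_tree, subset)
    ref_key = topology_ids_from_tree(reference, taxa_sub)
    M, V = site_data.pair_data(rows)
    return taxa_sub, M, V, ref_key


def ps_single_outgroup(
    aln: Alignment,
    full_tree: Tree,
    rec: CladeRecord,
    outgroup: str,
    replicates: int = 1000,
    seed: int = 0,
    *,
    deletion: str = "complete",
    identity_bootstrap: bool = False,
    site_data: SiteData | None = None,
) -> OutgroupResult:
    """Ps of ``rec`` using one closest-outgroup candidate.

    Every replicate resamples the (globally filtered) alignment columns,
    restricts to the clade plus the outgroup, rebuilds the NJ tree and
    compares its unrooted topology with the original subtree.  Degenerate
    replicates (no comparable sites for some pair, pairwise deletion only)
    count toward N but never toward s.
    """
    if len(rec.clade_taxa) < 3:
        raise ValidationError(
            "subtree stability is undefined for clades of fewer than 3 "
            "sequences (two sequences always produce the same tree)"
        )
    if outgroup not in rec.sister_taxa:
        raise ValidationError(
            f"{outgroup!r} is not a closest-outgroup candidate of the clade"
        )
    if not isinstance(replicates, (int, np.integer)) or replicates < 1:
        raise ValidationError("replicates must be a positive integer")
    sd = site_data if site_data is not None else SiteData(aln, deletion)
    taxa_sub, M, V, ref_key = _subset_context(aln, full_tree, rec, outgroup, sd)
    k = len(taxa_sub)
    stream = stream_tokens(
        _PS_STREAM_TAG, ",".join(sorted(rec.clade_taxa)), outgroup
    )
    s = 0
    degenerate = 0
    for rep in range(replicates):
        rng = replicate_rng(seed, stream, rep)
        w = _replicate_weights(sd.n_sites, rng, identity_bootstrap)
        D = replicate_distance(M, V, w, k)
        if D is None:
            degenerate += 1
            continue
        if nj_topology_ids(D) == ref_key:
            s += 1
    if degenerate:
        logger.warning(
            "clade {%s} / outgroup %s: %d of %d replicates degenerate "
            "(counted toward N, not s)",
            ",".join(sorted(rec.clade_taxa)), outgroup, degenerate, replicates,
        )
    return OutgroupResult(outgroup, s, replicates, 100.0 * s / replicates)


def ps_averaged(
    aln: Alignment,
    full_tree: Tree,
    rec: CladeRecord,
    replicates: int = 1000,
    seed: int = 0,
    *,
    deletion: str = "complete",
    identity_bootstrap: bool = False,
    site_data: SiteData | None = None,
) -> StabilityResult:
    """Ps over every closest-outgroup candidate, plus their mean.

    Candidates use independent, deterministically derived random streams,
    so results do not depend on evaluation order.
    """
    if not rec.ps_eligible:
        raise ValidationError(
            f"clade is not eligible for subtree stability ({rec.status})"
        )
    sd = site_data if site_data is not None else SiteData(aln, deletion)
    per = [
        ps_single_outgroup(
            aln, full_tree, rec, og, replicates, seed,
            deletion=deletion, identity_bootstrap=identity_bootstrap,
            site_data=sd,
        )
        for og in closest_outgroups(rec)
    ]
    ps_mean = sum(r.ps for r in per) / len(per)
    return StabilityResult(rec, per, ps_mean)


def stability_profile(
    aln: Alignment,
    full_tree: Tree,
    replicates: int = 1000,
    seed: int = 0,
    *,
    root_outgroup: str | None = None,
    deletion: str = "complete",
    identity_bootstrap: bool = False,
) -> list[StabilityResult]:
    """Averaged Ps for every eligible clade of the rooted inferred tree.

    If no ``root_outgroup`` is given the tree is rooted at the leaf with
    the greatest mean p-distance to all others (logged).
    """
    from .distance import distance_matrix
    from .tree import root_at

    check_replicates(replicates)
    if root_outgroup is None:
        root_outgroup = choose_root_outgroup(distance_matrix(aln, deletion))
        logger.info(
            "no root outgroup given; rooting at %r "
            "(greatest mean p-distance)", root_outgroup,
        )
    rooted = root_at(full_tree, root_outgroup)
    sd = SiteData(aln, deletion)
    return [
        ps_averaged(
            aln, full_tree, rec, replicates, seed,
            deletion=deletion, identity_bootstrap=identity_bootstrap,
            site_data=sd,
        )
        for rec in enumerate_clades(rooted)
        if rec.ps_eligible
    ]


def choose_root_outgroup(dm: DistanceMatrix) -> str:
    """Default rooting heuristic: leaf with greatest mean distance.

    Ties break toward the lexicographically smallest name.
    """
    means = dm.d.sum(axis=1) / (dm.n_taxa - 1)
    best = means.max()
    candidates = [t for t, v in zip(dm.taxa, means) if v == best]
    return min(candidates)
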