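"""Felsenstein bootstrap over alignment columns and per-branch support (Pb).

Each replicate draws ``n_sites`` columns with replacement from the (already
column-filtered) alignment, rebuilds the p-distance matrix and the NJ tree,
and checks which splits of the originally inferred tree it contains.  Pb of
a branch is the percentage of replicates containing its split.

Replicates whose distance computation fails (a pair with no comparable
sites after resampling, pairwise deletion only) count toward the replicate
total but support no split; they are tallied and logged rather than
silently dropped, so Pb denominators stay honest.

``identity_bootstrap=True`` replaces resampling with the identity column
list: every replicate then reproduces the original tree and every support
is forced to 100% — an end-to-end invariant used for validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import replicate_rng, stream_tokens
from .alignment import Alignment
from .distance import DistanceMatrix, SiteData, replicate_distance
from .errors import ReplicateCountWarning, ValidationError
from .nj import neighbor_joining, nj_topology_ids
from .tree import Split, Tree, bipartitions, write_newick

logger = logging.getLogger("substab")

#: Recommended minimum replicate count for an accurate support value.
RECOMMENDED_REPLICATES = 500

_PB_STREAM = stream_tokens("pb")


@dataclass(frozen=True)
class BranchSupport:
    """Bootstrap support of one interior branch."""

    split: Split
    pb: float
    replicates: int


def resample_columns(n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """``n_sites`` column indices drawn uniformly with replacement."""
    if n_sites < 1:
        raise ValidationError("resampling needs at least one column")
    return rng.integers(0, n_sites, size=n_sites)


def _replicate_weights(
    n_sites: int, rng: np.random.Generator, identity: bool
) -> np.ndarray:
    if identity:
        return np.ones(n_sites)
    return np.bincount(
        resample_columns(n_sites, rng), minlength=n_sites
    ).astype(float)


def check_replicates(replicates: int) -> None:
    if not isinstance(replicates, (int, np.integer)) or replicates < 1:
        raise ValidationError("replicates must be a positive integer")
    if replicates < RECOMMENDED_REPLICATES:
        message = (
            f"{replicates} bootstrap replicates requested; at least "
            f"{RECOMMENDED_REPLICATES} are recommended for accurate "
            "support values"
        )
        warnings.warn(message, ReplicateCountWarning, stacklevel=3)
        logger.warning(message)


def branch_support(
    aln: Alignment,
    tree: Tree,
    replicates: int = 1000,
    seed: int = 0,
    *,
    deletion: str = "complete",
    identity_bootstrap: bool = False,
    site_data: SiteData | None = None,
    dump_path=None,
) -> list[BranchSupport]:
    """Pb for every interior branch of ``tree``.

    ``tree`` should have been inferred from ``aln`` by the same method (the
    pipeline enforces this); its leaf set must equal the alignment's taxa.
    ``dump_path``, if given, receives one Newick line per replicate tree
    for audit.
    """
    if tree.leaf_names() != frozenset(aln.taxa):
        raise ValidationError("tree leaves do not match alignment taxa")
    check_replicates(replicates)
    targets = bipartitions(tree)
    if not targets:
        return []

    sd = site_data if site_data is not None else SiteData(aln, deletion)
    n = aln.n_taxa
    M, V = sd.pair_data(range(n))
    taxa = list(aln.taxa)
    index = {name: i for i, name in enumerate(taxa)}

    def canonical(split: Split) -> frozenset[int]:
        side = split.side_a if taxa[0] not in split.side_a else split.side_b
        return frozenset(index[t] for t in side)

    by_key = {canonical(s): s for s in targets}
    counts = {s: 0 for s in targets}
    degenerate = 0
    dump = open(dump_path, "w") if dump_path else None
    try:
        for rep in range(replicates):
            rng = replicate_rng(seed, _PB_STREAM, rep)
            w = _replicate_weights(sd.n_sites, rng, identity_bootstrap)
            D = replicate_distance(M, V, w, n)
            if D is None:
                degenerate += 1
                logger.warning(
                    "replicate %d degenerate: a pair has no compared sites; "
                    "counted as non-supporting", rep,
                )
                continue
            key = nj_topology_ids(D)
            for found in key & by_key.keys():
                counts[by_key[found]] += 1
            if dump is not None:
                rep_tree = neighbor_joining(DistanceMatrix(aln.taxa, D))
                dump.write(write_newick(rep_tree) + "\n")
    finally:
        if dump is not None:
            dump.close()
    if degenerate:
        logger.warning(
            "%d of %d replicates were degenerate and support no split",
            degenerate, replicates,
        )
    return [
        BranchSupport(split, 100.0 * counts[split] / replicates, replicates)
        for split in sorted(targets)
    ]
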