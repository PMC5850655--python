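"""p-distances and the pairwise distance matrix driving neighbor joining.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ; comparison is exact match over {A,C,G,T} and
every other symbol (gap, N, IUPAC ambiguity) is missing data.  Two deletion
policies are offered:

``complete``
    Every column containing a missing symbol in ANY row is removed once,
    globally, before anything else — all pairs then share one well-defined
    set of columns, which is also the universe the bootstrap resamples.
    This is the default.
``pairwise``
    Each pair ignores only the columns where one of the two rows is
    missing, so different pairs may use different site counts.

:class:`SiteData` is the precomputed form used by the bootstrap modules:
per-pair mismatch/validity indicator matrices against which a replicate's
column-count vector is a single matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .errors import (
    AlignmentShapeError,
    NoOverlapError,
    NoSitesError,
    ValidationError,
)

# A,C,G,T -> 0..3; every other byte -> -1 (missing).
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode rows as an ``(n_taxa, n_sites)`` int8 matrix (missing = -1)."""
    raw = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_taxa, aln.n_sites)
    return _CODE[raw]


def _encode_row(row: str) -> np.ndarray:
    row = row.upper().replace("U", "T")
    return _CODE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def complete_mask(encoded: np.ndarray) -> np.ndarray:
    """Boolean mask of columns free of missing data in every row."""
    return (encoded >= 0).all(axis=0)


def p_distance(row_a: str, row_b: str, deletion: str = "pairwise") -> tuple[float, int]:
    """Proportion of differing sites between two sequences.

    Returns ``(p, m)`` with ``m`` the number of compared sites.  With
    ``deletion='pairwise'`` any column where either symbol is missing is
    skipped for this pair; ``deletion='complete-context'`` asserts the
    caller already removed such columns globally.
    """
    if len(row_a) != len(row_b):
        raise AlignmentShapeError(
            f"sequence lengths differ: {len(row_a)} vs {len(row_b)}"
        )
    a, b = _encode_row(row_a), _encode_row(row_b)
    if deletion == "pairwise":
        valid = (a >= 0) & (b >= 0)
    elif deletion == "complete-context":
        if (a < 0).any() or (b < 0).any():
            raise ValidationError(
                "complete-context comparison requires gap/ambiguity columns "
                "to have been removed beforehand"
            )
        valid = np.ones(len(a), dtype=bool)
    else:
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    m = int(valid.sum())
    if m == 0:
        raise NoOverlapError("sequence pair shares no comparable sites")
    diff = int(((a != b) & valid).sum())
    return diff / m, m


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances over an ordered taxon list.

    ``valid_sites[i, j]`` is the number of compared sites for the pair; it
    is ``None`` for synthetic (e.g. additive, tree-derived) matrices.
    """

    taxa: tuple[str, ...]
    d: np.ndarray
    valid_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} taxa"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_tsv(self, path: str | Path) -> None:
        """Debug export: tab-separated matrix with a taxon header row/column."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def distance_matrix(aln: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """Full p-distance matrix for ``aln`` under the given deletion policy."""
    if aln.n_taxa < 3:
        raise ValidationError("distance matrix needs at least 3 taxa")
    if deletion not in ("complete", "pairwise"):
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    X = encode_alignment(aln)
    if deletion == "complete":
        X = X[:, complete_mask(X)]
        if X.shape[1] == 0:
            raise NoSitesError(
                "complete deletion removed every column "
                "(each column contains a gap or ambiguity)"
            )
    n = aln.n_taxa
    iu = np.triu_indices(n, 1)
    A, B = X[iu[0]], X[iu[1]]
    valid = (A >= 0) & (B >= 0)
    m = valid.sum(axis=1)
    if (m == 0).any():
        k = int(np.argmax(m == 0))
        raise NoOverlapError(
            f"pair ({aln.taxa[iu[0][k]]!r}, {aln.taxa[iu[1][k]]!r}) shares "
            "no comparable sites"
        )
    diff = ((A != B) & valid).sum(axis=1)
    d = np.zeros((n, n))
    d[iu] = diff / m
    d.T[iu] = d[iu]
    vs = np.full((n, n), X.shape[1], dtype=np.int64)
    vs[iu] = m
    vs.T[iu] = vs[iu]
    return DistanceMatrix(aln.taxa, d, vs)


class SiteData:
    """Column-filtered, encoded alignment prepared for bootstrap resampling.

    With complete deletion the filtering happens here, once, so replicates
    resample only retained columns.  :meth:`pair_data` returns the per-pair
    mismatch matrix ``M`` (and validity matrix ``V`` under pairwise
    deletion) for a subset of rows; a replicate's distance vector is then
    ``(M @ w) / (V @ w)`` for the replicate's column-count vector ``w``.
    """

    def __init__(self, aln: Alignment, deletion: str = "complete") -> None:
        if deletion not in ("complete", "pairwise"):
            raise ValidationError(f"unknown deletion mode {deletion!r}")
        X = encode_alignment(aln)
        if deletion == "complete":
            X = X[:, complete_mask(X)]
            if X.shape[1] == 0:
                raise NoSitesError(
                    "complete deletion removed every column"
                )
        self.X = X
        self.taxa = aln.taxa
        self.deletion = deletion
        self.n_sites = X.shape[1]

    def pair_data(self, rows) -> tuple[np.ndarray, np.ndarray | None]:
        """``(M, V)`` mismatch/validity matrices for the given row indices."""
        sub = self.X[np.asarray(rows, dtype=int)]
        k = sub.shape[0]
        iu = np.triu_indices(k, 1)
        A, B = sub[iu[0]], sub[iu[1]]
        valid = (A >= 0) & (B >= 0)
        M = ((A != B) & valid).astype(np.float64)
        V = valid.astype(np.float64) if self.deletion == "pairwise" else None
        return M, V


def replicate_distance(
    M: np.ndarray, V: np.ndarray | None, w: np.ndarray, n: int
) -> np.ndarray | None:
    """Distance matrix of one bootstrap replicate, or ``None`` if degenerate.

    ``w`` holds how many times each retained column was drawn.  Under
    pairwise deletion a pair may end up with zero compared sites, in which
    case the replicate is degenerate and ``None`` is returned.
    """
    diff = M @ w
    if V is None:
        m = float(w.sum())
        if m == 0:
            return None
        p = diff / m
    else:
        m = V @ w
        if (m == 0).any():
            return None
        p = diff / m
    D = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    D[iu] = p
    D.T[iu] = p
    return D
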