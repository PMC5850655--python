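"""Reading, validating and writing multiple sequence alignments.

An :class:`Alignment` is an ordered set of named, equal-length nucleotide
sequences — the sole raw input of the pipeline.  Sequences are stored
uppercase with ``U`` normalised to ``T``; gaps (``-``), ``N`` and the IUPAC
ambiguity codes are accepted and treated as missing data by the distance
module.

Two on-disk dialects are supported: FASTA (read through Biopython's SeqIO;
header names end at the first whitespace) and relaxed sequential PHYLIP
(whitespace-delimited names, sequences may wrap over several lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, MissingTaxonError, ValidationError

#: Characters admitted after normalisation.  Everything outside A/C/G/T is
#: downstream missing data (see the distance module).
AMBIGUOUS = frozenset("RYSWKMBDHVN-")
ALLOWED = frozenset("ACGT") | AMBIGUOUS

_MAX_NAME = 64  # relaxed-PHYLIP name limit


def _normalize_row(row: str) -> str:
    return row.upper().replace("U", "T")


@dataclass
class Alignment:
    """Equal-length named nucleotide sequences.

    Parameters
    ----------
    taxa:
        Unique, nonempty taxon names, in input order.
    rows:
        One sequence per taxon.  Normalised to uppercase, ``U`` -> ``T``.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.rows = tuple(_normalize_row(r) for r in self.rows)
        if len(self.taxa) != len(self.rows):
            raise ValidationError(
                f"{len(self.taxa)} taxon names but {len(self.rows)} sequences"
            )
        if not self.taxa:
            raise ValidationError("empty alignment")
        seen: set[str] = set()
        for name in self.taxa:
            if not name:
                raise ValidationError("empty taxon name")
            if name in seen:
                raise ValidationError(f"duplicate taxon name {name!r}")
            seen.add(name)
        ref = len(self.rows[0])
        for name, row in zip(self.taxa, self.rows):
            if len(row) != ref:
                raise AlignmentShapeError(
                    f"sequence for {name!r} has length {len(row)}, "
                    f"expected {ref}"
                )
            for pos, sym in enumerate(row):
                if sym not in ALLOWED:
                    raise ValidationError(
                        f"unknown character {sym!r} at position {pos + 1} "
                        f"of sequence {name!r}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise MissingTaxonError(f"taxon {taxon!r} not in alignment") from None


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise ValidationError(f"{path}: empty file")


def _read_fasta(path: Path) -> Alignment:
    names: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq))
    if not names:
        raise ValidationError(f"{path}: no FASTA records found")
    return Alignment(tuple(names), tuple(rows))


def _read_phylip(path: Path) -> Alignment:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) < 2:
        raise ValidationError(f"{path}: PHYLIP header must be 'n_taxa n_sites'")
    try:
        n_taxa, n_sites = int(header[0]), int(header[1])
    except ValueError:
        raise ValidationError(
            f"{path}: non-numeric PHYLIP header {lines[0]!r}"
        ) from None
    tokens = "\n".join(lines[1:]).split()
    names: list[str] = []
    rows: list[str] = []
    i = 0
    for _ in range(n_taxa):
        if i >= len(tokens):
            raise AlignmentShapeError(
                f"{path}: expected {n_taxa} sequences, found {len(names)}"
            )
        name = tokens[i]
        if len(name) > _MAX_NAME:
            raise ValidationError(f"{path}: taxon name {name!r} exceeds "
                                  f"{_MAX_NAME} characters")
        i += 1
        chunks: list[str] = []
        length = 0
        while length < n_sites and i < len(tokens):
            chunks.append(tokens[i])
            length += len(tokens[i])
            i += 1
        seq = "".join(chunks)
        if len(seq) != n_sites:
            raise AlignmentShapeError(
                f"{path}: sequence for {name!r} has length {len(seq)}, "
                f"header says {n_sites}"
            )
        names.append(name)
        rows.append(seq)
    return Alignment(tuple(names), tuple(rows))


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read and validate an alignment from ``path``.

    ``format`` is ``fasta``, ``phylip`` or ``auto`` (sniffs a leading ``>``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "phylip":
        return _read_phylip(path)
    raise ValidationError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write ``aln`` to ``path`` as FASTA or relaxed sequential PHYLIP."""
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(aln.taxa, aln.rows)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            for name, row in zip(aln.taxa, aln.rows):
                fh.write(f"{name}  {row}\n")
    else:
        raise ValidationError(f"unknown alignment format {format!r}")


def restrict_alignment(aln: Alignment, taxa) -> Alignment:
    """Return the alignment restricted (and reordered) to ``taxa``.

    Column count is unchanged; every requested taxon must be present.
    """
    taxa = list(taxa)
    index = {name: i for i, name in enumerate(aln.taxa)}
    rows = []
    for name in taxa:
        if name not in index:
            raise MissingTaxonError(f"taxon {name!r} not in alignment")
        rows.append(aln.rows[index[name]])
    return Alignment(tuple(taxa), tuple(rows))
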