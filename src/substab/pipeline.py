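"""End-to-end run: alignment -> NJp tree -> Pb -> Ps -> annotated outputs.

``run_pipeline`` reads and validates the alignment, computes the p-distance
matrix, infers the NJ tree, roots it (user-chosen outgroup or the
greatest-mean-distance heuristic), computes bootstrap branch support for
every interior branch and averaged subtree stability for every eligible
clade, and writes four artifacts next to ``out_prefix``:

``<prefix>.nwk``   rooted tree with ``Pb|Ps`` internal labels (Ps ``NA``
                   where undefined)
``<prefix>.tsv``   one row per clade: members, Pb, per-outgroup Ps, mean Ps
``<prefix>.json``  full audit: run metadata plus exact s/N per outgroup
``<prefix>.log``   warnings and bookkeeping notes of the run

Outputs are byte-deterministic functions of (alignment, seed, replicates,
flags).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import Alignment, read_alignment
from .bootstrap import branch_support
from .distance import SiteData, distance_matrix
from .errors import ValidationError
from .nj import neighbor_joining
from .stability import (
    CladeRecord,
    StabilityResult,
    choose_root_outgroup,
    enumerate_clades,
    ps_averaged,
)
from .tree import Split, Tree, format_percent, root_at, write_newick

logger = logging.getLogger("substab")


@dataclass
class PipelineConfig:
    """All knobs of one run; every field maps to a CLI flag."""

    alignment: str | Path
    format: str = "auto"
    replicates: int = 1000
    seed: int = 0
    deletion: str = "complete"
    root_outgroup: str | None = None
    out_prefix: str | Path | None = None
    identity_bootstrap: bool = False
    dump_replicates: bool = False


@dataclass
class CladeRow:
    """One table row: a clade with its support and stability values."""

    clade_id: str
    taxa: tuple[str, ...]
    size: int
    pb: float | None
    stability: StabilityResult | None
    status: str

    @property
    def ps_mean(self) -> float | None:
        return self.stability.ps_mean if self.stability else None


@dataclass
class RunReport:
    """The artifact's output: annotated tree plus the per-clade table."""

    tree: Tree                      # unrooted inferred tree
    rooted_tree: Tree               # rooted display tree
    newick: str                     # annotated Newick ("Pb|Ps" labels)
    rows: list[CladeRow]
    metadata: dict
    log_lines: list[str] = field(default_factory=list)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__()
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full Pb/Ps pipeline described in the module docstring."""
    log_lines: list[str] = []
    handler = _ListHandler(log_lines)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        aln = read_alignment(config.alignment, config.format)
        if aln.n_taxa < 4:
            raise ValidationError(
                f"tree inference needs at least 4 taxa, got {aln.n_taxa}"
            )
        dm = distance_matrix(aln, config.deletion)
        tree = neighbor_joining(dm)

        if config.root_outgroup is not None:
            root_name = config.root_outgroup
            root_choice = "user"
        else:
            root_name = choose_root_outgroup(dm)
            root_choice = "heuristic"
            logger.info(
                "no root outgroup given; rooting at %r "
                "(greatest mean p-distance)", root_name,
            )
        rooted = root_at(tree, root_name)

        dump_path = None
        if config.dump_replicates:
            if config.out_prefix is None:
                raise ValidationError(
                    "--dump-replicates requires an output prefix"
                )
            dump_path = Path(f"{config.out_prefix}.replicates.nwk")
        supports = branch_support(
            aln, tree, config.replicates, config.seed,
            deletion=config.deletion,
            identity_bootstrap=config.identity_bootstrap,
            dump_path=dump_path,
        )
        pb_map: dict[Split, float] = {bs.split: bs.pb for bs in supports}

        sd = SiteData(aln, config.deletion)
        rows: list[CladeRow] = []
        ps_map: dict[Split, float] = {}
        for k, rec in enumerate(enumerate_clades(rooted), start=1):
            stability = None
            if rec.ps_eligible:
                stability = ps_averaged(
                    aln, tree, rec, config.replicates, config.seed,
                    deletion=config.deletion,
                    identity_bootstrap=config.identity_bootstrap,
                    site_data=sd,
                )
                ps_map[rec.defining_branch] = stability.ps_mean
            rows.append(
                CladeRow(
                    clade_id=f"C{k}",
                    taxa=tuple(sorted(rec.clade_taxa)),
                    size=len(rec.clade_taxa),
                    pb=pb_map.get(rec.defining_branch),
                    stability=stability,
                    status=rec.status,
                )
            )

        newick = write_newick(rooted, annotation="pb_ps", pb=pb_map, ps=ps_map)
        metadata = {
            "package": "substab",
            "version": __version__,
            "seed": config.seed,
            "replicates": config.replicates,
            "deletion": config.deletion,
            "root_outgroup": root_name,
            "root_choice": root_choice,
            "identity_bootstrap": config.identity_bootstrap,
            "n_taxa": aln.n_taxa,
            "n_sites": aln.n_sites,
            "alignment": str(config.alignment),
        }
        report = RunReport(tree, rooted, newick, rows, metadata, log_lines)
        if config.out_prefix is not None:
            _write_outputs(report, config.out_prefix)
        return report
    finally:
        logger.removeHandler(handler)


def _fmt(value: float | None) -> str:
    return "NA" if value is None else format_percent(value)


def _write_outputs(report: RunReport, prefix: str | Path) -> None:
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(prefix + ".nwk", "w") as fh:
        fh.write(report.newick + "\n")

    header = [
        "clade_id", "size", "pb", "ps_mean", "outgroups",
        "per_outgroup_ps", "s_counts", "replicates", "status", "taxa",
    ]
    with open(prefix + ".tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in report.rows:
            st = row.stability
            fh.write("\t".join([
                row.clade_id,
                str(row.size),
                _fmt(row.pb),
                _fmt(row.ps_mean),
                ";".join(r.outgroup for r in st.per_outgroup) if st else "NA",
                ";".join(_fmt(r.ps) for r in st.per_outgroup) if st else "NA",
                ";".join(str(r.s) for r in st.per_outgroup) if st else "NA",
                str(st.n_replicates) if st else "NA",
                row.status,
                ",".join(row.taxa),
            ]) + "\n")

    audit = dict(report.metadata)
    audit["tree"] = report.newick
    audit["clades"] = [
        {
            "clade_id": row.clade_id,
            "taxa": list(row.taxa),
            "size": row.size,
            "pb": row.pb,
            "status": row.status,
            "ps_mean": row.ps_mean,
            "per_outgroup": [
                {"outgroup": r.outgroup, "s": r.s, "N": r.n, "ps": r.ps}
                for r in (row.stability.per_outgroup if row.stability else [])
            ],
        }
        for row in report.rows
    ]
    with open(prefix + ".json", "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(prefix + ".log", "w") as fh:
        for line in report.log_lines:
            fh.write(line + "\n")
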