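"""The full Pb/Ps pipeline on a simulated alignment.

Simulates a high-signal ladder tree, writes it as FASTA, runs the whole
pipeline (NJ tree -> bootstrap branch support -> averaged subtree
stability) and prints the per-clade table plus the annotated Newick whose
internal labels read "Pb|Ps".
"""

import tempfile
from pathlib import Path

from substab import caterpillar_tree, simulate_alignment, write_alignment
from substab.pipeline import PipelineConfig, run_pipeline

truth = caterpillar_tree(8, internal_len=0.05, terminal_len=0.05)
aln = simulate_alignment(truth, n_sites=5000, seed=1)

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "sim.fasta"
    write_alignment(aln, fasta)
    config = PipelineConfig(
        alignment=fasta,
        replicates=1000,
        seed=1,
        root_outgroup="t8",
        out_prefix=Path(tmp) / "run",
    )
    report = run_pipeline(config)

print("clade_id  size  Pb      mean_Ps  status")
for row in report.rows:
    pb = "NA" if row.pb is None else f"{row.pb:g}"
    ps = "NA" if row.ps_mean is None else f"{row.ps_mean:g}"
    print(f"{row.clade_id:<9} {row.size:<5} {pb:<7} {ps:<8} {row.status}")

print("\nannotated tree (internal labels are Pb|Ps, NA = undefined):")
print(report.newick)
# Every interior branch carries Pb; clades of >= 3 sequences additionally
# carry the outgroup-averaged Ps.  Here the signal is strong, so both
# statistics sit at or near 100 for every branch: the tree is reliable
# AND its subtrees are stable.
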