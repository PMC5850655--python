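# substab — branch support *and* subtree stability for NJ trees

How much should you trust a published phylogeny? The standard answer is the
bootstrap probability **Pb** of each interior branch: the percentage of
bootstrap replicates (resampling alignment columns with replacement) whose
re-inferred tree contains that branch's bipartition. But Pb only measures how
often *one split* recurs — it says nothing about whether the internal
arrangement of the clade below that split is itself stable. A clade can sit
behind a branch with Pb = 100% while its internal branching order collapses
under resampling.

`substab` computes, next to Pb, the **subtree stability Ps** of every clade
of three or more sequences in a neighbor-joining tree built on p-distances
(the *NJp* method):

1. Root the inferred tree at a chosen outgroup leaf and read off its clades.
2. For a clade *C*, the **closest outgroups** are the leaves of *C*'s sister
   group.
3. For one closest outgroup *g*: bootstrap the alignment columns, restrict
   each replicate to *C* ∪ {*g*}, rebuild the NJ tree on that subset, and
   count the replicates *s* (out of *N*) whose unrooted topology is
   identical to the original subtree — the inferred full tree restricted to
   the same taxa. Then

   **Ps = (s / N) × 100 %.**

4. When several closest outgroups exist, Ps is computed once per candidate
   and the unweighted arithmetic mean is reported.

A subtree is trustworthy only when **both** Pb and Ps are high. Ps is
undefined for two-sequence clades (two sequences always give the same tree).

This package targets molecular evolution workflows — e.g. multigene-family
trees such as the mammalian MHC class II β chain genes — where deep clades
with many short internal branches routinely show high Pb yet very low Ps.

## Worked example

```python
from substab import caterpillar_tree, simulate_alignment, write_alignment
from substab.pipeline import PipelineConfig, run_pipeline

truth = caterpillar_tree(8, internal_len=0.05, terminal_len=0.05)
aln = simulate_alignment(truth, n_sites=5000, seed=1)
write_alignment(aln, "sim.fasta")
report = run_pipeline(PipelineConfig(
    alignment="sim.fasta", replicates=1000, seed=1,
    root_outgroup="t8", out_prefix="run",
))
```

Running `python examples/full_pipeline.py` (the same computation) prints:

```
clade_id  size  Pb      mean_Ps  status
C1        2     100     NA       NA:two-taxa
C2        3     100     100      ok
C3        4     100     100      ok
C4        5     100     100      ok
C5        6     100     100      ok
C6        7     NA      NA       NA:no-outgroup
```

Each row is one clade of the rooted tree: `Pb` is the bootstrap support of
its defining branch, `mean_Ps` the outgroup-averaged subtree stability.
`NA:two-taxa` marks two-sequence clades (Ps undefined); `NA:no-outgroup`
marks the clade directly under the root, whose "branch" is just the root
leaf's pendant edge — no interior branch, hence neither statistic. With
branches of 0.05 substitutions/site and 5000 sites the signal is strong and
every value sits at 100: the tree is reliable and its subtrees are stable.

The annotated Newick written alongside carries `Pb|Ps` labels on internal
nodes (`NA` where Ps is undefined), e.g. `(t1,t2)100|NA` — parseable by any
Newick reader that accepts internal-node labels.

## Command line

```bash
substab simulate --leaves 8 --sites 5000 --seed 1 --out sim.fasta
substab run --alignment sim.fasta --replicates 1000 --seed 1 \
            --root-outgroup t8 --out-prefix run
```

`substab run` writes `run.nwk` (annotated tree), `run.tsv` (clade table),
`run.json` (full audit with every s/N pair) and `run.log`. Flags mirror the
library: `--deletion complete|pairwise` controls gap handling (complete
deletion — dropping every column containing a gap/ambiguity anywhere —
is the default and keeps the bootstrap's column universe identical for all
pairs), `--identity-bootstrap` disables resampling (every support must then
be 100, a pipeline self-check), `--dump-replicates` writes every replicate
tree. Fewer than 500 replicates triggers a warning; outputs are
byte-deterministic functions of (alignment, seed, flags).

The library is the primary interface; `examples/` holds one short script per
capability (NJ from distances, JC69 calibration, single-clade stability, the
full pipeline).

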