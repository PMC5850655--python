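# Methods

## The two statistics

Let *A* be an alignment of *n* ≥ 4 nucleotide sequences with *L* columns.
The package infers an unrooted binary tree *T* by neighbor joining on the
matrix of p-distances (proportion of differing sites over compared sites),
then attaches two per-branch quantities.

**Branch support (Pb).** Nonparametric bootstrap over columns: each
replicate draws *L* columns with replacement, recomputes the p-distance
matrix and the NJ tree, and a branch of *T* is supported when the replicate
tree contains its bipartition. Pb is the supporting percentage of
replicates. Pb attaches to every interior branch, equivalently every
nontrivial split; its resolution is 100/replicates.

**Subtree stability (Ps).** *T* is rooted at an outgroup leaf; every
internal vertex below the root defines a clade *C* with a sister group *S*.
For each closest-outgroup candidate *g* ∈ *S*, the *reference* is the
induced subtree of the original *T* on *C* ∪ {*g*} (pruning plus
suppression of degree-2 vertices), not a re-inferred subset tree: stability
is measured relative to what was originally published, and on coherent data
the two coincide anyway. Each of *N* replicates resamples the (globally
filtered) columns, restricts to *C* ∪ {*g*}, rebuilds the NJ subset tree
and scores a match when its unrooted topology equals the reference;
Ps(*C*, *g*) = 100·*s*/*N*. The clade's reported value is the unweighted
mean over all candidates *g*, averaged before any rounding.

*N* is fixed at the requested replicate count: every replicate produces
*some* unrooted subset tree, so the natural denominator is the number of
trials, not a count conditioned on events in full-tree replicates.
Replicates whose distance computation degenerates (a pair with zero
compared sites, possible only under pairwise deletion) count toward *N*,
never toward *s*, and are logged — silently dropping them would bias the
denominator.

**Which clades get a Ps.** Two-sequence clades never do (two sequences
always produce the same tree). A clade whose parent is the root does not
either: with the root on a leaf's pendant edge, that clade's "defining
branch" is the trivial split of the root leaf — there is no interior branch
and no sister group to draw an outgroup from. It is reported
`NA:no-outgroup` rather than silently skipped. Every other clade of ≥ 3
sequences is eligible, and every nontrivial split of the tree appears
exactly once in the output table.

Note an asymmetry that is easy to miss: the branch *above* a clade never
acts as a discriminating edge inside that clade's own subset problem (it
dissolves into the outgroup's pendant path under suppression). A zero-length
branch above clade *X* therefore depresses Pb(*X*) and the Ps of the
*enclosing* clade whose subset problem contains that branch — the two
statistics flag the same ambiguity from different directions, which is
precisely why both are needed.

## Distances and missing data

Comparison is exact match on {A, C, G, T}; gaps, `N` and IUPAC ambiguity
codes are missing data. Default deletion mode is **complete**: every column
containing a missing symbol in any row is removed once, globally, *before*
bootstrap resampling, so all pairs and all replicates share one column
universe. Pairwise deletion is available behind a flag; it lets each pair
keep its own columns at the cost of replicate-dependent site counts.
Filtering before resampling (rather than per replicate) keeps the
resampling universe fixed, which the replicate bookkeeping assumes.

Only the uncorrected p-distance is used for inference; model-corrected
distances are out of scope. The bootstrap hot path precomputes per-pair
mismatch and validity indicator matrices so one replicate's distance matrix
is a single matrix–vector product with the replicate's column-count vector.

## Neighbor joining details

Standard Saitou–Nei agglomeration with the Studier–Keppler criterion
Q(i,j) = (r−2)·d(i,j) − R(i) − R(j). Ties in Q are broken toward the
lexicographically smallest pair of active-cluster indices in creation
order, making runs reproducible across platforms. The last three clusters
are joined at the center vertex with the three-point formulas. Negative
estimated branch lengths are clamped to zero in the returned tree; the
topology is whatever the Q criterion selected. Three taxa return the unique
star; fewer is an error. The method is used identically for the full tree
and every replicate/subset tree — support values are only meaningful when
the replicate trees come from the same inference as the original.

## Randomness and determinism

Every replicate gets its own `numpy` generator seeded from
`SeedSequence([seed, *stream, replicate_index])`, where `stream` is a SHA-256
derived token pair identifying the purpose — the full-tree Pb stream, or a
(clade, outgroup) pair for Ps. Consequences: identical configurations give
byte-identical outputs; evaluating clades in any order, or one clade in
isolation, reproduces exactly the same (s, N); per-replicate work could be
parallelised without changing results. The identity-bootstrap mode replaces
the resampled column counts by the all-ones vector, which must force every
Pb and every eligible Ps to 100 — an end-to-end invariant the tests assert
on gap-containing inputs.

## Rooting

Clade enumeration needs a root. The pipeline takes an explicit
`--root-outgroup`; absent that, it roots at the leaf with the greatest mean
p-distance to all others (ties toward the lexicographically smallest name)
and logs the choice. The Ps machinery itself is rooting-agnostic: subset
comparisons are between unrooted topologies.

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| replicates | 1000 | count | standard practice for support values; resolution 0.1 % |
| replicate floor / warning | 1 / < 500 | count | below ~500 the quantisation of Ps and Pb dominates |
| deletion | complete | — | one shared column universe for all pairs and replicates |
| NJ tie-break | smallest index pair | — | platform-independent determinism |
| rooting heuristic | max mean distance | — | the most distant leaf is the best outgroup guess absent user input |

## The synthetic-data generator

`simulate_alignment` evolves i.i.d. uniform root sites down a tree under
JC69: a branch of length *t* (expected substitutions/site) flips each site
with probability (3/4)(1 − e^(−4t/3)), uniformly to one of the other three
bases. `caterpillar_tree` builds the ladder shape typical of multigene-family
trees; `random_rooted_tree` gives arbitrary shapes for property tests;
`additive_distance_matrix` produces the exactly additive matrices on which
NJ is provably exact.

What the generator deliberately omits: rate heterogeneity across sites,
base-composition bias, indels (gaps enter test fixtures by injection, not
simulation), and selection. Passing tests therefore demonstrate the
*machinery* — correct resampling, counting, topology comparison and
bookkeeping — and the statistics' qualitative behaviour (high signal ⇒ both
high; zero-length branch ⇒ both depressed). They do not certify behaviour
under model misspecification on real data, where p-distances saturate and
NJp itself can be inconsistent.

Test and validation problem sizes were chosen so the whole suite exercises
every code path in seconds: 5–8 taxa, 2000–5000 sites, 100–1000 replicates,
with 0.05 substitutions/site branches as the "clearly resolvable" regime
and a zeroed branch as the "no signal" regime. At 5000 sites a 0.05 branch
carries ≈ 250 expected substitutions — overwhelming signal, so recovery
failures would indicate bugs, not noise.

## Numerical and degenerate-input choices

- Support percentages are exact ratios of integers (100·count/replicates);
  Ps means are averaged unrounded and rounded only for display.
- The all-zero distance matrix is accepted: NJ returns an arbitrary (but
  deterministic, via the tie-break) binary topology with zero lengths.
- Asymmetry beyond 1e-12 in a distance matrix is an error, not silently
  symmetrised.
- Newick output formats lengths with `%.10g` and quotes labels only when
  they contain reserved characters; the annotated dialect writes internal
  labels `Pb|Ps` with `NA` for undefined Ps.
- Alignment parsing normalises case and U→T; unknown symbols, duplicate or
  empty names, and ragged rows are hard errors naming the offender.

## Known limitations

- **Identity-bootstrap vs. reference choice.** The Ps reference is the
  induced subtree of the original full tree. An identity replicate
  re-infers NJ on the subset's original columns; in pathological
  conflicting-signal data NJ restricted to a subset can differ from the
  restriction of the full NJ tree, in which case identity-mode Ps would
  fall below 100 — itself a signal of instability. On all tested fixtures
  the two coincide.
- Ps compares *whole* subset topologies, so one unstable cherry deep inside
  a large clade drags the clade's Ps down even if the rest is solid; this
  is by design (it is what "stability of the subtree" means) but means Ps
  of large clades trends low.
- Recursive tree algorithms bound the practical tree size to roughly the
  Python recursion limit (~1000 leaves) — far above the tens-of-taxa scale
  the method targets.
- Amino-acid alphabets, corrected distances, other inference methods and
  figure rendering are out of scope; the inference step is pluggable only
  in the sense that all topology algebra is method-agnostic.
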