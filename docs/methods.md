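# Methods

## The model

Bacterial genomes differ in how much of their sequence is made of motifs
that share a base composition with restriction-enzyme recognition sites.
`spectrabin` exploits this as an alignment-free signature. Known length-6
recognition sites are DNA palindromes (a word `w` with
`w == reverse(complement(w))`), which forces their base composition to be
self-complementary: `nA == nT` and `nC == nG`. At length 6 exactly four such
compositions exist, and permuting the base multiset of each yields the four
*spectrum sets*, named by their seed words:

| seed   | composition (A,C,G,T) | permutations | palindromes | members |
|--------|----------------------|--------------|-------------|---------|
| AAATTT | (3,0,0,3)            | 20           | 8           | 12      |
| AATTCG | (2,1,1,2)            | 180          | 24          | 156     |
| CCGGAT | (1,2,2,1)            | 180          | 24          | 156     |
| CCCGGG | (0,3,3,0)            | 20           | 8           | 12      |

Palindromes are excluded from the sets: restriction sites are avoided in
genomes, so their observed frequencies would confound a composition
signal. A fifth profile space, `PAL6`, holds all 4^3 = 64 length-6
palindromes and is kept for whole-chromosome relatedness trees.

For a motif `m_i` and a sequence fragment `S_L` (read, contig or genome)
the profiled statistic is the coverage proportion

    p(m_i in S_L) = count(m_i) * |m_i| / |S_L|,

the fraction of the fragment covered by non-overlapping copies of the
motif. One proportion per set member, in fixed lexicographic motif order,
forms the fragment's profile vector. Vectors are compared by a configurable
metric and merged into a tree by agglomerative hierarchical clustering; a
flat cut at k groups yields bins.

## Assumptions and conventions

- **Counting** is an exact, case-insensitive, forward-strand scan. The
  default non-overlapping mode is a left-to-right greedy scan (advance by
  |m| after a match, by 1 otherwise), which equals the maximum number of
  non-overlapping occurrences and is therefore direction-invariant; an
  overlapping mode (all start positions) exists for sensitivity checks.
  Forward-strand-only is safe in this feature space because every spectrum
  set is closed under reverse complement — a motif and its reverse
  complement are separate columns of the same matrix.
- **Ambiguity codes.** Non-ACGT letters never match a motif window but do
  count toward |S_L|, keeping proportions comparable across fragments of
  equal length.
- **Clustering defaults** are Euclidean distance with complete linkage,
  the stock behaviour of the R `hclust`-plus-heatmap workflow this pipeline
  mirrors; the original description names only "a clustering analysis", so
  metric and linkage are exposed as flags (`manhattan`, `correlation`;
  `average`, `single`). Merge ties are broken toward the smallest pair of
  cluster indices, making trees bit-reproducible; the merge loop is
  implemented directly (O(n³), fine at desk scale) because library linkage
  routines do not pin down tie order, and is cross-checked against scipy on
  tie-free data in the test suite.
- **Clustering always sees raw proportions.** The per-column z-scaling
  offered for heatmap export is applied after the dendrogram is computed
  and affects display only, so bins never depend on rendering options.
- **Newick export** uses the ultrametric embedding in which the cophenetic
  distance between two leaves equals their merge height: leaves sit at
  height 0 and a child's branch is half the height difference to its
  parent (two leaves merged at height h get branches h/2 each). Tree
  comparison is the unrooted Robinson–Foulds bipartition distance; a
  monophyly check (is each named group exactly one bin of the k-cut?)
  serves as the desk-scale counterpart of comparing subtree arrangements
  against a reference taxonomy by eye.

## Set selection and binning

- **Contrast** of a realised grouping is the mean silhouette width of the
  profile rows under the configured metric — bounded in [-1, 1], 0 by
  convention for degenerate groupings (all-zero distances, or every group
  a singleton).
- **The spectrum set test** profiles only the parent genomes (the known
  close relatives of a pool) under each candidate set and ranks sets by
  the mean pairwise *per-motif RMS* distance between parent profiles
  (Euclidean distance divided by the square root of the set size, so
  12-motif and 156-motif sets score on one scale). Silhouette cannot rank
  this design — with each parent its own group every cluster is a
  singleton and silhouette is identically zero — so the report's score is
  a separation statistic rather than a silhouette. Identical parents give
  all-zero scores and an alphabetical ranking. The default candidates are
  the four seed sets; `PAL6` is opt-in, since it mixes all four
  compositions and is meant for chromosome phylogenies rather than set
  selection.
- **Iterative removal** handles pools of three or more organisms: each
  round splits the remaining fragments at k=2 with the next set in the
  schedule and removes the bin whose mean profile lies farthest from the
  pooled mean (ties toward the smaller bin). The default schedule is the
  top g−1 entries of the spectrum-set-test ranking for g parents — one
  removal per round, remainder as the last group; a longer schedule would
  keep splitting an already-pure remainder. A round whose silhouette
  contrast falls below 0.25 logs a warning that removal is not supported
  by the data (the threshold is advisory only and affects no result).
- k is user-supplied; automatic model selection of the number of organisms
  is out of scope.

## The synthetic data generator

Parents are i.i.d. sequences with P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2,
optionally with specific motifs planted at non-overlapping random
positions; fragments are fixed-length substrings at uniform starts with
optional i.i.d. substitution errors. Everything is reproducible from
integer seeds, byte-for-byte.

The study conditions used throughout the tests are 1 Mb parents at GC
0.30 / 0.50 / 0.65 with 5 fragments of 5 kb per parent — a synthetic
analogue of an AT-rich genus, an intermediate genus, and a GC-rich genus.
These sizes keep the whole suite inside a couple of minutes on one CPU
while leaving the motif-count statistics in the same regime as real 5 kb
contigs. The generator does **not** emulate homopolymer or indel error
profiles, coverage variation, repeats, or the oligonucleotide
autocorrelation of real genomes; passing tests therefore demonstrate that
the statistic separates composition-divergent sources at realistic
fragment lengths, not that it resolves closely related real strains.

## Measured behaviour under the study conditions

- Two parents (GC 0.30 vs 0.65), AAATTT set, k=2: recovery is 10/10 in
  every replicate observed (mean accuracy 1.00 over 50 fragment draws).
- Three parents (GC 0.30/0.50/0.65), schedule from the spectrum set test
  ([AAATTT, CCCGGG]): mean accuracy ≈ 0.99 over replicates, with perfect
  15/15 recovery in roughly 9 of 10 fragment draws — the GC 0.50 vs 0.65
  split at 5 kb is the stochastic step, since CCCGGG motif counts in a
  5 kb fragment are small (a handful per motif).
- Accuracy is monotone in fragment length (≈0.70 at 700 bp, ≈0.81 at
  1000 bp, ≈0.95 at 2 kb, ≈1.00 at 5 kb for the two-parent design). Note
  that at 1000 bp this sits well below high-confidence territory even for
  a 0.35 GC gap: minimum-length guidance (warn below 700 bp, recommend
  ≥1000 bp) is guidance, not a guarantee.

## Numerical choices and degenerate inputs

- Proportions are exact IEEE quotients of integer counts; tests verify
  them against rational arithmetic.
- Sequences shorter than the motif length profile to all-zero vectors and
  still bin (with a warning); a correlation metric on a constant profile
  row is an error rather than a NaN.
- Duplicate sequence ids are rejected at profile time, naming the id.
- All randomness flows through `numpy.random.default_rng` seeded from the
  caller; no global state.

## Known limitations

- Length-6 sets only; the enumeration code is length-generic but no other
  seed lengths are registered.
- Composition signal only: two organisms with similar GC and similar
  restriction-site usage will not separate, whatever the fragment length.
- The silhouette-based contrast and the centroid-distance removal rule are
  this package's operationalisations of a qualitative "high contrast in
  the heatmap" notion; alternatives (gap statistic, between/within sum of
  squares) would be defensible and may rank borderline cases differently.
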