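# spectrabin

Alignment-free differentiation and binning of metagenomic sequence
fragments by **spectrum-set** base composition.

Metagenome assembly starts with a mixed pool of reads and contigs from
several organisms; grouping ("binning") fragments by presumed origin
before assembly shrinks the search space dramatically. `spectrabin` bins
fragments using a purely statistical signature: the proportions of a
fragment covered by the *spectrum sets* — the four families of length-6
motifs obtained by permuting the base compositions of bacterial
restriction-enzyme recognition sites.

Because known length-6 recognition sites are DNA palindromes, their
compositions satisfy nA = nT and nC = nG, and only four exist:
`AAATTT` (3A3T), `AATTCG` (2A2T1C1G), `CCGGAT` (1A1T2C2G) and `CCCGGG`
(3C3G). Excluding palindromes (which genomes avoid), the sets contain 12,
156, 156 and 12 motifs. For each motif m in a set, a fragment S is scored
with the coverage proportion

    p(m in S) = count(m) · |m| / |S|

and the resulting profile vectors are hierarchically clustered (Euclidean,
complete linkage by default) into a tree of relatedness; cutting the tree
at k gives k bins. For pools of three or more organisms, the most
contrasting bin is removed and the remainder re-binned with the next
spectrum set (*iterative removal*). A *spectrum set test* run on the
parent genomes (known close relatives of the pool) picks which sets
discriminate best — choosing the wrong set can erase the contrast between
two organisms entirely.

The package also ships a seeded simulator (composition-controlled genomes,
fixed-length fragment pools with optional substitution errors, truth
tables), newick export with Robinson–Foulds tree comparison, and clustered
heatmap-matrix export. See `docs/methods.md` for the full model
description and measured behaviour.

## Worked example

Simulate an AT-rich (GC 0.30) and a GC-rich (GC 0.65) parent genome of
1 Mb each with a mixed pool of ten 5 kb fragments, pick a set, and bin:

```console
$ spectrabin simulate --parents 2 --gc 0.30,0.65 --length 1000000 \
      --frag-n 5 --frag-len 5000 --seed 17 --out-dir demo
$ spectrabin test-sets --parents demo/parents.fasta
set     score       rank
AAATTT  0.0108146   1
CCCGGG  0.00694155  2
CCGGAT  0.00169529  3
AATTCG  0.00142199  4
# chosen: AAATTT
```

The score is the mean per-motif RMS distance between the parents' profile
vectors under each set: the AT-composition set contrasts these two genomes
about 7× more strongly than either mixed-composition set, so `AAATTT` is
chosen.

```console
$ spectrabin bin demo/pool.fasta --set AAATTT --k 2 --out demo/bins.tsv
wrote 10 assignments to demo/bins.tsv
$ head -3 demo/bins.tsv
sequence_id                 round  bin_label  contrast_score
parent1_gc0.30|f4|228890    1      1          0.779455
parent1_gc0.30|f0|641383    1      1          0.779455
```

All five `parent1` fragments land in bin 1 and all five `parent2`
fragments in bin 2 — 10/10 agreement with the simulator's truth table
(`demo/truth.tsv`) — with a mean silhouette contrast of 0.78 between the
bins. Other subcommands: `sets` (print set members), `profile` (the raw
proportion matrix), `cluster` (newick tree, flat cuts, heatmap TSV/PNG),
`bin --iterative` (contrast-removal binning for ≥3 organisms) and `run`
(the whole pipeline with a JSON run log). Everything is also available as
a library: `spectrabin.profile_matrix`, `spectrabin.cluster`,
`spectrabin.bin_pool`, `spectrabin.iterative_removal`, ….

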