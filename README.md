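# alnkit

Fast manipulation and summary statistics for multiple sequence alignments,
aimed at phylogenomic workflows that juggle hundreds to thousands of
single-locus alignments: building and dismantling supermatrices, converting
among the formats that inference programs expect, and screening loci by
their basic properties (missing data, variability, composition).

`alnkit` is pure standard-library Python and can be used either as an
importable package or through the `alnkit` command, one action per
invocation, with optional parallel processing across input files.

## What it does

* **Read/write five dialects** — FASTA, PHYLIP (sequential and
  interleaved, relaxed taxon names), NEXUS (sequential and interleaved) —
  with lossless any-to-any conversion.
* **Concatenate** loci into a supermatrix over the lexicographically
  sorted union of their taxa. A taxon unsampled at a locus is filled with
  `?` (unknown — not `-`, which would assert an indel). A partition file
  records each locus's 1-based inclusive coordinates, `name = start-end`.
* **Split** a supermatrix back into per-locus files given a partition
  scheme; RAxML-style model prefixes (`DNA, gene1 = 1-100`), `charset`
  lines, comma-separated multi-ranges and codon stride notation
  (`1-99\3`) are all accepted.
* **Remove taxa** by name; **build jackknife replicates**, each
  concatenated from loci sampled uniformly without replacement under a
  user-supplied seed.
* **Summarize** each alignment: number of taxa, length, total matrix
  cells, undetermined characters, percent missing data, AT/GC content
  (DNA), counts and proportions of variable and parsimony-informative
  sites, and per-character counts.

Site classification uses the standard parsimony criterion: after dropping
missing characters (`?`, `-`, and `N`/`X` by data type) and IUPAC partial
ambiguity codes, a column is *parsimony informative* if at least two
states each occur in at least two sequences, *constant* if at most one
state remains, and *variable but uninformative* otherwise. With
site-pattern counts \(n_1 \ge n_2 \ge \dots\) over unambiguous states, the
rule is simply: informative iff \(n_2 \ge 2\).

## Worked example

```sh
$ printf '>sp1\nAAA\n>sp2\nCCC\n' > g1.fas
$ printf '>sp2\nGG\n>sp3\nTT\n'  > g2.fas
$ alnkit concat -i g1.fas g2.fas -f fasta -d dna -u fasta -o super
$ cat super.fas
>sp1
AAA??
>sp2
CCCGG
>sp3
???TT
$ cat super-partitions.txt
g1 = 1-3
g2 = 4-5
```

`sp1` was never sequenced for locus `g2` and `sp3` never for `g1`, so the
supermatrix pads those blocks with `?`; the partition file locates each
locus for downstream partitioned inference. Summarizing the result:

```sh
$ alnkit summary -i super.fas -f fasta -d dna -o stats.tsv
$ cut -f1-12 stats.tsv
Alignment_name  No_of_taxa  Alignment_length  Total_matrix_cells  Undetermined_characters  Missing_percent  No_variable_sites  Proportion_variable_sites  Parsimony_informative_sites  Proportion_parsimony_informative  AT_content  GC_content
super           3           5                 15                  5                        33.33            5                  1                          0                            0                                 0.5         0.5
```

Five of the fifteen cells are the inserted `?` fills (33.33% missing).
Every column has two residues and one unknown, so all five sites are
variable, but no state appears twice in any column — zero sites are
parsimony informative, which is why heavily padded supermatrices can carry
much less signal than their length suggests. Among the ten unambiguous
bases, A+T = G+C, hence AT and GC contents of 0.5. The remaining columns
of `stats.tsv` count each character (here A:3, C:3, G:2, T:2, ?:5).

Splitting inverts the concatenation (`-e` drops taxa that are entirely
missing within a partition):

```sh
$ alnkit split -i super.fas -f fasta -d dna -l super-partitions.txt -e
```

All of this is equally available as a library:

```python
from alnkit import read_file, concatenate, summarize, DataType, FormatSpec
loci = [read_file(p, FormatSpec.FASTA) for p in ("g1.fas", "g2.fas")]
sm = concatenate(loci)
stats = summarize(sm.alignment, DataType.DNA)
```

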