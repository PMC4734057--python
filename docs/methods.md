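# Methods

This note records the definitions, conventions and design choices behind
`alnkit`, in the spirit of a model-description vignette: what exactly is
computed, which knobs matter, what the synthetic data emulate, and where
the edges are.

## Data model

An alignment is an ordered list of `(taxon name, sequence)` records of
identical length, validated once at construction: unique, non-empty,
line-break-free taxon names; equal row lengths; input order preserved
verbatim. Zero-site alignments are legal objects (a batch run over
thousands of loci must not die on a degenerate file); any proportion over
zero sites is reported as 0 rather than NaN.

Two alphabet regimes are supported and must be declared by the caller
(`dna` / `aa`); they are never guessed from content. The regime fixes the
**missing-character set** — `?`, `-`, plus the full-ambiguity code `N`
(nucleotide) or `X` (amino acid), case-insensitive — and whether base
composition applies. IUPAC partial-ambiguity codes (`RYSWKMBDHV` for DNA;
`B`, `Z`, `J` for protein) are *not* missing: they appear in per-character
counts but are excluded from site-state reasoning, because assigning them
to a single state would require an arbitrary resolution. Characters
outside all three sets are tolerated, counted, logged once per alignment,
and otherwise treated like ambiguities.

Sequence case is preserved byte-for-byte in every output; all statistics
case-fold first. This keeps conversion lossless (soft-masked input stays
soft-masked) while keeping statistics independent of masking.

## File formats

Five dialects: FASTA, PHYLIP sequential/interleaved, NEXUS
sequential/interleaved. The declared input format is authoritative — there
is no auto-detection, trading a small user obligation for speed and
unambiguous parsing.

* **FASTA**: wrapped (multi-line) records are accepted; the taxon name is
  the description line up to the first whitespace (the remainder is
  discarded with a logged notice, since no other dialect can carry it).
  Output is unwrapped.
* **PHYLIP**: relaxed names — a name is terminated by whitespace and may
  be any length. Strict 10-column files parse too as long as names contain
  no internal spaces; genuinely padded names with spaces are out of scope.
  The `ntaxa nsites` header is verified against parsed content and any
  disagreement is an error citing expected vs found. In interleaved
  reading, blocks after the first may repeat taxon names or omit them;
  lines cycle through taxa in first-block order.
* **NEXUS**: keyword matching is case-insensitive, square-bracket comments
  (nesting allowed) are stripped first, and both `DATA` and `CHARACTERS`
  blocks are accepted. `DIMENSIONS` counts, when present, are verified.
  Interleaved matrices must repeat taxa in identical order in every block;
  out-of-order blocks are rejected rather than silently reassembled,
  because reordering usually signals a corrupt or truncated file. Output
  declares `DATATYPE=DNA|PROTEIN MISSING=? GAP=-`.

Interleaved writers use 60-residue blocks, the conventional width. Output
files are named `<input stem>.<fas|phy|int-phy|nex|int-nex>`. Writers and
readers are exact inverses; the suite checks write→read identity
property-based over randomized alignments (including empty sequences and
missing-heavy rows) and cross-checks parsing against Biopython on
generated files.

## Summary statistics

Per alignment: taxon count, length, total cells (taxa × length), count of
missing characters and percent missing (rendered to 2 decimals in the
table, full precision internally), counts and proportions of variable and
parsimony-informative sites, AT/GC content (DNA only), and per-character
counts (canonical alphabet always present with explicit zeros, plus any
extra observed characters).

Site classification, per column: case-fold, drop missing and ambiguous
characters, count state multiplicities over the remaining unambiguous
states. ≤ 1 distinct state → constant (a column of nothing but `?`/`-`/`N`
is constant, not variable); ≥ 2 states each with multiplicity ≥ 2 →
parsimony informative; anything else → variable but uninformative. A
consequence worth stating prominently: tools that *resolve* ambiguity
codes instead of excluding them can report slightly different
variable/informative proportions on real data containing many partial
ambiguities.

AT content is (A+T)/(A+C+G+T) over unambiguous bases only, and GC its
complement, so the two always sum to 1 when any unambiguous base exists;
with none at all, both are reported as 0. For amino-acid data the two
columns are blank.

The multi-file summary is a TSV with one row per input in input-path
order, independent of worker count.

## Concatenation, splitting, replicates

Concatenation takes the lexicographically sorted union of taxon names —
input-order union would depend on file order and parallel scheduling;
sorting makes output reproducible — and fills each taxon's unsampled loci
with `?` of the locus length. Partitions are emitted in input order, named
by source-file stem (duplicates get `_2`, `_3`, … with a warning), as
1-based inclusive contiguous ranges tiling `1..L` exactly; this tiling is
revalidated on every construction. A zero-length locus contributes no
partition (a partition's site list may not be empty) and is logged.

The partition-file writer emits the minimal `name = start-end` dialect;
the parser additionally tolerates what published schemes contain: RAxML
model prefixes, `charset` keywords, trailing semicolons, comma-separated
multi-ranges, codon stride `start-end\k`, and `#` comments. Overlapping
partitions parse with a warning (loci may legitimately share sites);
malformed lines fail with their line number.

Splitting extracts each partition's sites in order for every taxon;
`remove_empty` then drops taxa whose extracted sequence is entirely
missing, which makes splitting the exact inverse of concatenation up to
the padded-in taxa. A partition left with no taxa at all is skipped with
a warning rather than aborting the batch. Site indices beyond the matrix
fail before anything is written for that input.

Replicates (phylogenetic jackknife): each replicate concatenates `k` loci
sampled uniformly **without replacement** from the input set — the
jackknife convention; draws are independent across replicates and driven
by a single `random.Random(seed)`, so identical seed + inputs give
byte-identical outputs. A with-replacement (bootstrap-style) variant would
be a small flag-guarded addition but is not currently exposed.

## Command-line interface

One action per run (`summary`, `concat`, `convert`, `split`, `remove`,
`replicate`, `gen-fixtures`); input files, input format and data type are
always mandatory; flag order is irrelevant. Parallelism (`-c`) distributes
whole input files across worker processes — the natural unit for
thousands-of-loci workloads — and reassembles results in input order, so
output bytes are identical for any worker count. Per-file failures are
logged and skipped; the exit status is zero iff every file succeeded.
Input files are never modified, and a conversion whose output path would
coincide with its input is refused for that file. Logs go to standard
error, data to files.

## Synthetic data

The `gen-fixtures` action / `alnkit.fixtures` module generates toy
alignments: i.i.d. uniform residues with each cell independently replaced
by a missing character at a configurable rate (default 5%, 8 taxa × 100
sites — a miniature single-locus alignment), plus a manifest of each
file's true composition as tracked during generation, so computed
statistics can be checked against values known by construction.
`random_locus_set` additionally emulates patchy taxon occupancy (default
80% over a shared pool), which is what forces fill characters during
concatenation, as in real multilocus datasets.

What the generator does **not** emulate: phylogenetic correlation among
sites or taxa (no tree, no substitution model), realistic base
composition or rate heterogeneity, indel structure (gaps are i.i.d., not
contiguous), or real-world format quirks beyond those the parsers
explicitly tolerate. Passing tests on these fixtures therefore
demonstrates bookkeeping correctness — parsing, coordinates, counting,
determinism — not robustness to every file ever written, and the
statistics' biological interpretation is exercised only at toy scale.

## Verification problem sizes and numerical choices

The self-verification battery (tests and `scripts/acceptance.py`) uses:
all 8⁵ = 32,768 length-5 columns over `{A,C,G,T,-,?,N,R}` against a
brute-force classifier; 500 randomized alignments (1–30 taxa, 0–200
sites, 0–40% missing, both datatypes) through all five dialects; 200
randomized locus sets for concatenate→split inversion; 1,000 single-locus
draws from 4 loci tested for sampling uniformity by chi-square at
α = 0.01; and 1,000 generated files compared byte-for-byte between serial
and 8-worker conversion. These sizes make the checks exhaustive where the
space is enumerable and comfortably redundant elsewhere while keeping the
whole battery in the seconds-to-a-minute range on one core.

All counting is exact integer arithmetic; the only floating-point
quantities are ratios of counts, computed at full precision and rounded
only for display (missing percent to 2 decimals, proportions to 6
significant digits in the TSV).

## Known limitations

* No automatic format detection; a wrong `-f` produces a parse error (or,
  in pathological cases, a mis-parse the header checks cannot catch).
* PHYLIP names containing spaces (strict padded dialect) are unsupported.
* NEXUS support covers data/character matrices only — no trees, sets
  beyond `charset` lines in partition files, or MrBayes blocks.
* Per-taxon statistics, sequence translation/recoding and consensus
  sequences are out of scope.
* Statistics stream whole alignments through memory; matrices far beyond
  ~10⁹ cells are better summarized locus-wise.
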