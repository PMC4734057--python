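"""Alignment-transforming operations.

Concatenation of many single-locus alignments into a supermatrix over the
union of their taxa (unsampled loci filled with '?'), splitting a
supermatrix back into loci given a partition scheme, taxon removal, and
seeded random replicate datasets for the phylogenetic jackknife.

Coordinates are 1-based inclusive everywhere, matching the conventions of
the partition files consumed by phylogenetic inference programs.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass
from typing import Sequence

from .core import Alignment, AlignmentError, DataType, Partition, validate_alignment

log = logging.getLogger(__name__)

#: fill character for taxa unsampled at a locus — '?' (unknown), never '-'
#: (which would assert an indel)
FILL_CHAR = "?"


@dataclass(frozen=True)
class Supermatrix:
    """A concatenated alignment plus the partitions locating each locus.

    Partitions are contiguous, non-overlapping, ascending, jointly tiling
    ``1..length``, with unique names.
    """

    alignment: Alignment
    partitions: tuple[Partition, ...]

    def __post_init__(self) -> None:
        partitions = tuple(self.partitions)
        object.__setattr__(self, "partitions", partitions)
        names = [p.name for p in partitions]
        if len(set(names)) != len(names):
            raise AlignmentError("supermatrix partition names must be unique")
        pos = 1
        for p in partitions:
            if not p.is_contiguous:
                raise AlignmentError(f"supermatrix partition {p.name!r} is not contiguous")
            if p.start != pos:
                raise AlignmentError(
                    f"supermatrix partitions do not tile: {p.name!r} starts at "
                    f"{p.start}, expected {pos}"
                )
            pos = p.end + 1
        if pos != self.alignment.length + 1:
            raise AlignmentError(
                f"supermatrix partitions cover 1..{pos - 1} but the alignment "
                f"has {self.alignment.length} sites"
            )


@dataclass(frozen=True)
class ReplicateSpec:
    """How to draw jackknife replicates: ``n_replicates`` supermatrices,
    each concatenated from ``loci_per_replicate`` loci sampled uniformly
    without replacement, from a generator seeded with ``seed``."""

    n_replicates: int
    loci_per_replicate: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise AlignmentError("n_replicates must be >= 1")
        if self.loci_per_replicate < 1:
            raise AlignmentError("loci_per_replicate must be >= 1")


def concatenate(alignments: Sequence[Alignment]) -> Supermatrix:
    """Concatenate alignments into a supermatrix over the union of taxa.

    Taxa are sorted lexicographically for reproducible output.  A taxon
    absent from a locus receives a run of '?' of that locus's length.
    Partition ``i`` is named after alignment ``i``'s ``source_name`` (with a
    numeric suffix on duplicates) and spans the contiguous 1-based range the
    locus occupies.  Zero-length loci contribute no partition.
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate: empty alignment list")
    taxa = sorted({name for aln in alignments for name in aln.taxon_names})
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[Partition] = []
    used_names: set[str] = set()
    pos = 1
    for aln in alignments:
        length = aln.length
        by_name = dict(aln.records)
        for t in taxa:
            pieces[t].append(by_name.get(t, FILL_CHAR * length))
        if length == 0:
            log.warning(
                "locus %r has zero sites and contributes no partition",
                aln.source_name,
            )
            continue
        name = aln.source_name
        if name in used_names:
            k = 2
            while f"{name}_{k}" in used_names:
                k += 1
            log.warning(
                "duplicate locus name %r disambiguated as %r", name, f"{name}_{k}"
            )
            name = f"{name}_{k}"
        used_names.add(name)
        partitions.append(Partition.from_range(name, pos, pos + length - 1))
        pos += length
    records = tuple((t, "".join(pieces[t])) for t in taxa)
    aln = validate_alignment(records, source_name="concatenated")
    return Supermatrix(aln, tuple(partitions))


# ---------------------------------------------------------------------------
# partition files


def write_partition_file(partitions: Sequence[Partition]) -> str:
    """One line per partition: ``<name> = <start>-<end>`` (1-based inclusive).

    Non-contiguous partitions are written as comma-separated runs, which
    :func:`parse_partition_file` round-trips.
    """
    lines = []
    for p in partitions:
        runs: list[str] = []
        start = prev = p.sites[0]
        for s in p.sites[1:]:
            if s == prev + 1:
                prev = s
                continue
            runs.append(f"{start}-{prev}" if prev > start else str(start))
            start = prev = s
        runs.append(f"{start}-{prev}" if prev > start else str(start))
        lines.append(f"{p.name} = {', '.join(runs)}")
    return "".join(line + "\n" for line in lines)


_RANGE_RE = re.compile(
    r"^(?P<start>\d+)(?:\s*-\s*(?P<end>\d+)(?:\s*\\\s*(?P<stride>\d+))?)?$"
)


def _expand_chunk(chunk: str, lineno: int) -> list[int]:
    m = _RANGE_RE.match(chunk.strip())
    if m is None:
        raise AlignmentError(
            f"malformed site range {chunk!r} on line {lineno}"
        )
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    stride = int(m.group("stride")) if m.group("stride") else 1
    if start < 1 or end < start or stride < 1:
        raise AlignmentError(
            f"implausible site range {chunk!r} on line {lineno}"
        )
    return list(range(start, end + 1, stride))


def parse_partition_file(text: str) -> list[Partition]:
    """Parse a partition scheme: ``name = start-end`` lines.

    Tolerated extras seen in published schemes: RAxML-style leading model
    tokens (``DNA, gene1 = 1-100`` / ``WAG, ...``), a leading ``charset``
    keyword, stride notation ``start-end\\k`` (every k-th site), and
    comma-separated multi-range site lists.  Blank lines and ``#`` comment
    lines are skipped.  Partitions may overlap (a warning is logged);
    malformed lines raise with their line number.
    """
    partitions: list[Partition] = []
    claimed: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip().rstrip(";").strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise AlignmentError(f"malformed partition line {lineno}: {raw!r}")
        left, right = line.split("=", 1)
        left = left.strip()
        if re.match(r"charset\s", left, re.IGNORECASE):
            left = left.split(None, 1)[1]
        if "," in left:  # "DNA, gene1" / "WAG, gene1" model prefix
            left = left.rsplit(",", 1)[1]
        name = left.strip()
        if not name:
            raise AlignmentError(f"missing partition name on line {lineno}")
        sites: set[int] = set()
        for chunk in right.split(","):
            if chunk.strip():
                sites.update(_expand_chunk(chunk, lineno))
        if not sites:
            raise AlignmentError(f"no sites given for {name!r} on line {lineno}")
        overlap = sites & claimed
        if overlap:
            log.warning(
                "partition %r re-claims %d site(s) already assigned "
                "(first: %d)",
                name,
                len(overlap),
                min(overlap),
            )
        claimed |= sites
        partitions.append(Partition(name, tuple(sorted(sites))))
    return partitions


# ---------------------------------------------------------------------------
# splitting and taxon removal


def split(
    supermatrix_aln: Alignment,
    partitions: Sequence[Partition],
    remove_empty: bool = False,
    datatype: DataType = DataType.DNA,
) -> list[Alignment]:
    """Extract one alignment per partition from a concatenated matrix.

    With ``remove_empty``, taxa whose extracted sequence is entirely
    missing characters are dropped from that output.  A partition whose
    extraction would leave no taxa at all is skipped with a warning.
    """
    length = supermatrix_aln.length
    out: list[Alignment] = []
    for p in partitions:
        if p.end > length:
            raise AlignmentError(
                f"partition {p.name!r} references site {p.end} beyond "
                f"alignment length {length}"
            )
        idx = [s - 1 for s in p.sites]
        records: list[tuple[str, str]] = []
        for name, seq in supermatrix_aln.records:
            sub = "".join(seq[i] for i in idx)
            if remove_empty and all(datatype.is_missing(c) for c in sub):
                continue
            records.append((name, sub))
        if not records:
            log.warning(
                "partition %r is entirely missing data for every taxon; "
                "no alignment written",
                p.name,
            )
            continue
        out.append(validate_alignment(records, source_name=p.name))
    return out


def remove_taxa(aln: Alignment, names: Sequence[str]) -> Alignment:
    """Drop records whose taxon name is in ``names``; order preserved.

    Names not present are tolerated with a warning.  Removing every taxon
    is an error.
    """
    wanted = set(names)
    missing = wanted - set(aln.taxon_names)
    for name in sorted(missing):
        log.warning("taxon %r not found in %r", name, aln.source_name)
    records = tuple((n, s) for n, s in aln.records if n not in wanted)
    if not records:
        raise AlignmentError("removal of all taxa: empty alignment would result")
    return validate_alignment(records, aln.source_name)


# ---------------------------------------------------------------------------
# replicates


def make_replicates(
    alignments: Sequence[Alignment], spec: ReplicateSpec
) -> list[Supermatrix]:
    """Build seeded jackknife replicate supermatrices.

    Each replicate concatenates ``loci_per_replicate`` alignments sampled
    uniformly without replacement; draws are independent across replicates.
    Identical seed and inputs give identical outputs.
    """
    if spec.loci_per_replicate > len(alignments):
        raise AlignmentError(
            f"cannot sample {spec.loci_per_replicate} loci without replacement "
            f"from {len(alignments)} input alignments"
        )
    rng = random.Random(spec.seed)
    replicates: list[Supermatrix] = []
    for _ in range(spec.n_replicates):
        chosen = rng.sample(range(len(alignments)), spec.loci_per_replicate)
        replicates.append(concatenate([alignments[i] for i in chosen]))
    return replicates
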