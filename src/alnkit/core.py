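"""Core data model for multiple sequence alignments.

Everything downstream (format I/O, concatenation, summary statistics) is
built on a single immutable :class:`Alignment` value: an ordered list of
``(taxon name, sequence)`` records of equal length, tagged with the name of
the file it came from.  Validation happens once, at construction, so the
rest of the package can assume well-formed matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence, Tuple


class AlignmentError(ValueError):
    """Raised when alignment data violate a structural invariant."""


# Canonical residue sets, all uppercase; membership tests case-fold first.
_DNA_STATES = frozenset("ACGT")
_AA_STATES = frozenset("ACDEFGHIKLMNPQRSTVWY")
_DNA_MISSING = frozenset("?-N")
_AA_MISSING = frozenset("?-X")
# IUPAC partial-ambiguity codes: carry some state information, so they are
# neither "missing" nor usable as a single state in site classification.
_DNA_AMBIGUOUS = frozenset("RYSWKMBDHV")
_AA_AMBIGUOUS = frozenset("BZJ")


class DataType(Enum):
    """Declared alphabet regime of an alignment: nucleotide or amino acid.

    Governs which characters count as missing/undetermined ('N' for DNA,
    'X' for protein, plus '?' and '-' for both) and which statistics apply
    (AT/GC content is DNA-only).
    """

    DNA = "dna"
    AA = "aa"

    @classmethod
    def from_string(cls, value: str) -> "DataType":
        try:
            return cls(value.lower())
        except ValueError:
            raise AlignmentError(
                f"unknown data type {value!r}; expected 'dna' or 'aa'"
            ) from None

    @property
    def missing_chars(self) -> frozenset[str]:
        """Characters conveying no state information (uppercase)."""
        return _DNA_MISSING if self is DataType.DNA else _AA_MISSING

    @property
    def unambiguous_states(self) -> frozenset[str]:
        return _DNA_STATES if self is DataType.DNA else _AA_STATES

    @property
    def ambiguity_codes(self) -> frozenset[str]:
        return _DNA_AMBIGUOUS if self is DataType.DNA else _AA_AMBIGUOUS

    @property
    def canonical_alphabet(self) -> tuple[str, ...]:
        """Fixed display order for per-character count columns."""
        if self is DataType.DNA:
            return tuple("ACGT") + ("-", "?", "N")
        return tuple(sorted(_AA_STATES)) + ("-", "?", "X")

    def is_missing(self, char: str) -> bool:
        return char.upper() in self.missing_chars


class FormatSpec(Enum):
    """The five supported alignment dialects."""

    FASTA = "fasta"
    PHYLIP = "phylip"
    PHYLIP_INT = "phylip-int"
    NEXUS = "nexus"
    NEXUS_INT = "nexus-int"

    @classmethod
    def from_string(cls, value: str) -> "FormatSpec":
        try:
            return cls(value.lower())
        except ValueError:
            choices = ", ".join(f.value for f in cls)
            raise AlignmentError(
                f"unknown format {value!r}; expected one of: {choices}"
            ) from None

    @property
    def suffix(self) -> str:
        return _SUFFIXES[self]

    @property
    def interleaved(self) -> bool:
        return self in (FormatSpec.PHYLIP_INT, FormatSpec.NEXUS_INT)


_SUFFIXES = {
    FormatSpec.FASTA: "fas",
    FormatSpec.PHYLIP: "phy",
    FormatSpec.PHYLIP_INT: "int-phy",
    FormatSpec.NEXUS: "nex",
    FormatSpec.NEXUS_INT: "int-nex",
}


class SiteClass(Enum):
    """Mutually exclusive, exhaustive classification of one alignment column."""

    CONSTANT = "constant"
    VARIABLE_UNINFORMATIVE = "variable_uninformative"
    PARSIMONY_INFORMATIVE = "parsimony_informative"


@dataclass(frozen=True)
class Alignment:
    """An ordered, validated collection of equal-length sequence records.

    Parameters
    ----------
    records
        ``(taxon_name, sequence)`` pairs, order preserved exactly as given.
    source_name
        Name of the originating file (stem), used for partition naming when
        alignments are concatenated.
    """

    records: Tuple[Tuple[str, str], ...]
    source_name: str = "alignment"

    def __post_init__(self) -> None:
        records = tuple((str(n), str(s)) for n, s in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise AlignmentError("alignment must contain at least one record")
        seen: set[str] = set()
        length = len(records[0][1])
        for name, seq in records:
            if not name:
                raise AlignmentError("taxon name may not be empty")
            if "\n" in name or "\r" in name:
                raise AlignmentError(f"taxon name {name!r} contains a line break")
            if name in seen:
                raise AlignmentError(f"duplicate taxon name {name!r}")
            seen.add(name)
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: taxon {name!r} has {len(seq)} sites, "
                    f"expected {length}"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        """Number of sites (columns)."""
        return len(self.records[0][1])

    @property
    def taxon_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence_of(self, name: str) -> str:
        for taxon, seq in self.records:
            if taxon == name:
                return seq
        raise KeyError(name)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.records)

    def __len__(self) -> int:
        return self.n_taxa

    def columns(self) -> Iterator[tuple[str, ...]]:
        """Yield alignment columns (site-wise tuples of characters)."""
        return zip(*self.sequences)

    def with_source(self, source_name: str) -> "Alignment":
        return Alignment(self.records, source_name)


def validate_alignment(
    records: Iterable[Tuple[str, str]], source_name: str = "alignment"
) -> Alignment:
    """Build an :class:`Alignment` from raw records, enforcing all invariants.

    Raises :class:`AlignmentError` for ragged rows (naming the offending
    taxon), duplicate taxon names, empty names, or an empty record list.
    Idempotent: validating the records of a valid Alignment returns an
    equal Alignment.
    """
    return Alignment(tuple(records), source_name)


@dataclass(frozen=True)
class Partition:
    """A named, ordered set of 1-based site indices locating a locus.

    Site indices are strictly increasing and >= 1.  Partitions emitted by
    concatenation are contiguous ranges; partitions parsed from a scheme
    file may carry stride or multi-range site lists.
    """

    name: str
    sites: Tuple[int, ...]

    def __post_init__(self) -> None:
        sites = tuple(int(s) for s in self.sites)
        object.__setattr__(self, "sites", sites)
        if not self.name:
            raise AlignmentError("partition name may not be empty")
        if not sites:
            raise AlignmentError(f"partition {self.name!r} has no sites")
        if sites[0] < 1:
            raise AlignmentError(
                f"partition {self.name!r}: site indices are 1-based, got {sites[0]}"
            )
        for a, b in zip(sites, sites[1:]):
            if b <= a:
                raise AlignmentError(
                    f"partition {self.name!r}: sites must be strictly increasing"
                )

    @classmethod
    def from_range(cls, name: str, start: int, end: int) -> "Partition":
        """Contiguous 1-based inclusive range ``start-end``."""
        if end < start:
            raise AlignmentError(
                f"partition {name!r}: empty range {start}-{end}"
            )
        return cls(name, tuple(range(start, end + 1)))

    @property
    def start(self) -> int:
        return self.sites[0]

    @property
    def end(self) -> int:
        return self.sites[-1]

    @property
    def is_contiguous(self) -> bool:
        return len(self.sites) == self.end - self.start + 1
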