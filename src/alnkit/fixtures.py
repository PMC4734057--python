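"""Randomized toy-alignment generator.

Produces small synthetic alignments in any supported dialect, with
configurable taxon count, length, taxon occupancy and missing-data rate,
plus a manifest recording the ground-truth composition tracked during
generation (so tests can check computed statistics against values known by
construction, not recomputed).

Residues are drawn i.i.d. uniformly over the unambiguous alphabet; each
cell is independently replaced by a missing character ('?', '-', or N/X)
with probability ``missing_rate``.  Default shape (8 taxa x 100 sites,
5% missing) is a miniature of a typical single-locus phylogenomic
alignment; property tests and batch benchmarks override it freely.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import Alignment, DataType, FormatSpec, validate_alignment
from .io import output_name, write_file

_MISSING_DNA = "?-N"
_MISSING_AA = "?-X"


def _alphabets(datatype: DataType) -> tuple[str, str]:
    states = "".join(sorted(datatype.unambiguous_states))
    missing = _MISSING_DNA if datatype is DataType.DNA else _MISSING_AA
    return states, missing


def random_records(
    rng: random.Random,
    n_taxa: int,
    length: int,
    datatype: DataType = DataType.DNA,
    missing_rate: float = 0.05,
    taxon_names: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], int]:
    """Draw raw records; returns ``(records, n_missing_inserted)``."""
    states, missing = _alphabets(datatype)
    if taxon_names is None:
        taxon_names = [f"t{i + 1:03d}" for i in range(n_taxa)]
    n_missing = 0
    records: list[tuple[str, str]] = []
    for name in taxon_names:
        chars = []
        for _ in range(length):
            if rng.random() < missing_rate:
                chars.append(rng.choice(missing))
                n_missing += 1
            else:
                chars.append(rng.choice(states))
        records.append((name, "".join(chars)))
    return records, n_missing


def random_alignment(
    rng: random.Random,
    n_taxa: int = 8,
    length: int = 100,
    datatype: DataType = DataType.DNA,
    missing_rate: float = 0.05,
    name: str = "aln",
    taxon_names: Sequence[str] | None = None,
) -> Alignment:
    records, _ = random_records(
        rng, n_taxa, length, datatype, missing_rate, taxon_names
    )
    return validate_alignment(records, source_name=name)


def random_locus_set(
    rng: random.Random,
    n_loci: int = 10,
    pool_size: int = 12,
    occupancy: float = 0.8,
    min_taxa: int = 2,
    length_range: tuple[int, int] = (20, 80),
    datatype: DataType = DataType.DNA,
    missing_rate: float = 0.05,
) -> list[Alignment]:
    """Draw a set of single-locus alignments over a shared taxon pool.

    Each locus samples each pool taxon with probability ``occupancy``
    (at least ``min_taxa`` kept), emulating the patchy taxon occupancy of
    real multilocus datasets so that concatenation must insert fill
    characters.
    """
    pool = [f"sp{i + 1:03d}" for i in range(pool_size)]
    loci: list[Alignment] = []
    for i in range(n_loci):
        taxa = [t for t in pool if rng.random() < occupancy]
        while len(taxa) < min_taxa:
            extra = rng.choice([t for t in pool if t not in taxa])
            taxa.append(extra)
        taxa.sort()
        length = rng.randint(*length_range)
        loci.append(
            random_alignment(
                rng,
                len(taxa),
                length,
                datatype,
                missing_rate,
                name=f"locus{i + 1:03d}",
                taxon_names=taxa,
            )
        )
    return loci


@dataclass(frozen=True)
class FixtureInfo:
    """Ground truth for one generated fixture file."""

    path: Path
    n_taxa: int
    length: int
    undetermined_count: int


def write_fixture_files(
    out_dir: str | Path,
    n_files: int = 10,
    format: FormatSpec = FormatSpec.FASTA,
    datatype: DataType = DataType.DNA,
    n_taxa: int = 8,
    length: int = 100,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[FixtureInfo], Path]:
    """Write ``n_files`` random alignments plus a ``manifest.tsv``.

    The manifest records each file's true taxon count, length and number of
    missing characters inserted during generation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    infos: list[FixtureInfo] = []
    for i in range(n_files):
        stem = f"aln{i + 1:04d}"
        records, n_missing = random_records(
            rng, n_taxa, length, datatype, missing_rate
        )
        aln = validate_alignment(records, source_name=stem)
        path = out_dir / output_name(stem, format)
        write_file(aln, format, path, datatype)
        infos.append(FixtureInfo(path, n_taxa, length, n_missing))
    manifest = out_dir / "manifest.tsv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["file", "n_taxa", "length", "undetermined_characters"])
        for info in infos:
            writer.writerow(
                [info.path.name, info.n_taxa, info.length, info.undetermined_count]
            )
    return infos, manifest
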