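"""Per-alignment summary statistics and the multi-alignment summary table.

The statistic battery per alignment: number of taxa, length, total matrix
cells, undetermined-character count, percent missing data, AT/GC content
(DNA only), counts and proportions of variable and parsimony-informative
sites, and per-character counts.

Site classification works on unambiguous states only, case-folded:
missing characters ('?', '-', and N or X depending on datatype) and IUPAC
partial-ambiguity codes are excluded from a column's state multiset before
classifying.  A site is *constant* if at most one distinct state remains,
*parsimony informative* if at least two states each occur at least twice,
and *variable but uninformative* otherwise.  This exclusion rule matters
when comparing proportions across tools that resolve ambiguities instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from multiprocessing import Pool
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import Alignment, AlignmentError, DataType, FormatSpec, SiteClass
from .io import BatchResult, read_file

log = logging.getLogger(__name__)

#: fixed leading columns of the summary table, in output order
FIXED_COLUMNS = (
    "Alignment_name",
    "No_of_taxa",
    "Alignment_length",
    "Total_matrix_cells",
    "Undetermined_characters",
    "Missing_percent",
    "No_variable_sites",
    "Proportion_variable_sites",
    "Parsimony_informative_sites",
    "Proportion_parsimony_informative",
    "AT_content",
    "GC_content",
)


@dataclass(frozen=True)
class SummaryStats:
    """The full statistic bundle for one alignment.

    ``at_content``/``gc_content`` are ``None`` for amino-acid data (and
    rendered blank in the table).  Proportions over a zero-site alignment
    are reported as 0 so degenerate inputs do not break batch runs.
    """

    name: str
    n_taxa: int
    length: int
    total_cells: int
    undetermined_count: int
    missing_percent: float
    at_content: float | None
    gc_content: float | None
    variable_count: int
    variable_prop: float
    informative_count: int
    informative_prop: float
    char_counts: Mapping[str, int]


def classify_site(column: Sequence[str], datatype: DataType) -> SiteClass:
    """Classify one alignment column as constant / variable / informative.

    Unknown characters (anything outside the datatype's states, missing set
    and ambiguity codes) are treated like ambiguities: excluded from the
    state multiset, with a logged notice.
    """
    if not column:
        raise AlignmentError("cannot classify an empty column")
    states = datatype.unambiguous_states
    missing = datatype.missing_chars
    ambiguous = datatype.ambiguity_codes
    counts: Counter[str] = Counter()
    for ch in column:
        c = ch.upper()
        if c in states:
            counts[c] += 1
        elif c not in missing and c not in ambiguous:
            log.debug("unknown character %r treated as ambiguous", ch)
    if len(counts) <= 1:
        return SiteClass.CONSTANT
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.VARIABLE_UNINFORMATIVE


def site_class_counts(aln: Alignment, datatype: DataType) -> dict[SiteClass, int]:
    counts = {cls: 0 for cls in SiteClass}
    for column in aln.columns():
        counts[classify_site(column, datatype)] += 1
    return counts


def summarize(aln: Alignment, datatype: DataType) -> SummaryStats:
    """Compute the full statistic battery for one alignment."""
    char_counts: Counter[str] = Counter()
    for seq in aln.sequences:
        char_counts.update(seq.upper())

    known = (
        datatype.unambiguous_states
        | datatype.missing_chars
        | datatype.ambiguity_codes
    )
    unknown = set(char_counts) - known
    if unknown:
        log.info(
            "alignment %r contains characters outside the %s alphabet, "
            "treated as ambiguous: %s",
            aln.source_name,
            datatype.value,
            "".join(sorted(unknown)),
        )

    total_cells = aln.n_taxa * aln.length
    undetermined = sum(char_counts[c] for c in datatype.missing_chars)
    missing_percent = 100.0 * undetermined / total_cells if total_cells else 0.0

    if datatype is DataType.DNA:
        acgt = {b: char_counts.get(b, 0) for b in "ACGT"}
        denom = sum(acgt.values())
        at = (acgt["A"] + acgt["T"]) / denom if denom else 0.0
        gc = (acgt["G"] + acgt["C"]) / denom if denom else 0.0
    else:
        at = gc = None

    classes = site_class_counts(aln, datatype)
    informative = classes[SiteClass.PARSIMONY_INFORMATIVE]
    variable = informative + classes[SiteClass.VARIABLE_UNINFORMATIVE]
    length = aln.length

    # canonical alphabet always present (zero counts included), extras kept
    counts = {c: 0 for c in datatype.canonical_alphabet}
    counts.update(char_counts)

    return SummaryStats(
        name=aln.source_name,
        n_taxa=aln.n_taxa,
        length=length,
        total_cells=total_cells,
        undetermined_count=undetermined,
        missing_percent=missing_percent,
        at_content=at,
        gc_content=gc,
        variable_count=variable,
        variable_prop=variable / length if length else 0.0,
        informative_count=informative,
        informative_prop=informative / length if length else 0.0,
        char_counts=counts,
    )


def _fmt_prop(value: float | None) -> str:
    if value is None:
        return ""
    return f"{round(value, 6):g}"


def summary_table(stats: Sequence[SummaryStats], datatype: DataType) -> str:
    """Render a TSV table, one row per alignment, stable column order.

    Character-count columns are the canonical alphabet of the datatype in
    fixed order, followed by any extra observed characters sorted.
    """
    canonical = list(datatype.canonical_alphabet)
    extra = sorted(
        {c for s in stats for c in s.char_counts} - set(canonical)
    )
    char_cols = canonical + extra
    lines = ["\t".join(FIXED_COLUMNS + tuple(char_cols))]
    for s in stats:
        row = [
            s.name,
            str(s.n_taxa),
            str(s.length),
            str(s.total_cells),
            str(s.undetermined_count),
            f"{s.missing_percent:.2f}",
            str(s.variable_count),
            _fmt_prop(s.variable_prop),
            str(s.informative_count),
            _fmt_prop(s.informative_prop),
            _fmt_prop(s.at_content),
            _fmt_prop(s.gc_content),
        ]
        row += [str(s.char_counts.get(c, 0)) for c in char_cols]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _summarize_one(args: tuple) -> tuple[SummaryStats | None, str | None]:
    path, in_format, datatype = args
    try:
        aln = read_file(path, in_format)
        return summarize(aln, datatype), None
    except Exception as exc:
        return None, f"{path}: {exc}"


def summarize_files(
    paths: Sequence[str | Path],
    in_format: FormatSpec,
    datatype: DataType,
    cores: int = 1,
) -> tuple[str, BatchResult]:
    """Summarize many files into one TSV table, optionally in parallel.

    Rows follow input path order regardless of ``cores``.  Files that fail
    to parse are logged and omitted from the table; the returned
    :class:`BatchResult` records them so callers can exit nonzero.
    """
    if not paths:
        raise AlignmentError("no input files")
    tasks = [(str(p), in_format, datatype) for p in paths]
    if cores > 1 and len(tasks) > 1:
        with Pool(processes=cores) as pool:
            results = pool.map(
                _summarize_one, tasks, chunksize=max(1, len(tasks) // (cores * 4))
            )
    else:
        results = [_summarize_one(t) for t in tasks]
    batch = BatchResult()
    stats: list[SummaryStats] = []
    for (st, err), task in zip(results, tasks):
        if err is not None:
            log.error("summary failed: %s", err)
            batch.failures.append((Path(task[0]), err))
        else:
            stats.append(st)
    return summary_table(stats, datatype), batch
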