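"""Readers and writers for the five supported alignment dialects.

Supported: FASTA (wrapped or single-line), PHYLIP sequential and
interleaved with relaxed taxon names (name terminated by whitespace, any
length), and NEXUS sequential and interleaved (DATA or CHARACTERS block).
The caller always declares the input format; there is no auto-detection.

Writers are exact inverses of the readers: for any valid alignment ``a``
and dialect ``f``, ``read_alignment(write_alignment(a, f), f)`` returns an
equal alignment.  Sequence case is preserved verbatim.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from multiprocessing import Pool
from pathlib import Path
from typing import Iterable, Sequence

from .core import Alignment, AlignmentError, DataType, FormatSpec, validate_alignment

log = logging.getLogger(__name__)

#: residues per line in interleaved output blocks
BLOCK_WIDTH = 60


class ParseError(AlignmentError):
    """Raised when a file's content cannot be interpreted under the declared format."""


@dataclass(frozen=True)
class ParsedFile:
    """An alignment plus informational metadata recovered during parsing."""

    alignment: Alignment
    detected_interleaving: bool = False


# ---------------------------------------------------------------------------
# reading


def parse_text(text: str, format: FormatSpec, source_name: str = "alignment") -> ParsedFile:
    """Parse the full content of one alignment file under a declared dialect."""
    if not text.strip():
        raise ParseError("empty input")
    if format is FormatSpec.FASTA:
        records, inter = _parse_fasta(text)
    elif format is FormatSpec.PHYLIP:
        records, inter = _parse_phylip_sequential(text)
    elif format is FormatSpec.PHYLIP_INT:
        records, inter = _parse_phylip_interleaved(text)
    else:
        records, inter = _parse_nexus(text)
    return ParsedFile(validate_alignment(records, source_name), inter)


def read_alignment(text: str, format: FormatSpec, source_name: str = "alignment") -> Alignment:
    """Parse alignment text; see :func:`parse_text`."""
    return parse_text(text, format, source_name).alignment


def read_file(path: str | Path, format: FormatSpec) -> Alignment:
    """Read one alignment file; the file stem becomes ``source_name``."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return read_alignment(text, format, source_name=path.stem)


def _parse_fasta(text: str) -> tuple[list[tuple[str, str]], bool]:
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            header = line[1:].strip()
            if not header:
                raise ParseError("FASTA record with empty description line")
            parts = header.split(None, 1)
            name = parts[0]
            if len(parts) > 1:
                log.info(
                    "FASTA description for %r truncated at first whitespace", name
                )
            chunks = []
        else:
            if name is None:
                raise ParseError("sequence data found before the first '>' header")
            chunks.append(re.sub(r"\s+", "", line))
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise ParseError("no FASTA records found")
    return records, False


def _phylip_header(line: str) -> tuple[int, int]:
    parts = line.split()
    if len(parts) < 2:
        raise ParseError(f"malformed PHYLIP header: {line!r}")
    try:
        ntax, nchar = int(parts[0]), int(parts[1])
    except ValueError:
        raise ParseError(f"malformed PHYLIP header: {line!r}") from None
    if ntax < 1 or nchar < 0:
        raise ParseError(f"implausible PHYLIP header counts: {line!r}")
    return ntax, nchar


def _parse_phylip_sequential(text: str) -> tuple[list[tuple[str, str]], bool]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    ntax, nchar = _phylip_header(lines[0])
    tokens = " ".join(lines[1:]).split()
    pos = 0
    records: list[tuple[str, str]] = []
    for _ in range(ntax):
        if pos >= len(tokens):
            raise ParseError(
                f"PHYLIP header declares {ntax} taxa but only "
                f"{len(records)} were found"
            )
        name = tokens[pos]
        pos += 1
        parts: list[str] = []
        got = 0
        # a token that would overshoot the declared length belongs to the
        # next record (its taxon name), so leave it unconsumed
        while got < nchar and pos < len(tokens) and got + len(tokens[pos]) <= nchar:
            parts.append(tokens[pos])
            got += len(tokens[pos])
            pos += 1
        seq = "".join(parts)
        if len(seq) != nchar:
            raise ParseError(
                f"taxon {name!r}: header declares {nchar} sites, found {len(seq)}"
            )
        records.append((name, seq))
    if pos < len(tokens):
        raise ParseError(
            f"unexpected data after {ntax} declared taxa "
            f"(starting at {tokens[pos]!r})"
        )
    return records, False


def _parse_phylip_interleaved(text: str) -> tuple[list[tuple[str, str]], bool]:
    raw = [ln for ln in text.splitlines() if ln.strip()]
    ntax, nchar = _phylip_header(raw[0])
    lines = raw[1:]
    if len(lines) < ntax:
        raise ParseError(
            f"PHYLIP header declares {ntax} taxa but only {len(lines)} "
            "matrix lines were found"
        )
    names: list[str] = []
    fragments: list[list[str]] = []
    for line in lines[:ntax]:
        parts = line.split()
        names.append(parts[0])
        fragments.append(["".join(parts[1:])])
    # Later blocks may or may not repeat the taxon names; lines cycle
    # through taxa in the order of the first block.
    for j, line in enumerate(lines[ntax:]):
        i = j % ntax
        parts = line.split()
        if parts and parts[0] == names[i]:
            parts = parts[1:]
        fragments[i].append("".join(parts))
    records = []
    for name, frags in zip(names, fragments):
        seq = "".join(frags)
        if len(seq) != nchar:
            raise ParseError(
                f"taxon {name!r}: header declares {nchar} sites, found {len(seq)}"
            )
        records.append((name, seq))
    return records, len(lines) > ntax


def _strip_nexus_comments(text: str) -> str:
    """Remove square-bracket comments (nesting allowed); newlines survive."""
    out: list[str] = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth > 0:
            depth -= 1
        elif depth == 0:
            out.append(ch)
        elif ch == "\n":
            out.append(ch)
    return "".join(out)


def _parse_nexus(text: str) -> tuple[list[tuple[str, str]], bool]:
    clean = _strip_nexus_comments(text)
    m = re.search(r"\bmatrix\b", clean, re.IGNORECASE)
    if m is None:
        raise ParseError("no recognizable MATRIX section in NEXUS input")
    body = clean[m.end():]
    end = body.find(";")
    if end < 0:
        raise ParseError("NEXUS MATRIX section is not terminated by ';'")
    body = body[:end]

    entries: list[tuple[str, str]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        name = parts[0].strip("'\"")
        entries.append((name, "".join(parts[1:])))
    if not entries:
        raise ParseError("NEXUS MATRIX section is empty")

    # First block = taxa until the first repeated name; every later block
    # must repeat the taxa in identical order (reordered blocks are rejected
    # rather than silently realigned).
    order: list[str] = []
    seen: set[str] = set()
    for name, _ in entries:
        if name in seen:
            break
        order.append(name)
        seen.add(name)
    nt = len(order)
    if len(entries) % nt != 0:
        raise ParseError(
            "interleaved NEXUS MATRIX blocks are ragged: "
            f"{len(entries)} lines over {nt} taxa"
        )
    frags: dict[str, list[str]] = {n: [] for n in order}
    n_blocks = len(entries) // nt
    for b in range(n_blocks):
        for k in range(nt):
            name, frag = entries[b * nt + k]
            if name != order[k]:
                raise ParseError(
                    f"taxa out of order in interleaved NEXUS block {b + 1}: "
                    f"expected {order[k]!r}, found {name!r}"
                )
            frags[name].append(frag)
    records = [(n, "".join(frags[n])) for n in order]

    ntax_m = re.search(r"ntax\s*=\s*(\d+)", clean, re.IGNORECASE)
    nchar_m = re.search(r"nchar\s*=\s*(\d+)", clean, re.IGNORECASE)
    if ntax_m and int(ntax_m.group(1)) != nt:
        raise ParseError(
            f"DIMENSIONS declares NTAX={ntax_m.group(1)} but {nt} taxa were parsed"
        )
    if nchar_m:
        nchar = int(nchar_m.group(1))
        for name, seq in records:
            if len(seq) != nchar:
                raise ParseError(
                    f"taxon {name!r}: DIMENSIONS declares NCHAR={nchar}, "
                    f"found {len(seq)}"
                )
    return records, n_blocks > 1


# ---------------------------------------------------------------------------
# writing


def write_alignment(
    aln: Alignment, format: FormatSpec, datatype: DataType = DataType.DNA
) -> str:
    """Compose alignment text in the requested dialect.

    ``datatype`` only affects the NEXUS FORMAT line (DATATYPE=DNA|PROTEIN).
    """
    if format is FormatSpec.FASTA:
        return _write_fasta(aln)
    if format is FormatSpec.PHYLIP:
        return _write_phylip(aln)
    if format is FormatSpec.PHYLIP_INT:
        return _write_phylip_interleaved(aln)
    return _write_nexus(aln, datatype, interleaved=format is FormatSpec.NEXUS_INT)


def write_file(
    aln: Alignment,
    format: FormatSpec,
    path: str | Path,
    datatype: DataType = DataType.DNA,
) -> Path:
    path = Path(path)
    path.write_text(write_alignment(aln, format, datatype))
    return path


def _write_fasta(aln: Alignment) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in aln.records)


def _name_width(aln: Alignment) -> int:
    return max(len(name) for name in aln.taxon_names)


def _write_phylip(aln: Alignment) -> str:
    w = _name_width(aln)
    lines = [f"{aln.n_taxa} {aln.length}"]
    for name, seq in aln.records:
        lines.append(f"{name:<{w}}  {seq}".rstrip())
    return "\n".join(lines) + "\n"


def _blocks(length: int) -> list[tuple[int, int]]:
    if length == 0:
        return [(0, 0)]
    return [(i, min(i + BLOCK_WIDTH, length)) for i in range(0, length, BLOCK_WIDTH)]


def _write_phylip_interleaved(aln: Alignment) -> str:
    w = _name_width(aln)
    lines = [f"{aln.n_taxa} {aln.length}"]
    for bi, (lo, hi) in enumerate(_blocks(aln.length)):
        if bi > 0:
            lines.append("")
        for name, seq in aln.records:
            if bi == 0:
                lines.append(f"{name:<{w}}  {seq[lo:hi]}".rstrip())
            else:
                lines.append(seq[lo:hi])
    return "\n".join(lines) + "\n"


def _write_nexus(aln: Alignment, datatype: DataType, interleaved: bool) -> str:
    w = _name_width(aln)
    dt = "DNA" if datatype is DataType.DNA else "PROTEIN"
    fmt = f"FORMAT DATATYPE={dt} MISSING=? GAP=-"
    if interleaved:
        fmt += " INTERLEAVE=YES"
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.length};",
        fmt + ";",
        "MATRIX",
    ]
    blocks = _blocks(aln.length) if interleaved else [(0, aln.length)]
    for bi, (lo, hi) in enumerate(blocks):
        if bi > 0:
            lines.append("")
        for name, seq in aln.records:
            lines.append(f"{name:<{w}}  {seq[lo:hi]}".rstrip())
    lines += [";", "END;"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# batch conversion


@dataclass
class BatchResult:
    """Outcome of a per-file batch operation."""

    outputs: list[Path] = field(default_factory=list)
    failures: list[tuple[Path, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def output_name(stem: str, format: FormatSpec) -> str:
    """Output filename convention: ``<input stem>.<dialect suffix>``."""
    return f"{stem}.{format.suffix}"


def _convert_one(args: tuple) -> tuple[str | None, str | None]:
    path, in_format, out_format, out_dir, datatype = args
    path = Path(path)
    try:
        aln = read_file(path, in_format)
        target_dir = Path(out_dir) if out_dir is not None else path.parent
        target = target_dir / output_name(path.stem, out_format)
        if target.resolve() == path.resolve():
            raise AlignmentError(
                f"output path {target} would overwrite the input file"
            )
        write_file(aln, out_format, target, datatype)
        return str(target), None
    except Exception as exc:  # per-file isolation: one bad file must not stop the batch
        return None, f"{path}: {exc}"


def convert_files(
    paths: Sequence[str | Path],
    in_format: FormatSpec,
    out_format: FormatSpec,
    cores: int = 1,
    out_dir: str | Path | None = None,
    datatype: DataType = DataType.DNA,
) -> BatchResult:
    """Convert many alignment files, one output per input, optionally in parallel.

    Input files are never modified.  Failures are logged and collected;
    remaining files still convert.  Output bytes are identical whatever
    ``cores`` is, because each output depends only on its own input and
    results are handled in input order.
    """
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    tasks = [(str(p), in_format, out_format, out_dir, datatype) for p in paths]
    if cores > 1 and len(tasks) > 1:
        with Pool(processes=cores) as pool:
            results = pool.map(_convert_one, tasks, chunksize=max(1, len(tasks) // (cores * 4)))
    else:
        results = [_convert_one(t) for t in tasks]
    batch = BatchResult()
    for (out, err), task in zip(results, tasks):
        if err is not None:
            log.error("conversion failed: %s", err)
            batch.failures.append((Path(task[0]), err))
        else:
            batch.outputs.append(Path(out))
    return batch
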