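"""Text-format boundary: FASTA, bedGraph, and BED dialects.

Internally the package uses 1-based inclusive genomic coordinates (browser
display convention). bedGraph/BED files are 0-based half-open; the readers
and writers convert at this boundary and nowhere else.

bedGraph dialect: 4 whitespace-separated columns (chrom, start, end, value),
``track``/``browser``/``#`` lines skipped on read, never written.
BED output is BED6.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


class FormatError(ValueError):
    """A file does not conform to the expected text dialect."""


# ---------------------------------------------------------------------------
# FASTA


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path_or_handle) -> list[FastaRecord]:
    """Parse a FASTA file.

    Record ids are the header token up to the first whitespace; sequences are
    upper-cased. CRLF and LF dialects parse identically. Duplicate ids and
    empty records are errors.
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        text = Path(path_or_handle).read_text()
    records: list[FastaRecord] = []
    seen: set[str] = set()
    current: FastaRecord | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty FASTA record: {current.id!r}")
        current.sequence = seq
        records.append(current)

    for raw in _io.StringIO(text):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            if not header:
                raise FormatError("FASTA header with no identifier")
            rid, _, desc = header.partition(" ")
            if rid in seen:
                raise FormatError(f"duplicate FASTA id: {rid!r}")
            seen.add(rid)
            current = FastaRecord(id=rid, sequence="", description=desc)
            chunks = []
        else:
            if current is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    _flush()
    return records


def write_fasta(path_or_handle, records: Iterable[FastaRecord], width: int = 60) -> None:
    def _emit(handle) -> None:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_bedgraph(path_or_handle) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph into 1-based inclusive (chrom, start, end, value)."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        lines = Path(path_or_handle).read_text().splitlines()
    out: list[tuple[str, int, int, float]] = []
    for n, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"bedGraph line {n}: expected 4 columns, got {len(parts)}")
        chrom, start, end, value = parts
        s, e = int(start), int(end)
        if e <= s:
            raise FormatError(f"bedGraph line {n}: empty or inverted interval")
        out.append((chrom, s + 1, e, float(value)))
    return out


def write_bedgraph(path_or_handle, intervals: Sequence[tuple[str, int, int, float]]) -> None:
    """Write 1-based inclusive intervals as 0-based half-open bedGraph lines."""

    def _emit(handle) -> None:
        for chrom, start, end, value in intervals:
            handle.write(f"{chrom}\t{start - 1}\t{end}\t{value:g}\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


def write_bed6(
    path_or_handle,
    features: Sequence[tuple[str, int, int, str, float, str]],
    score_scale: float = 1000.0,
) -> None:
    """Write BED6; scores given in [0, 1] are scaled to the BED 0-1000 range."""

    def _emit(handle) -> None:
        for chrom, start, end, name, score, strand in features:
            bed_score = int(round(max(0.0, min(1.0, score)) * score_scale))
            handle.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{bed_score}\t{strand}\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


def read_bed(path_or_handle) -> list[tuple[str, int, int, str, float, str]]:
    """Read BED3-6 into 1-based inclusive tuples (missing fields defaulted)."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        lines = Path(path_or_handle).read_text().splitlines()
    out = []
    for n, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"BED line {n}: fewer than 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"feature{n}"
        score = float(parts[4]) if len(parts) > 4 else 0.0
        strand = parts[5] if len(parts) > 5 else "."
        out.append((chrom, start + 1, end, name, score, strand))
    return out
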