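"""Block-structured TSV/CSV peak-list I/O.

MALDI/TOF peak lists are exchanged as plain tab- or comma-separated text
organised in *blocks*, one block per biological sample.  Within a block each
technical replicate occupies a pair of columns — the n-th spectrum uses
column ``2n-1`` for m/z (Da) and column ``2n`` for abundance.  Spectra of
different lengths are zero-padded: rows past the end of a shorter spectrum
carry ``0`` in both of its columns.  The first row of a block holds free-text
labels, the second row the column headers (``m/z`` / ``abund`` repeated).
Blocks are separated by a row whose first cell starts with ``\\\\``.

This module also writes the output file families produced by the pipeline:
plain two-column peak lists, isotopic-group reports, average spectra and
cross-spectrum alignments (TSV, plus an HTML rendering of the tabular
reports for human inspection).
"""

from __future__ import annotations

import csv
import html
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "Peak",
    "Spectrum",
    "SampleBlock",
    "AlignmentRow",
    "Alignment",
    "read_block_file",
    "parse_blocks",
    "write_block_file",
    "format_blocks",
    "write_peak_list",
    "write_average_spectrum",
    "write_alignment",
    "read_alignment",
    "write_isotopic_groups_report",
]

_HEADER_TOKENS = {"m/z", "mz", "abund", "abundance", "intensity"}


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


@dataclass(frozen=True, slots=True)
class Peak:
    """One detected signal: m/z in Da and abundance in arbitrary units."""

    mz: float
    abundance: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.abundance < 0:
            raise ValidationError(
                f"peak abundance must be non-negative, got {self.abundance}"
            )


@dataclass(frozen=True, slots=True)
class Spectrum:
    """An ordered peak list belonging to one sample replicate.

    ``peaks`` are strictly ascending in m/z; ``source`` identifies
    (sample id, replicate index).
    """

    label: str
    peaks: tuple[Peak, ...]
    source: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        for a, b in zip(self.peaks, self.peaks[1:]):
            if not a.mz < b.mz:
                raise ValidationError(
                    f"spectrum {self.label!r}: peaks not strictly ascending "
                    f"at m/z {a.mz} / {b.mz}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def total_abundance(self) -> float:
        return math.fsum(p.abundance for p in self.peaks)

    def replace_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return Spectrum(self.label, tuple(peaks), self.source)


@dataclass(frozen=True, slots=True)
class SampleBlock:
    """One input block: the replicate spectra of a single biological sample.

    ``label_row`` preserves the raw first row of the block so that a
    write/read cycle is the identity on parsed content.
    """

    sample_id: str
    spectra: tuple[Spectrum, ...]
    label_row: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.spectra) < 1:
            raise ValidationError("a sample block needs at least one spectrum")


@dataclass(frozen=True, slots=True)
class AlignmentRow:
    """One aligned signal across spectra.

    ``per_spectrum_mz`` / ``per_spectrum_abundance`` hold one optional value
    per aligned spectrum; ``None`` marks a spectrum in which the signal is
    absent (missing, not zero).  ``support`` counts the non-missing entries.
    """

    support: int
    mean_mz: float
    per_spectrum_mz: tuple[Optional[float], ...]
    mean_abundance: float
    per_spectrum_abundance: tuple[Optional[float], ...]

    def __post_init__(self) -> None:
        present = [v for v in self.per_spectrum_mz if v is not None]
        if self.support != len(present):
            raise ValidationError(
                f"support {self.support} != {len(present)} non-missing m/z entries"
            )
        if self.support < 1:
            raise ValidationError("an alignment row needs support >= 1")
        for mz, ab in zip(self.per_spectrum_mz, self.per_spectrum_abundance):
            if (mz is None) != (ab is None):
                raise ValidationError("m/z and abundance must be missing together")
        if present and abs(self.mean_mz - math.fsum(present) / len(present)) > 1e-6:
            raise ValidationError("mean_mz is not the mean of the per-spectrum m/z")


@dataclass(frozen=True, slots=True)
class Alignment:
    """Aligned rows across a fixed, ordered set of spectra."""

    spectrum_labels: tuple[str, ...]
    rows: tuple[AlignmentRow, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.rows, self.rows[1:]):
            if a.mean_mz > b.mean_mz:
                raise ValidationError("alignment rows must ascend in mean m/z")
        for row in self.rows:
            if len(row.per_spectrum_mz) != len(self.spectrum_labels):
                raise ValidationError("row width does not match spectrum count")


# ---------------------------------------------------------------------------
# block reader
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    """Tab wins over comma when both occur (comma may sit inside labels)."""
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


_DELIMS = {"tsv": "\t", "csv": ","}


def _parse_cell(cell: str, row_no: int, col_no: int) -> float:
    text = cell.strip()
    if text == "":
        return 0.0  # ragged spreadsheet exports: treat as padding
    if "," in text:
        raise ParseError(
            f"row {row_no}, column {col_no}: {cell!r} — comma decimal "
            "separators are not supported, use periods"
        )
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"row {row_no}, column {col_no}: {cell!r} is not a number"
        ) from None


def _is_separator(row: Sequence[str]) -> bool:
    return bool(row) and row[0].strip().startswith("\\")


def _is_header(row: Sequence[str]) -> bool:
    tokens = {c.strip().lower() for c in row if c.strip()}
    return bool(tokens & _HEADER_TOKENS)


def _parse_one_block(
    rows: list[tuple[int, list[str]]], block_index: int
) -> SampleBlock:
    label_row: Optional[tuple[str, ...]] = None
    header_row: Optional[list[str]] = None
    data_rows: list[tuple[int, list[str]]] = []
    for row_no, row in rows:
        if not data_rows and _is_header(row):
            header_row = row
            continue
        if label_row is None and header_row is None and not data_rows:
            # first row: labels unless it already looks numeric
            try:
                float(row[0].strip() or "x")
            except ValueError:
                label_row = tuple(c.strip() for c in row)
                continue
        data_rows.append((row_no, row))

    if data_rows:
        width = max(len(r) for _, r in data_rows)
        if width % 2:
            raise FormatError(
                f"block starting at row {data_rows[0][0]}: odd column count "
                f"({width}); spectra occupy (m/z, abundance) column pairs"
            )
        n_spectra = width // 2
    elif header_row is not None:
        n_spectra = max(1, len(header_row) // 2)
    else:
        # label-only block: one label per spectrum pair (or per sample)
        n_spectra = max(1, (len(label_row or ()) + 1) // 2)

    first_cell = (label_row[0] if label_row else "").strip()
    sample_id = first_cell if first_cell else f"sample_{block_index + 1}"

    spectra = []
    for i in range(n_spectra):
        peaks = []
        for row_no, row in data_rows:
            mz_cell = row[2 * i] if 2 * i < len(row) else ""
            ab_cell = row[2 * i + 1] if 2 * i + 1 < len(row) else ""
            mz = _parse_cell(mz_cell, row_no, 2 * i + 1)
            ab = _parse_cell(ab_cell, row_no, 2 * i + 2)
            if mz == 0.0 and ab == 0.0:
                continue  # zero padding of a shorter spectrum
            if mz < 0 or ab < 0:
                raise ValidationError(
                    f"row {row_no}, spectrum {i + 1}: negative value "
                    f"(m/z={mz}, abundance={ab})"
                )
            if mz == 0.0:
                raise ValidationError(
                    f"row {row_no}, spectrum {i + 1}: abundance {ab} with zero m/z"
                )
            peaks.append(Peak(mz, ab))
        if any(a.mz >= b.mz for a, b in zip(peaks, peaks[1:])):
            warnings.warn(
                f"spectrum {i + 1} of sample {sample_id!r} was not sorted by "
                "m/z; sorting",
                stacklevel=4,
            )
            peaks.sort(key=lambda p: p.mz)
        label = ""
        if label_row and 2 * i < len(label_row):
            label = label_row[2 * i]
        if not label:
            label = f"{sample_id}:{i + 1}"
        spectra.append(Spectrum(label, tuple(peaks), (sample_id, i)))
    return SampleBlock(sample_id, tuple(spectra), label_row)


def parse_blocks(text: str, dialect: Optional[str] = None) -> list[SampleBlock]:
    """Parse block-structured peak-list text into :class:`SampleBlock` objects.

    ``dialect`` is ``"tsv"``, ``"csv"`` or ``None`` to sniff the delimiter
    from the first line.
    """
    if dialect is None:
        first_line = text.splitlines()[0] if text.splitlines() else ""
        delim = _sniff_delimiter(first_line)
    else:
        try:
            delim = _DELIMS[dialect]
        except KeyError:
            raise ValidationError(f"unknown dialect {dialect!r}") from None

    reader = csv.reader(io.StringIO(text), delimiter=delim)
    blocks: list[SampleBlock] = []
    current: list[tuple[int, list[str]]] = []
    for row_no, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if _is_separator(row):
            if current:
                blocks.append(_parse_one_block(current, len(blocks)))
                current = []
            continue
        current.append((row_no, row))
    if current:
        blocks.append(_parse_one_block(current, len(blocks)))
    return blocks


def read_block_file(path, dialect: Optional[str] = None) -> list[SampleBlock]:
    """Read a block-structured TSV/CSV peak-list file.

    Returns one :class:`SampleBlock` per input block.  Zero-padding rows —
    ``(0, 0)`` in a spectrum's column pair — are dropped; a pair with a
    positive m/z and an abundance of exactly 0 is kept as a genuine
    zero-intensity peak.
    """
    text = Path(path).read_text()
    return parse_blocks(text, dialect)


# ---------------------------------------------------------------------------
# block writer
# ---------------------------------------------------------------------------

def format_blocks(blocks: Sequence[SampleBlock], dialect: str = "tsv") -> str:
    """Render sample blocks in the block peak-list layout (inverse of the reader)."""
    try:
        delim = _DELIMS[dialect]
    except KeyError:
        raise ValidationError(f"unknown dialect {dialect!r}") from None

    out = io.StringIO()
    writer = csv.writer(out, delimiter=delim, lineterminator="\n")
    for b_idx, block in enumerate(blocks):
        if b_idx:
            writer.writerow(["\\\\"])
        n = len(block.spectra)
        if block.label_row is not None:
            label_cells = list(block.label_row)
        else:
            label_cells = []
            for s in block.spectra:
                label_cells += [s.label, ""]
        writer.writerow(label_cells)
        header = []
        for _ in range(n):
            header += ["m/z", "abund"]
        writer.writerow(header)
        depth = max((len(s.peaks) for s in block.spectra), default=0)
        for r in range(depth):
            row = []
            for s in block.spectra:
                if r < len(s.peaks):
                    row += [_fmt(s.peaks[r].mz), _fmt(s.peaks[r].abundance)]
                else:
                    row += ["0", "0"]
            writer.writerow(row)
    return out.getvalue()


def write_block_file(blocks: Sequence[SampleBlock], path, dialect: str = "tsv") -> None:
    """Write sample blocks to ``path`` in the block peak-list format."""
    Path(path).write_text(format_blocks(blocks, dialect))


# ---------------------------------------------------------------------------
# output file families
# ---------------------------------------------------------------------------

def write_peak_list(spectrum: Spectrum, path) -> None:
    """Write a plain two-column (m/z, abundance) TSV peak list."""
    lines = ["m/z\tabund"]
    lines += [f"{_fmt(p.mz)}\t{_fmt(p.abundance)}" for p in spectrum.peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def write_average_spectrum(avg, path) -> None:
    """Write an average spectrum as a two-column (mean m/z, mean abundance) TSV.

    ``avg`` is an :class:`maldikit.align.AverageSpectrum`.
    """
    lines = ["m/z\tabund"]
    lines += [f"{_fmt(p.mean_mz)}\t{_fmt(p.mean_abundance)}" for p in avg.peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def _alignment_table(alignment: Alignment) -> tuple[list[str], list[list[str]]]:
    labels = list(alignment.spectrum_labels)
    header = ["n_spectra", "mz_avg", *labels, "abund_avg", *labels]
    rows = []
    for row in alignment.rows:
        cells = [str(row.support), _fmt(row.mean_mz)]
        cells += ["" if v is None else _fmt(v) for v in row.per_spectrum_mz]
        cells.append(_fmt(row.mean_abundance))
        cells += ["" if v is None else _fmt(v) for v in row.per_spectrum_abundance]
        rows.append(cells)
    return header, rows


def _html_table(title: str, header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    parts = [
        "<!DOCTYPE html>",
        f"<html><head><meta charset='utf-8'><title>{html.escape(title)}</title>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;text-align:right}</style></head><body>",
        f"<h1>{html.escape(title)}</h1>",
        "<table><tr>" + "".join(f"<th>{html.escape(h)}</th>" for h in header) + "</tr>",
    ]
    for row in rows:
        parts.append(
            "<tr>" + "".join(f"<td>{html.escape(c)}</td>" for c in row) + "</tr>"
        )
    parts.append("</table></body></html>")
    return "\n".join(parts)


def write_alignment(alignment: Alignment, path, mode: str = "tsv") -> None:
    """Write an alignment table.

    TSV layout per row: support count; mean m/z followed by one m/z column
    per aligned spectrum; mean abundance followed by one abundance column per
    spectrum.  Missing peaks are empty cells.  ``mode="html"`` renders the
    same table for readability.
    """
    header, rows = _alignment_table(alignment)
    if mode == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        Path(path).write_text("\n".join(lines) + "\n")
    elif mode == "html":
        Path(path).write_text(_html_table("Alignment", header, rows))
    else:
        raise ValidationError(f"unknown alignment output mode {mode!r}")


def read_alignment(path) -> Alignment:
    """Parse an alignment TSV written by :func:`write_alignment`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty alignment file")
    header = lines[0].split("\t")
    n = (len(header) - 3) // 2  # 1 + (1+n) + (1+n) columns
    labels = tuple(header[2 : 2 + n])
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        support = int(cells[0])
        mean_mz = float(cells[1])
        per_mz = tuple(float(c) if c else None for c in cells[2 : 2 + n])
        mean_ab = float(cells[2 + n])
        per_ab = tuple(float(c) if c else None for c in cells[3 + n : 3 + 2 * n])
        rows.append(AlignmentRow(support, mean_mz, per_mz, mean_ab, per_ab))
    return Alignment(labels, tuple(rows))


def write_isotopic_groups_report(groups, path, mode: str = "tsv") -> None:
    """Write the isotopic-group report: per retained peak, its source peaks.

    ``groups`` is a sequence of :class:`maldikit.preprocess.IsotopicGroup`.
    Each row lists the retained (monoisotopic) m/z, the summed abundance, the
    member count and the original (m/z, abundance) pairs joined into it.
    """
    header = ["mono_mz", "summed_abund", "n_members", "members"]
    rows = []
    for g in groups:
        members = "; ".join(
            f"({_fmt(p.mz)}, {_fmt(p.abundance)})" for p in g.members
        )
        rows.append(
            [_fmt(g.monoisotopic.mz), _fmt(g.monoisotopic.abundance),
             str(len(g.members)), members]
        )
    if mode == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        Path(path).write_text("\n".join(lines) + "\n")
    elif mode == "html":
        Path(path).write_text(_html_table("Isotopic groups", header, rows))
    else:
        raise ValidationError(f"unknown isotopic-group output mode {mode!r}")
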