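"""Readers/writers for BED, bedGraph and refGene-style tables, plus track
normalization.

All formats are the plain-text, tab-separated, 0-based half-open dialects
produced by the standard toolchain (MACS2 bedGraph output, UCSC table
browser exports). refGene ``txStart``/``txEnd`` already use this convention,
so no coordinate shifting happens anywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Sequence, Union

from .genome import GeneRecord, GenomicInterval, Peak, SignalTrack

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


class DegenerateTrackError(ValueError):
    """Operation undefined on a track with zero total mass."""


def _data_lines(path: PathLike) -> Iterable[tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            yield lineno, line.split("\t")


def _parse_int(text: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {text!r}") from None


def read_bed(path: PathLike) -> List[Peak]:
    """Load a BED3/BED5/BED6 file as a list of peaks.

    Column 4 becomes the peak name (``peak_<i>`` when absent), column 5 the
    score. Track/comment lines are skipped.
    """
    peaks: List[Peak] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
        chrom = cols[0]
        start = _parse_int(cols[1], "start", path, lineno)
        end = _parse_int(cols[2], "end", path, lineno)
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{len(peaks)}"
        score = None
        if len(cols) > 4 and cols[4] not in ("", "."):
            try:
                score = float(cols[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score {cols[4]!r}") from None
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
        try:
            peaks.append(Peak(GenomicInterval(chrom, start, end, strand), name, score))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    # names must be unique within one loaded set; suffix repeats
    seen: dict = {}
    out: List[Peak] = []
    for p in peaks:
        if p.name in seen:
            seen[p.name] += 1
            out.append(Peak(p.interval, f"{p.name}.{seen[p.name]}", p.score))
        else:
            seen[p.name] = 0
            out.append(p)
    return out


def write_bed(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end), p.name]
            if p.score is not None or p.interval.strand != ".":
                cols.append(repr(p.score) if p.score is not None else ".")
            if p.interval.strand != ".":
                cols.append(p.interval.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: PathLike) -> SignalTrack:
    """Load a 4-column bedGraph as a :class:`SignalTrack`.

    Values must be nonnegative; runs on one chromosome must not overlap
    (bookended runs are fine and are kept unmerged).
    """
    rows: List[tuple[str, int, int, float]] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        chrom = cols[0]
        start = _parse_int(cols[1], "start", path, lineno)
        end = _parse_int(cols[2], "end", path, lineno)
        try:
            value = float(cols[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value {cols[3]!r}") from None
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative value {value}")
        rows.append((chrom, start, end, value))
    try:
        return SignalTrack.from_runs(rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    """Write runs in sorted order; zero-value runs are omitted."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            if value == 0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_gene_table(path: PathLike, has_bin_column: bool = False) -> List[GeneRecord]:
    """Load a UCSC refGene-dialect table.

    Expected columns (after the optional leading numeric bin): name, chrom,
    strand, txStart, txEnd, and optionally a trailing gene symbol (full
    refGene rows carry it in column 13). Duplicate rows are retained —
    TSS deduplication is a separate, explicit step.
    """
    records: List[GeneRecord] = []
    for lineno, cols in _data_lines(path):
        if has_bin_column:
            cols = cols[1:]
        if len(cols) < 5:
            raise FormatError(f"{path}:{lineno}: expected >= 5 columns, got {len(cols)}")
        accession, chrom, strand = cols[0], cols[1], cols[2]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
        tx_start = _parse_int(cols[3], "txStart", path, lineno)
        tx_end = _parse_int(cols[4], "txEnd", path, lineno)
        symbol = cols[12] if len(cols) > 12 else (cols[5] if len(cols) > 5 else None)
        try:
            records.append(GeneRecord(accession, chrom, strand, tx_start, tx_end, symbol))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_gene_table(genes: Sequence[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cols = [g.accession, g.chrom, g.strand, str(g.tx_start), str(g.tx_end)]
            if g.gene_symbol is not None:
                cols.append(g.gene_symbol)
            fh.write("\t".join(cols) + "\n")


def normalize_track(track: SignalTrack, target_mass: float = 1e6) -> SignalTrack:
    """Scale every run so total mass equals ``target_mass``.

    This is the total-read-count normalization that makes tracks from
    libraries of different depth comparable (reads-per-million when
    ``target_mass`` is 1e6).
    """
    mass = track.total_mass
    if mass <= 0:
        raise DegenerateTrackError("cannot normalize a track with zero total mass")
    return track.scaled(target_mass / mass)
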