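"""Core genomic value types.

All coordinates are 0-based half-open (BED/bedGraph native). Strand is
``"+"``, ``"-"`` or ``"."`` (unstranded). A :class:`SignalTrack` is a
piecewise-constant, per-base coverage function: bases not covered by any
run have value 0, so window means are always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located half-open span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def edge_distance(self, other: "GenomicInterval") -> Optional[int]:
        """Gap between closest edges; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class Peak:
    """A named interval with an optional nonnegative score."""

    interval: GenomicInterval
    name: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be nonnegative, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneRecord:
    """One transcript row of a refGene-style table."""

    accession: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"txEnd must exceed txStart: [{self.tx_start}, {self.tx_end})"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        """5' end of the transcript: txStart on +, txEnd - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class SignalTrack:
    """Sparse per-base signal: sorted non-overlapping ``(start, end, value)`` runs.

    Runs are held per chromosome as three parallel numpy arrays to keep
    window queries cheap. Zero-value runs are permitted in memory but are
    equivalent to absent runs.
    """

    def __init__(
        self, runs: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None
    ) -> None:
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    def _set_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, v: np.ndarray) -> None:
        s = s.astype(np.int64)
        e = e.astype(np.int64)
        v = v.astype(np.float64)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("run arrays must have equal length")
        if np.any(e <= s):
            raise ValueError(f"{chrom}: every run must satisfy end > start")
        if np.any(s < 0):
            raise ValueError(f"{chrom}: negative run start")
        if np.any(v < 0):
            raise ValueError(f"{chrom}: negative signal value")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if len(s) > 1 and np.any(s[1:] < e[:-1]):
            i = int(np.argmax(s[1:] < e[:-1]))
            raise ValueError(
                f"{chrom}: overlapping runs "
                f"[{s[i]},{e[i]}) and [{s[i + 1]},{e[i + 1]})"
            )
        self._runs[chrom] = (s, e, v)

    @classmethod
    def from_runs(
        cls, runs: Iterable[Tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, rows in by_chrom.items():
            arr = np.asarray(rows, dtype=np.float64).reshape(-1, 3)
            track._set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
        return track

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._runs[chrom]

    def iter_runs(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in self.chroms:
            s, e, v = self._runs[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    @property
    def total_mass(self) -> float:
        """Sum over runs of value x length (analog of total read count)."""
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self._runs.values())
        )

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._runs.items()}
        )

    def without_zero_runs(self) -> "SignalTrack":
        out: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for c, (s, e, v) in self._runs.items():
            keep = v > 0
            if keep.any():
                out[c] = (s[keep], e[keep], v[keep])
        return SignalTrack(out)

    def equals(self, other: "SignalTrack", rtol: float = 0.0) -> bool:
        """Equality under the value-0 convention (zero runs ignored)."""
        a, b = self.without_zero_runs(), other.without_zero_runs()
        if a.chroms != b.chroms:
            return False
        for chrom in a.chroms:
            sa, ea, va = a.runs(chrom)
            sb, eb, vb = b.runs(chrom)
            if len(sa) != len(sb):
                return False
            if not (
                np.array_equal(sa, sb)
                and np.array_equal(ea, eb)
                and np.allclose(va, vb, rtol=rtol, atol=0.0)
            ):
                return False
        return True
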