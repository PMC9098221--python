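"""Windowed signal quantification over coverage tracks.

The intensity of an interval is its mean signal density per base
(total signal mass overlapping the interval divided by interval length),
the convention of matrix/metaprofile tools operating on coverage tracks.
Using the mean rather than the sum keeps clamped windows of unequal
length comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .genome import GenomicInterval, Peak, SignalTrack


@dataclass(frozen=True)
class DifferentialParams:
    """Pseudocount and fold threshold for intensity ratios.

    ``pseudocount`` is added symmetrically to numerator and denominator so
    zero-coverage windows give finite, antisymmetric log-ratios;
    ``fold_threshold`` is the linear fold change required to call an
    interval changed.
    """

    pseudocount: float = 0.25
    fold_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")


def window_intensity(track: SignalTrack, interval: GenomicInterval) -> float:
    """Mean signal density per base within ``interval`` (0 if uncovered)."""
    starts, ends, values = track.runs(interval.chrom)
    if len(starts) == 0:
        return 0.0
    # runs are sorted and disjoint: candidates are those with end > interval.start
    # and start < interval.end
    lo = int(np.searchsorted(ends, interval.start, side="right"))
    hi = int(np.searchsorted(starts, interval.end, side="left"))
    if lo >= hi:
        return 0.0
    s = np.maximum(starts[lo:hi], interval.start)
    e = np.minimum(ends[lo:hi], interval.end)
    mass = float(np.sum(values[lo:hi] * (e - s)))
    return mass / len(interval)


Anchor = Tuple[str, int, str]  # (chrom, position, strand)


def _as_anchor(obj: Union[Anchor, Peak, "object"]) -> Anchor:
    if isinstance(obj, tuple):
        return obj
    if isinstance(obj, Peak):
        return (obj.chrom, obj.interval.midpoint, obj.interval.strand)
    # duck-typed PromoterTSS
    return (obj.chrom, obj.tss, obj.strand)


@dataclass
class IntensityMatrix:
    """Binned intensities around a list of anchors.

    Rows follow the anchor order; minus-strand rows are stored reversed so
    that columns always run upstream -> downstream of transcription. The
    aggregate metaprofile is the column mean.
    """

    values: np.ndarray  # (n_anchors, n_bins)
    row_names: List[str]
    bin_starts: np.ndarray  # offsets of bin left edges relative to the anchor

    @property
    def aggregate(self) -> np.ndarray:
        if self.values.size == 0:
            return np.zeros(self.values.shape[1])
        return self.values.mean(axis=0)


def profile_matrix(
    track: SignalTrack,
    anchors: Sequence[Union[Anchor, Peak, "object"]],
    flank_bp: int,
    bin_bp: int,
    row_names: Optional[Sequence[str]] = None,
) -> IntensityMatrix:
    """Per-anchor binned intensity over ``anchor +/- flank_bp``.

    ``flank_bp`` must be divisible by ``bin_bp``. Each cell is the
    window intensity of its bin; bins falling below position 0 score 0
    (uncovered by convention).
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    rows = np.zeros((len(anchors), n_bins))
    names: List[str] = []
    for i, raw in enumerate(anchors):
        chrom, pos, strand = _as_anchor(raw)
        names.append(row_names[i] if row_names is not None else f"anchor_{i}")
        for j, off in enumerate(offsets):
            if strand == "-":
                # mirror: bin j covers transcription-relative [off, off+bin),
                # i.e. genomic [pos - off - bin + 1, pos - off + 1)
                start = pos - int(off) - bin_bp + 1
                end = pos - int(off) + 1
            else:
                start = pos + int(off)
                end = start + bin_bp
            if end <= 0:
                continue
            start = max(start, 0)
            rows[i, j] = window_intensity(
                track, GenomicInterval(chrom, start, end)
            ) * (end - start) / bin_bp
    return IntensityMatrix(rows, names, offsets)


def log2_ratio(a: float, b: float, params: DifferentialParams = DifferentialParams()) -> float:
    """``log2((a + eps) / (b + eps))``; undefined at a = b = 0 with eps = 0."""
    eps = params.pseudocount
    if a + eps == 0 or b + eps == 0:
        raise ValueError("log2_ratio undefined: zero intensity with zero pseudocount")
    return float(np.log2((a + eps) / (b + eps)))
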