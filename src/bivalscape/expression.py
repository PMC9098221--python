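"""DEG thresholding on consumed expression tables, linkage of peaks to DEG
TSSs, mean differential intensity, and Wilcoxon rank tests.

Differential expression itself (the count model) is consumed from an
upstream table; only the printed thresholding rule — p <= 0.05 and fold
change >= 1.5, boundaries inclusive, down-regulation via the reciprocal —
is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PromoterTSS
from .genome import GenomicInterval, Peak, SignalTrack
from .quant import DifferentialParams, log2_ratio, window_intensity


class DEGDirection(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene row of an expression table; fold_change is a linear ratio
    (knockdown over control)."""

    gene: str
    value_control: float
    value_kd: float
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if self.value_control < 0 or self.value_kd < 0 or self.fold_change < 0:
            raise ValueError("expression values and fold change must be >= 0")


def read_expression_table(path: Union[str, Path]) -> List[ExpressionRecord]:
    """TSV with columns gene, value_ctrl, value_kd, fold_change, p_value."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "value_ctrl", "value_kd", "fold_change", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ExpressionRecord(
            str(r.gene),
            float(r.value_ctrl),
            float(r.value_kd),
            float(r.fold_change),
            float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


def filter_degs(
    records: Sequence[ExpressionRecord],
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> List[DEGDirection]:
    """UP/DOWN/NONE per record; boundary values are included (<=, >=)."""
    calls: List[DEGDirection] = []
    for r in records:
        if r.p_value <= p_max and r.fold_change >= fc_min:
            calls.append(DEGDirection.UP)
        elif r.p_value <= p_max and r.fold_change <= 1.0 / fc_min:
            calls.append(DEGDirection.DOWN)
        else:
            calls.append(DEGDirection.NONE)
    return calls


@dataclass(frozen=True)
class TSSLink:
    """The closest in-range peaks for one DEG TSS (either may be absent)."""

    tss: PromoterTSS
    brg1_peak: Optional[Peak]
    brg1_distance: Optional[int]
    atac_peak: Optional[Peak]
    atac_distance: Optional[int]


def _closest_peak(
    tss: PromoterTSS, peaks: Sequence[Peak], max_dist: int
) -> Tuple[Optional[Peak], Optional[int]]:
    anchor = GenomicInterval(tss.chrom, tss.tss, tss.tss + 1)
    best: Optional[Tuple[int, int, int, int]] = None  # (dist, not_upstream, start, idx)
    for i, p in enumerate(peaks):
        d = anchor.edge_distance(p.interval)
        if d is None or d > max_dist:
            continue
        # a peak is transcription-upstream when its midpoint lies 5' of the TSS
        mid = p.interval.midpoint
        upstream = mid < tss.tss if tss.strand == "+" else mid > tss.tss
        key = (d, 0 if upstream else 1, p.start, i)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return peaks[best[3]], best[0]


def link_peaks_to_deg_tss(
    deg_tss_list: Sequence[PromoterTSS],
    brg1_peaks: Sequence[Peak],
    atac_peaks: Sequence[Peak],
    brg1_max_dist: int = 2000,
    atac_max_dist: int = 500,
) -> List[TSSLink]:
    """Closest BRG1 peak within 2 kb and closest ATAC peak within 500 bp of
    each DEG TSS; equidistant ties resolve toward the upstream peak, then by
    genomic position."""
    return [
        TSSLink(
            tss,
            *_closest_peak(tss, brg1_peaks, brg1_max_dist),
            *_closest_peak(tss, atac_peaks, atac_max_dist),
        )
        for tss in deg_tss_list
    ]


def mean_differential(
    linked_peaks: Sequence[Peak],
    control_track: SignalTrack,
    kd_track: SignalTrack,
    params: DifferentialParams = DifferentialParams(),
) -> float:
    """Mean over peaks of log2((kd + eps) / (control + eps)) interval intensity."""
    if len(linked_peaks) == 0:
        raise ValueError("mean differential of an empty peak set is undefined")
    ratios = [
        log2_ratio(
            window_intensity(kd_track, p.interval),
            window_intensity(control_track, p.interval),
            params,
        )
        for p in linked_peaks
    ]
    return float(np.mean(ratios))


def rank_tests(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
    exact_max_n: int = 10,
) -> float:
    """Two-sided Wilcoxon p-value: signed-rank when paired, rank-sum otherwise.

    Exact null enumeration up to ``exact_max_n`` per sample; the normal
    approximation with continuity correction beyond that.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank tests require non-empty samples")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        if np.all(d == 0):
            raise ValueError("degenerate paired test: all differences are zero")
        method = "exact" if a.size <= exact_max_n and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method, correction=True)
    else:
        method = (
            "exact"
            if a.size <= exact_max_n
            and b.size <= exact_max_n
            and np.unique(np.concatenate([a, b])).size == a.size + b.size
            else "asymptotic"
        )
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
    return float(res.pvalue)
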