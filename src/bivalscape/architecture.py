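"""TSS subregion architecture and the five-cluster change taxonomy.

Active promoters carry two flanking BRG1 maxima at the -1 and +1
nucleosomes, separated by the nucleosome-free region (NFR) at the TSS.
Three transcription-oriented subregions capture this architecture:
Upstream and Downstream brackets over the two nucleosomal BRG1 maxima and
a Center bracket over the NFR/accessibility maximum. Fold changes of BRG1
occupancy between control and knockdown in the Upstream/Downstream pair
define five clusters of affected TSSs: both down; upstream-only down;
downstream-only down; and the two compensatory down/up patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from .catalog import PromoterTSS
from .genome import GenomicInterval, SignalTrack
from .quant import DifferentialParams, window_intensity


class ChangeCall(str, Enum):
    DECREASED = "DECREASED"
    INCREASED = "INCREASED"
    UNCHANGED = "UNCHANGED"


class ClusterLabel(str, Enum):
    CLUSTER1 = "Cluster1"
    CLUSTER2 = "Cluster2"
    CLUSTER3 = "Cluster3"
    CLUSTER4 = "Cluster4"
    CLUSTER5 = "Cluster5"
    UNCLUSTERED = "UNCLUSTERED"


# (upstream call, downstream call) -> cluster
CLUSTER_TABLE: Dict[Tuple[ChangeCall, ChangeCall], ClusterLabel] = {
    (ChangeCall.DECREASED, ChangeCall.DECREASED): ClusterLabel.CLUSTER1,
    (ChangeCall.DECREASED, ChangeCall.UNCHANGED): ClusterLabel.CLUSTER2,
    (ChangeCall.UNCHANGED, ChangeCall.DECREASED): ClusterLabel.CLUSTER3,
    (ChangeCall.DECREASED, ChangeCall.INCREASED): ClusterLabel.CLUSTER4,
    (ChangeCall.INCREASED, ChangeCall.DECREASED): ClusterLabel.CLUSTER5,
}


@dataclass(frozen=True)
class RegionOffsets:
    """Subregion spans in bp relative to the TSS, transcription-oriented.

    Defaults bracket canonical -1/+1 nucleosome positions: upstream
    [-300, -100), center [-100, +100), downstream [+100, +300). Spans must
    be ordered and disjoint.
    """

    upstream_span: Tuple[int, int] = (-300, -100)
    center_span: Tuple[int, int] = (-100, 100)
    downstream_span: Tuple[int, int] = (100, 300)

    def __post_init__(self) -> None:
        spans = [self.upstream_span, self.center_span, self.downstream_span]
        for lo, hi in spans:
            if hi <= lo:
                raise ValueError(f"empty subregion span ({lo}, {hi})")
        for (_, a_hi), (b_lo, _) in zip(spans, spans[1:]):
            if b_lo < a_hi:
                raise ValueError("subregion spans must be ordered and disjoint")


@dataclass(frozen=True)
class RegionTriplet:
    upstream: GenomicInterval
    center: GenomicInterval
    downstream: GenomicInterval


def _place(chrom: str, tss: int, strand: str, span: Tuple[int, int]) -> GenomicInterval:
    lo, hi = span
    if strand == "-":
        # mirror about the TSS base: transcription-relative [lo, hi)
        # maps to genomic [tss - hi + 1, tss - lo + 1)
        start, end = tss - hi + 1, tss - lo + 1
    else:
        start, end = tss + lo, tss + hi
    return GenomicInterval(chrom, max(0, start), end, strand)


def define_regions(
    p: PromoterTSS, offsets: RegionOffsets = RegionOffsets()
) -> RegionTriplet:
    """Place the Upstream/Center/Downstream triplet at a promoter."""
    return RegionTriplet(
        upstream=_place(p.chrom, p.tss, p.strand, offsets.upstream_span),
        center=_place(p.chrom, p.tss, p.strand, offsets.center_span),
        downstream=_place(p.chrom, p.tss, p.strand, offsets.downstream_span),
    )


def call_change(
    control_intensity: float,
    kd_intensity: float,
    params: DifferentialParams = DifferentialParams(),
) -> ChangeCall:
    """Three-way fold-change call with pseudocount stabilization."""
    c = control_intensity + params.pseudocount
    k = kd_intensity + params.pseudocount
    if c <= 0 or k <= 0:
        raise ValueError("fold-change call undefined: zero intensity, zero pseudocount")
    if c / k >= params.fold_threshold:
        return ChangeCall.DECREASED
    if k / c >= params.fold_threshold:
        return ChangeCall.INCREASED
    return ChangeCall.UNCHANGED


def assign_cluster(up: ChangeCall, down: ChangeCall) -> ClusterLabel:
    """Map an (upstream, downstream) call pair to its cluster."""
    return CLUSTER_TABLE.get((up, down), ClusterLabel.UNCLUSTERED)


def region_change_calls(
    p: PromoterTSS,
    control_track: SignalTrack,
    kd_track: SignalTrack,
    offsets: RegionOffsets = RegionOffsets(),
    params: DifferentialParams = DifferentialParams(),
) -> Tuple[ChangeCall, ChangeCall]:
    """(upstream, downstream) fold-change calls for one promoter."""
    triplet = define_regions(p, offsets)
    up = call_change(
        window_intensity(control_track, triplet.upstream),
        window_intensity(kd_track, triplet.upstream),
        params,
    )
    down = call_change(
        window_intensity(control_track, triplet.downstream),
        window_intensity(kd_track, triplet.downstream),
        params,
    )
    return up, down


def select_decreased_tss(
    catalog: Sequence[PromoterTSS],
    control_track: SignalTrack,
    kd_track: SignalTrack,
    offsets: RegionOffsets = RegionOffsets(),
    params: DifferentialParams = DifferentialParams(),
) -> List[PromoterTSS]:
    """TSSs with a DECREASED call in at least one flanking region.

    Dropping low-activity promoter classes (e.g. H3K4me3-Low) from the
    result is the caller's explicit, separate step.
    """
    selected: List[PromoterTSS] = []
    for p in catalog:
        up, down = region_change_calls(p, control_track, kd_track, offsets, params)
        if ChangeCall.DECREASED in (up, down):
            selected.append(p)
    return selected


def cluster_catalog(
    catalog: Sequence[PromoterTSS],
    control_track: SignalTrack,
    kd_track: SignalTrack,
    offsets: RegionOffsets = RegionOffsets(),
    params: DifferentialParams = DifferentialParams(),
) -> List[ClusterLabel]:
    """Cluster label for every promoter (UNCLUSTERED when no region decreased)."""
    labels: List[ClusterLabel] = []
    for p in catalog:
        up, down = region_change_calls(p, control_track, kd_track, offsets, params)
        labels.append(assign_cluster(up, down))
    return labels
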