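"""Recovery evaluation of the pipeline against synthetic ground truth.

These helpers run the full analysis on generator output and score it
against the truth table: promoter-class label accuracy, cluster label
accuracy on the promoters the analysis targets (the non-H3K4me3-Low
classes, whose BRG1 architecture carries the knockdown effects), and mean
absolute error of per-region log2 fold-change estimates.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .architecture import define_regions, region_change_calls
from .catalog import build_catalog
from .classify import PromoterClass, classify_promoters
from .io import normalize_track
from .pipeline import mark_intensities
from .quant import window_intensity
from .simulate import SyntheticConfig, generate_gene_table, generate_tracks

_LOW = PromoterClass.H3K4ME3_LOW.value


def class_recovery(config: SyntheticConfig) -> Tuple[float, int]:
    """Fraction of promoters whose quartile class matches the truth."""
    genes, truth = generate_gene_table(config)
    tracks = generate_tracks(config, truth)
    catalog = build_catalog(genes, chrom_lengths=truth.chrom_lengths)
    k4 = mark_intensities(catalog, [tracks["h3k4me3_control"]])
    k27 = mark_intensities(catalog, [tracks["h3k27me3_control"]])
    labels = classify_promoters(k4, k27)
    hits = sum(
        lab.value == t for lab, t in zip(labels, truth.promoters.promoter_class)
    )
    return hits / len(catalog), len(catalog)


def cluster_recovery(config: SyntheticConfig) -> Tuple[float, int]:
    """Cluster-label accuracy on non-Low promoters, tracks depth-normalized."""
    genes, truth = generate_gene_table(config)
    tracks = generate_tracks(config, truth)
    catalog = build_catalog(genes, chrom_lengths=truth.chrom_lengths)
    ctrl = normalize_track(tracks["brg1_control"])
    kd = normalize_track(tracks["brg1_kd"])
    hits = total = 0
    for p, row in zip(catalog, truth.promoters.itertuples(index=False)):
        if row.promoter_class == _LOW:
            continue
        from .architecture import assign_cluster

        up, down = region_change_calls(p, ctrl, kd)
        predicted = assign_cluster(up, down).value
        expected = "UNCLUSTERED" if row.cluster == "NONE" else row.cluster
        hits += predicted == expected
        total += 1
    return hits / total, total


def effect_recovery_mae(config: SyntheticConfig) -> Tuple[float, int]:
    """Mean |estimated - injected| log2 fold change over flanking regions.

    Estimated on depth-matched raw tracks with no pseudocount: the
    generator produces both conditions at identical sequencing depth, so
    the raw ratio is the unbiased estimate of the injected effect.
    """
    genes, truth = generate_gene_table(config)
    tracks = generate_tracks(config, truth)
    catalog = build_catalog(genes, chrom_lengths=truth.chrom_lengths)
    errors = []
    for p, row in zip(catalog, truth.promoters.itertuples(index=False)):
        if row.promoter_class == _LOW:
            continue
        triplet = define_regions(p)
        for region, injected in (
            (triplet.upstream, row.up_effect),
            (triplet.downstream, row.down_effect),
        ):
            c = window_intensity(tracks["brg1_control"], region)
            k = window_intensity(tracks["brg1_kd"], region)
            errors.append(abs(float(np.log2(k / c)) - injected))
    return float(np.mean(errors)), len(errors)
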