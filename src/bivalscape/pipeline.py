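"""End-to-end orchestration: simulate -> catalog -> classify -> cluster ->
peak algebra -> DEG linkage -> summary.

Every stage writes a plain-text table; the summary JSON collects the
headline numbers (class counts, cluster counts, High/Low sizes, mean
differential intensities). Runs are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .architecture import (
    ChangeCall,
    ClusterLabel,
    RegionOffsets,
    assign_cluster,
    region_change_calls,
)
from .catalog import CatalogParams, PromoterTSS, build_catalog
from .classify import ClassifierParams, PromoterClass, classify_promoters
from .expression import (
    DEGDirection,
    filter_degs,
    link_peaks_to_deg_tss,
    mean_differential,
)
from .genome import Peak, SignalTrack
from .peaks import assign_nearby, merge_peaks, split_high_low
from .quant import DifferentialParams, window_intensity
from .simulate import SyntheticConfig, simulate_all

logger = logging.getLogger("bivalscape")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every tunable of the full run, with the printed-constant defaults."""

    outdir: str = "bivalscape_out"
    seed: int = 0
    simulation: SyntheticConfig = field(default_factory=SyntheticConfig)
    catalog: CatalogParams = field(default_factory=CatalogParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    offsets: RegionOffsets = field(default_factory=RegionOffsets)
    differential: DifferentialParams = field(default_factory=DifferentialParams)
    brg1_link_bp: int = 2000
    atac_link_bp: int = 500
    assign_max_dist_bp: int = 2000
    target_mass: float = 1e6
    write_tracks: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        kwargs: dict = {}
        for key, sub_cls in (
            ("simulation", SyntheticConfig),
            ("catalog", CatalogParams),
            ("classifier", ClassifierParams),
            ("offsets", RegionOffsets),
            ("differential", DifferentialParams),
        ):
            if key in raw:
                sub = raw.pop(key)
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def mark_intensities(
    catalog: Sequence[PromoterTSS],
    tracks: Sequence[SignalTrack],
    target_mass: float = 1e6,
) -> np.ndarray:
    """Per-promoter window intensity, averaged over replicate tracks after
    per-track normalization."""
    normed = [bio.normalize_track(t, target_mass) for t in tracks]
    vals = np.zeros((len(normed), len(catalog)))
    for i, t in enumerate(normed):
        vals[i] = [window_intensity(t, p.window) for p in catalog]
    return vals.mean(axis=0)


def run_all(config: PipelineConfig) -> Dict:
    """Execute every stage in dependency order; returns the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("parameters: %s", config)

    sim_config = config.simulation
    if sim_config.seed != config.seed:
        sim_config = SyntheticConfig(**{**sim_config.__dict__, "seed": config.seed})

    bundle = _stage("simulate")(simulate_all)(sim_config)
    genes, truth, tracks = bundle["genes"], bundle["truth"], bundle["tracks"]
    brg1_peaks, atac_peaks = bundle["brg1_peaks"], bundle["atac_peaks"]

    bio.write_gene_table(genes, out / "genes.refgene.txt")
    bio.write_bed(brg1_peaks, out / "brg1_peaks.bed")
    bio.write_bed(atac_peaks, out / "atac_peaks.bed")
    truth.promoters.to_csv(out / "truth.tsv", sep="\t", index=False)
    if config.write_tracks:
        for name, track in tracks.items():
            bio.write_bedgraph(track, out / f"{name}.bedgraph")

    catalog = _stage("catalog")(build_catalog)(
        genes, config.catalog, truth.chrom_lengths
    )

    # promoter classification from the two mark tracks
    k4 = _stage("quantify")(mark_intensities)(
        catalog, [tracks["h3k4me3_control"]], config.target_mass
    )
    k27 = mark_intensities(catalog, [tracks["h3k27me3_control"]], config.target_mass)
    classes = _stage("classify")(classify_promoters)(k4, k27, config.classifier)

    class_df = pd.DataFrame(
        {
            "name": [p.name for p in catalog],
            "chrom": [p.chrom for p in catalog],
            "strand": [p.strand for p in catalog],
            "tss": [p.tss for p in catalog],
            "h3k4me3": k4,
            "h3k27me3": k27,
            "promoter_class": [c.value for c in classes],
        }
    )
    class_df.to_csv(out / "classes.tsv", sep="\t", index=False, float_format="%.6g")

    # BRG1 region fold-changes and clusters on depth-normalized tracks
    @_stage("cluster-tss")
    def _cluster():
        ctrl = bio.normalize_track(tracks["brg1_control"], config.target_mass)
        kd = bio.normalize_track(tracks["brg1_kd"], config.target_mass)
        rows = []
        for p, cls in zip(catalog, classes):
            up, down = region_change_calls(
                p, ctrl, kd, config.offsets, config.differential
            )
            cluster = assign_cluster(up, down)
            decreased = ChangeCall.DECREASED in (up, down)
            rows.append(
                {
                    "name": p.name,
                    "promoter_class": cls.value,
                    "up_call": up.value,
                    "down_call": down.value,
                    "decreased": decreased,
                    "cluster": cluster.value,
                }
            )
        return pd.DataFrame(rows)

    cluster_df = _cluster()
    cluster_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    selected = cluster_df[
        cluster_df.decreased
        & (cluster_df.promoter_class != PromoterClass.H3K4ME3_LOW.value)
    ]

    # peak algebra: merge, nearby assignment, equal High/Low split
    @_stage("assign")
    def _peaks():
        if not atac_peaks:
            raise FileNotFoundError("no ATAC peak set available")
        merged = merge_peaks(brg1_peaks)
        assignments = assign_nearby(brg1_peaks, atac_peaks, config.assign_max_dist_bp)
        ctrl = bio.normalize_track(tracks["brg1_control"], config.target_mass)
        anchors = sorted({a.anchor_peak for a in assignments}, key=lambda p: (p.chrom, p.start, p.name))
        keys = [window_intensity(ctrl, p.interval) for p in anchors]
        split = split_high_low(anchors, keys)
        return merged, assignments, split

    merged, assignments, split = _peaks()
    bio.write_bed(merged, out / "merged_peaks.bed")
    pd.DataFrame(
        {
            "anchor": [a.anchor_peak.name for a in assignments],
            "assigned": [a.assigned_peak.name for a in assignments],
            "distance": [a.edge_distance for a in assignments],
        }
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)

    # DEG thresholding and peak linkage
    @_stage("link-deg")
    def _link():
        records = bundle["expression"]
        calls = filter_degs(records)
        down_symbols = {
            r.gene for r, c in zip(records, calls) if c == DEGDirection.DOWN
        }
        symbol_by_name = dict(zip(truth.promoters.name, truth.promoters.symbol))
        down_tss = [
            p
            for p in catalog
            if any(symbol_by_name.get(acc) in down_symbols for acc in p.member_accessions)
        ]
        links = link_peaks_to_deg_tss(
            down_tss, brg1_peaks, atac_peaks, config.brg1_link_bp, config.atac_link_bp
        )
        linked_brg1 = [l.brg1_peak for l in links if l.brg1_peak is not None]
        linked_atac = [l.atac_peak for l in links if l.atac_peak is not None]
        diffs = {}
        if linked_brg1:
            diffs["brg1"] = mean_differential(
                linked_brg1,
                bio.normalize_track(tracks["brg1_control"], config.target_mass),
                bio.normalize_track(tracks["brg1_kd"], config.target_mass),
                config.differential,
            )
        if linked_atac:
            diffs["atac"] = mean_differential(
                linked_atac,
                bio.normalize_track(tracks["atac_control"], config.target_mass),
                bio.normalize_track(tracks["atac_kd"], config.target_mass),
                config.differential,
            )
        return calls, down_tss, links, diffs

    calls, down_tss, links, diffs = _link()

    class_counts = class_df.promoter_class.value_counts().to_dict()
    cluster_counts = (
        selected.cluster.value_counts().to_dict() if len(selected) else {}
    )
    summary = {
        "n_genes": len(genes),
        "n_promoters": len(catalog),
        "class_counts": {k.value: int(class_counts.get(k.value, 0)) for k in PromoterClass},
        "n_decreased_tss": int(cluster_df.decreased.sum()),
        "n_decreased_tss_excl_low": int(len(selected)),
        "cluster_counts": {
            k.value: int(cluster_counts.get(k.value, 0))
            for k in ClusterLabel
            if k is not ClusterLabel.UNCLUSTERED
        },
        "n_merged_peaks": len(merged),
        "n_assignments": len(assignments),
        "high_low_sizes": [len(split.high), len(split.low)],
        "n_down_degs": sum(1 for c in calls if c == DEGDirection.DOWN),
        "n_down_deg_tss": len(down_tss),
        "n_linked_brg1": sum(1 for l in links if l.brg1_peak is not None),
        "n_linked_atac": sum(1 for l in links if l.atac_peak is not None),
        "mean_differential_log2": {k: round(v, 6) for k, v in diffs.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
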