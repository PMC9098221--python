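"""Synthetic chromatin-landscape generator with known ground truth.

Emulates the promoter architecture the pipeline quantifies: per-class
H3K4me3/H3K27me3 plateau levels over the -500/+1000 promoter window,
BRG1 concentrated in two Gaussian bumps at the -1/+1 nucleosome positions
flanking an accessible NFR bump at the TSS, and knockdown-induced
region-specific BRG1 losses following a five-cluster taxonomy. Sequencing
noise is Poisson fragment sampling per fixed-width bin.

Everything is deterministic under ``SyntheticConfig.seed``; each public
generator derives its own substream so the functions can be called in any
order or independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .architecture import ClusterLabel
from .catalog import CatalogParams, promoter_window
from .classify import PromoterClass
from .expression import ExpressionRecord
from .genome import GeneRecord, GenomicInterval, Peak, SignalTrack

ASSAYS = ("brg1", "atac", "h3k4me3", "h3k27me3")
CONDITIONS = ("control", "kd")

_UNAFFECTED = "NONE"


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions.

    Densities are in signal units per base; a level of 1.0 produces an
    expected 1.0 fragments per base at ``depth`` 1. ``kd_effect_log2``
    gives the (upstream, downstream) log2 fold change applied to the two
    BRG1 nucleosomal bumps for each cluster.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 2_000_000
    n_genes: int = 400
    fraction_noncoding: float = 0.10  # NR_ accessions
    fraction_short: float = 0.05  # transcripts < 2 kb
    fraction_duplicate_tss: float = 0.10  # extra transcript at an existing TSS
    # (Low, Only, Bivalent) mirroring the 5,982/12,305/5,640 proportions
    class_proportions: Tuple[float, float, float] = (0.25, 0.51, 0.24)
    # per-class (H3K4me3, H3K27me3) plateau densities over the promoter window
    mark_levels: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            PromoterClass.H3K4ME3_LOW.value: (1.0, 2.0),
            PromoterClass.H3K4ME3_ONLY.value: (10.0, 1.0),
            PromoterClass.BIVALENT.value: (8.0, 8.0),
        }
    )
    # -1/+1 nucleosome bump centers relative to the TSS (transcription-oriented)
    brg1_offsets: Tuple[int, int] = (-200, 150)
    brg1_sigma: float = 50.0
    # BRG1/accessibility amplitude per class: high in Only, moderate in
    # bivalent, low in Low
    brg1_amplitude: Dict[str, float] = field(
        default_factory=lambda: {
            PromoterClass.H3K4ME3_LOW.value: 0.5,
            PromoterClass.H3K4ME3_ONLY.value: 8.0,
            PromoterClass.BIVALENT.value: 4.0,
        }
    )
    nfr_atac_amplitude: Dict[str, float] = field(
        default_factory=lambda: {
            PromoterClass.H3K4ME3_LOW.value: 0.3,
            PromoterClass.H3K4ME3_ONLY.value: 8.0,
            PromoterClass.BIVALENT.value: 4.0,
        }
    )
    atac_sigma: float = 60.0
    # over (Cluster1..Cluster5, unaffected); Low-class promoters are always
    # unaffected (they carry almost no BRG1 to lose)
    cluster_proportions: Tuple[float, ...] = (0.12, 0.12, 0.12, 0.12, 0.12, 0.40)
    kd_effect_log2: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            ClusterLabel.CLUSTER1.value: (-1.5, -1.5),
            ClusterLabel.CLUSTER2.value: (-1.5, 0.0),
            ClusterLabel.CLUSTER3.value: (0.0, -1.5),
            ClusterLabel.CLUSTER4.value: (-1.5, 1.0),
            ClusterLabel.CLUSTER5.value: (1.0, -1.5),
            _UNAFFECTED: (0.0, 0.0),
        }
    )
    # fraction of KD BRG1 bump log2 change propagated to the KD NFR
    # accessibility bump
    atac_coupling: float = 0.5
    depth: float = 1.0  # fragment-sampling multiplier
    bin_bp: int = 10
    noise: bool = True
    n_decoy_peaks: int = 0  # BRG1 decoys in gene deserts
    # probability a clustered promoter's gene is a down-regulated DEG
    deg_down_prob: float = 0.7
    deg_up_prob: float = 0.05

    def __post_init__(self) -> None:
        extra = self.fraction_noncoding + self.fraction_short + self.fraction_duplicate_tss
        if extra > 1:
            raise ValueError("gene-category fractions exceed 1")
        for simplex, what in (
            (self.class_proportions, "class_proportions"),
            (self.cluster_proportions, "cluster_proportions"),
        ):
            if abs(sum(simplex) - 1.0) > 1e-9 or min(simplex) < 0:
                raise ValueError(f"{what} must be a probability simplex")
        if self.bin_bp <= 0 or self.depth <= 0:
            raise ValueError("bin_bp and depth must be positive")

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}


@dataclass
class SyntheticTruth:
    """Ground truth per promoter site plus expected track masses."""

    promoters: pd.DataFrame  # name, chrom, strand, tss, class, cluster, effects
    chrom_lengths: Dict[str, int]
    expected_mass: Dict[str, float]  # per "<assay>_<condition>" track

    def promoter_key(self) -> pd.DataFrame:
        return self.promoters.set_index(["chrom", "strand", "tss"], drop=False)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _gauss_mass(amplitude: float, sigma: float) -> float:
    return amplitude * sigma * np.sqrt(2 * np.pi)


def generate_gene_table(
    config: SyntheticConfig,
) -> Tuple[List[GeneRecord], SyntheticTruth]:
    """Gene table plus per-promoter ground truth.

    Promoter sites sit on a regular grid (snapped to the sampling bin so
    plateau edges are exact), far enough apart that neighboring promoter
    windows never overlap. Each site receives a class and, unless the
    class is H3K4me3-Low, a cluster; noncoding (NR_), short (< 2 kb) and
    duplicate-TSS transcripts exercise the catalog filters.
    """
    rng = _rng(config, 1)
    n_sites = config.n_genes
    per_chrom = int(np.ceil(n_sites / config.n_chroms))
    spacing = config.chrom_length_bp // (per_chrom + 1)
    if spacing < 8000:
        raise ValueError("chromosomes too short for the requested gene count")

    genes: List[GeneRecord] = []
    rows: List[dict] = []
    classes = [
        PromoterClass.H3K4ME3_LOW.value,
        PromoterClass.H3K4ME3_ONLY.value,
        PromoterClass.BIVALENT.value,
    ]
    clusters = [c.value for c in ClusterLabel if c is not ClusterLabel.UNCLUSTERED]
    cluster_names = clusters + [_UNAFFECTED]

    site = 0
    prev_site: Optional[dict] = None
    while site < n_sites:
        chrom = f"chr{site // per_chrom + 1}"
        slot = site % per_chrom
        tss = (slot + 1) * spacing
        tss -= tss % config.bin_bp  # snap to the sampling grid
        strand = "+" if rng.random() < 0.5 else "-"

        u = rng.random()
        if u < config.fraction_noncoding:
            kind = "noncoding"
        elif u < config.fraction_noncoding + config.fraction_short:
            kind = "short"
        elif (
            u < config.fraction_noncoding + config.fraction_short + config.fraction_duplicate_tss
            and prev_site is not None
        ):
            kind = "duplicate"
        else:
            kind = "coding"

        if kind == "duplicate":
            # an extra transcript at the previous surviving site's TSS
            chrom, strand, tss = prev_site["chrom"], prev_site["strand"], prev_site["tss"]
            length = int(rng.integers(2500, 8000))
            prev_site["n_members"] += 1
        else:
            length = int(rng.integers(500, 1999)) if kind == "short" else int(
                rng.integers(2500, 8000)
            )
        prefix = "NR_" if kind == "noncoding" else "NM_"
        acc = f"{prefix}{site:06d}"
        if strand == "+":
            tx_start, tx_end = tss, tss + length
        else:
            tx_start, tx_end = tss - length + 1, tss + 1
        symbol = (
            prev_site["symbol"] if kind == "duplicate" else f"gene{site}"
        )
        genes.append(GeneRecord(acc, chrom, strand, tx_start, tx_end, symbol))

        if kind == "coding":
            cls = classes[int(rng.choice(3, p=config.class_proportions))]
            if cls == PromoterClass.H3K4ME3_LOW.value:
                cluster = _UNAFFECTED
            else:
                cluster = cluster_names[
                    int(rng.choice(len(cluster_names), p=config.cluster_proportions))
                ]
            up, down = config.kd_effect_log2[cluster]
            row = {
                "name": acc,
                "symbol": symbol,
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "promoter_class": cls,
                "cluster": cluster,
                "up_effect": up,
                "down_effect": down,
                "n_members": 1,
            }
            rows.append(row)
            prev_site = row
        site += 1

    truth_df = pd.DataFrame(rows).sort_values(["chrom", "tss"]).reset_index(drop=True)
    truth = SyntheticTruth(truth_df, config.chrom_lengths, {})
    truth.expected_mass = _expected_masses(config, truth)
    return genes, truth


def _oriented(tss: int, strand: str, offset: int) -> int:
    return tss + offset if strand == "+" else tss - offset


def _bump_centers(row: pd.Series, config: SyntheticConfig) -> Tuple[int, int]:
    up_c = _oriented(int(row.tss), row.strand, config.brg1_offsets[0])
    down_c = _oriented(int(row.tss), row.strand, config.brg1_offsets[1])
    return up_c, down_c


def _expected_density(
    config: SyntheticConfig, truth: SyntheticTruth, assay: str, condition: str
) -> Dict[str, np.ndarray]:
    """Expected signal density per bin, per chromosome."""
    bw = config.bin_bp
    n_bins = {c: length // bw for c, length in truth.chrom_lengths.items()}
    dens = {c: np.zeros(n) for c, n in n_bins.items()}
    centers_by_chrom = {c: np.arange(n) * bw + bw / 2.0 for c, n in n_bins.items()}
    params = CatalogParams()
    for row in truth.promoters.itertuples(index=False):
        arr = dens[row.chrom]
        centers = centers_by_chrom[row.chrom]
        if assay in ("h3k4me3", "h3k27me3"):
            k4, k27 = config.mark_levels[row.promoter_class]
            level = k4 if assay == "h3k4me3" else k27
            win = promoter_window(
                row.chrom, int(row.tss), row.strand, params, truth.chrom_lengths[row.chrom]
            )
            # plateau snapped outward so every base of the window is covered
            arr[win.start // bw : -(-win.end // bw)] += level
        elif assay == "atac":
            amp = config.nfr_atac_amplitude[row.promoter_class]
            if condition == "kd":
                shift = config.atac_coupling * 0.5 * (row.up_effect + row.down_effect)
                amp *= 2.0**shift
            lo = max(0, int(row.tss) - int(6 * config.atac_sigma))
            hi = min(len(arr) * bw, int(row.tss) + int(6 * config.atac_sigma))
            sl = slice(lo // bw, -(-hi // bw))
            x = centers[sl]
            arr[sl] += amp * np.exp(-0.5 * ((x - row.tss) / config.atac_sigma) ** 2)
        else:  # brg1
            amp = config.brg1_amplitude[row.promoter_class]
            up_c, down_c = _bump_centers(row, config)
            for center, effect in ((up_c, row.up_effect), (down_c, row.down_effect)):
                a = amp * (2.0**effect if condition == "kd" else 1.0)
                lo = max(0, center - int(6 * config.brg1_sigma))
                hi = min(len(arr) * bw, center + int(6 * config.brg1_sigma))
                sl = slice(lo // bw, -(-hi // bw))
                x = centers[sl]
                arr[sl] += a * np.exp(-0.5 * ((x - center) / config.brg1_sigma) ** 2)
    return dens


def _expected_masses(config: SyntheticConfig, truth: SyntheticTruth) -> Dict[str, float]:
    masses: Dict[str, float] = {}
    for assay in ASSAYS:
        for condition in CONDITIONS:
            dens = _expected_density(config, truth, assay, condition)
            masses[f"{assay}_{condition}"] = float(
                config.depth * config.bin_bp * sum(a.sum() for a in dens.values())
            )
    return masses


def generate_tracks(
    config: SyntheticConfig, truth: SyntheticTruth
) -> Dict[str, SignalTrack]:
    """Eight tracks: {brg1, atac, h3k4me3, h3k27me3} x {control, kd}.

    With noise, fragment counts per bin are Poisson with mean
    ``density * bin_bp * depth`` and the stored run value is
    ``counts / bin_bp`` (fragments per base); noise-free tracks store
    ``density * depth`` directly.
    """
    tracks: Dict[str, SignalTrack] = {}
    for t_idx, assay in enumerate(ASSAYS):
        for c_idx, condition in enumerate(CONDITIONS):
            rng = _rng(config, 100 + 10 * t_idx + c_idx)
            dens = _expected_density(config, truth, assay, condition)
            runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for chrom, arr in dens.items():
                if config.noise:
                    counts = rng.poisson(arr * config.bin_bp * config.depth)
                    values = counts / config.bin_bp
                else:
                    values = arr * config.depth
                nz = np.nonzero(values)[0]
                if nz.size == 0:
                    continue
                starts = nz.astype(np.int64) * config.bin_bp
                ends = starts + config.bin_bp
                runs[chrom] = (starts, ends, values[nz])
            tracks[f"{assay}_{condition}"] = SignalTrack(runs)
    return tracks


def generate_peaks(
    truth: SyntheticTruth, config: SyntheticConfig
) -> Tuple[List[Peak], List[Peak]]:
    """BRG1 peaks at every simulated bump (2 per promoter) and one ATAC peak
    per NFR, each spanning +/- 2 sigma of its bump; optional BRG1 decoys in
    gene deserts, far from any ATAC peak."""
    brg1: List[Peak] = []
    atac: List[Peak] = []
    half_b = int(2 * config.brg1_sigma)
    half_a = int(2 * config.atac_sigma)
    for i, row in enumerate(truth.promoters.itertuples(index=False)):
        up_c, down_c = _bump_centers(row, config)
        for tag, center in (("up", up_c), ("down", down_c)):
            brg1.append(
                Peak(
                    GenomicInterval(row.chrom, center - half_b, center + half_b),
                    f"brg1_{i}_{tag}",
                )
            )
        atac.append(
            Peak(
                GenomicInterval(row.chrom, int(row.tss) - half_a, int(row.tss) + half_a),
                f"atac_{i}",
            )
        )
    if config.n_decoy_peaks:
        rng = _rng(config, 2)
        tss_by_chrom = {
            c: np.sort(g["tss"].to_numpy())
            for c, g in truth.promoters.groupby("chrom")
        }
        placed = 0
        chroms = sorted(truth.chrom_lengths)
        while placed < config.n_decoy_peaks:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(5000, truth.chrom_lengths[chrom] - 5000))
            tss = tss_by_chrom.get(chrom, np.zeros(0))
            if tss.size and np.min(np.abs(tss - pos)) < 4000:
                continue  # too close to a real promoter to be a desert
            brg1.append(
                Peak(
                    GenomicInterval(chrom, pos - half_b, pos + half_b),
                    f"brg1_decoy_{placed}",
                )
            )
            placed += 1
    return brg1, atac


def generate_expression_table(
    truth: SyntheticTruth, config: SyntheticConfig
) -> List[ExpressionRecord]:
    """One expression row per promoter symbol.

    Genes at clustered (BRG1-losing) promoters are down-regulated DEGs
    with probability ``deg_down_prob``; a small fraction of the rest are
    up-regulated; everything else is flat with a null p-value.
    """
    rng = _rng(config, 3)
    records: List[ExpressionRecord] = []
    for row in truth.promoters.itertuples(index=False):
        base = float(rng.lognormal(mean=3.0, sigma=0.8))
        affected = row.cluster != _UNAFFECTED
        r = rng.random()
        if affected and r < config.deg_down_prob:
            fc, p = 0.5 * float(rng.uniform(0.8, 1.2)), float(rng.uniform(0.0, 0.01))
            fc = min(fc, 1.0 / 1.5)
        elif not affected and r < config.deg_up_prob:
            fc, p = 1.5 * float(rng.uniform(1.0, 1.5)), float(rng.uniform(0.0, 0.01))
        else:
            fc, p = float(rng.uniform(0.9, 1.1)), float(rng.uniform(0.1, 1.0))
        records.append(
            ExpressionRecord(row.symbol, base, base * fc, fc, p)
        )
    return records


def simulate_all(config: SyntheticConfig) -> dict:
    """Run every generator; returns genes, truth, tracks, peaks, expression."""
    genes, truth = generate_gene_table(config)
    tracks = generate_tracks(config, truth)
    brg1_peaks, atac_peaks = generate_peaks(truth, config)
    expression = generate_expression_table(truth, config)
    return {
        "genes": genes,
        "truth": truth,
        "tracks": tracks,
        "brg1_peaks": brg1_peaks,
        "atac_peaks": atac_peaks,
        "expression": expression,
    }
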