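"""Promoter-TSS catalog construction.

From a refGene-style transcript table, keep protein-coding transcripts
(``NM_`` accessions) longer than 2 kb, collapse transcripts sharing the
exact same TSS into one promoter, and attach the -500/+1000 bp
quantification window, oriented along transcription (mirrored on the
minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genome import GeneRecord, GenomicInterval


@dataclass(frozen=True)
class CatalogParams:
    """Filters and window geometry for catalog construction.

    ``min_gene_length`` is exclusive: a transcript must be strictly longer
    to survive. Window extents are in bp relative to the TSS along the
    direction of transcription.
    """

    min_gene_length: int = 2000
    coding_prefix: str = "NM_"
    upstream_bp: int = 500
    downstream_bp: int = 1000
    dedup_by_strand: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp <= 0 or self.downstream_bp <= 0:
            raise ValueError("window extents must be positive")
        if self.min_gene_length < 0:
            raise ValueError("min_gene_length must be >= 0")


@dataclass(frozen=True)
class PromoterTSS:
    """A deduplicated TSS anchor plus its quantification window."""

    chrom: str
    strand: str
    tss: int
    window: GenomicInterval
    member_accessions: Tuple[str, ...]

    @property
    def name(self) -> str:
        return "|".join(self.member_accessions)


def select_protein_coding(
    genes: Sequence[GeneRecord], params: CatalogParams = CatalogParams()
) -> List[GeneRecord]:
    """Keep coding-prefix transcripts strictly longer than the length cutoff."""
    return [
        g
        for g in genes
        if g.accession.startswith(params.coding_prefix)
        and g.length > params.min_gene_length
    ]


def promoter_window(
    chrom: str,
    tss: int,
    strand: str,
    params: CatalogParams = CatalogParams(),
    chrom_length: Optional[int] = None,
) -> GenomicInterval:
    """The -upstream/+downstream window around a TSS, transcription-oriented.

    On the plus strand the window is ``[tss - up, tss + down)``. On the
    minus strand it is the mirror image about the TSS base,
    ``[tss - down + 1, tss + up + 1)``, so that "upstream" always means
    upstream of transcription. Clamped at 0 and at ``chrom_length`` when
    known.
    """
    up, down = params.upstream_bp, params.downstream_bp
    if strand == "+":
        start, end = tss - up, tss + down
    elif strand == "-":
        start, end = tss - down + 1, tss + up + 1
    else:
        raise ValueError(f"promoter window requires a stranded TSS, got {strand!r}")
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end, strand)


def deduplicate_tss(
    genes: Sequence[GeneRecord],
    params: CatalogParams = CatalogParams(),
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[PromoterTSS]:
    """Merge transcripts with the exact same TSS into one promoter.

    The grouping key is (chrom, strand, TSS) by default; divergent
    promoters at numerically coincident positions stay distinct. Set
    ``params.dedup_by_strand`` False to merge across strands (the
    representative strand is then the first member's).
    """
    groups: Dict[Tuple, List[GeneRecord]] = {}
    for g in genes:
        key = (g.chrom, g.strand, g.tss) if params.dedup_by_strand else (g.chrom, g.tss)
        groups.setdefault(key, []).append(g)

    promoters: List[PromoterTSS] = []
    for key, members in groups.items():
        chrom = members[0].chrom
        strand = members[0].strand
        tss = members[0].tss
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        window = promoter_window(chrom, tss, strand, params, clen)
        accs = tuple(sorted(m.accession for m in members))
        promoters.append(PromoterTSS(chrom, strand, tss, window, accs))
    promoters.sort(key=lambda p: (p.chrom, p.tss, p.strand))
    return promoters


def build_catalog(
    genes: Sequence[GeneRecord],
    params: CatalogParams = CatalogParams(),
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[PromoterTSS]:
    """Filter then deduplicate: the full catalog construction."""
    return deduplicate_tss(select_protein_coding(genes, params), params, chrom_lengths)
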