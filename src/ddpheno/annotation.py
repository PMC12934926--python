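"""Gene annotation parsing and phenotyping-region construction.

Genes are phenotyped over their annotated span plus a flanking window
(1 kb on each side by default). Because RNA-seq coverage within that
window can be contaminated by transcripts of neighbouring or overlapping
genes, each region records the exon intervals of every *other* gene that
intersects it; downstream binning removes any bin touching those exons.

All internal coordinates are 0-based half-open. GTF input (1-based,
inclusive) is converted on parse and back on export.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GeneRegion",
    "parse_gene_regions",
    "merge_intervals",
    "AnnotationError",
]

DEFAULT_BIOTYPES = frozenset({"protein_coding", "lncRNA"})

# GENCODE writes gene_type, Ensembl writes gene_biotype.
_BIOTYPE_KEYS = ("gene_type", "gene_biotype")


class AnnotationError(ValueError):
    """Raised for malformed or incomplete gene annotation input."""


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals: sorted, pairwise-disjoint output.

    Touching intervals ([a,b) and [b,c)) are merged.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class GeneRegion:
    """A gene's phenotyping window and its cross-gene exon annotation.

    Coordinates are 0-based half-open. ``region_start``/``region_end`` are
    the gene span extended by the flank and clipped to chromosome bounds.
    ``foreign_exons`` is the disjoint sorted union of exon intervals of all
    other genes intersecting the region.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    region_start: int
    region_end: int
    biotype: str
    foreign_exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.region_start <= self.gene_start < self.gene_end <= self.region_end):
            raise AnnotationError(
                f"{self.gene_id}: inconsistent region "
                f"[{self.region_start},{self.region_end}) vs gene "
                f"[{self.gene_start},{self.gene_end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.region_end - self.region_start

    @property
    def tss(self) -> int:
        """Transcription start site: gene_start on +, gene_end-1 on -."""
        return self.gene_start if self.strand == "+" else self.gene_end - 1


def _attr(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def parse_gene_regions(
    gtf_path: str | os.PathLike,
    flank_bp: int = 1000,
    biotypes: frozenset[str] | set[str] = DEFAULT_BIOTYPES,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GeneRegion]:
    """Parse a GTF and build one :class:`GeneRegion` per phenotyped gene.

    Parameters
    ----------
    gtf_path
        GTF file with ``gene`` and ``exon`` records (GENCODE or Ensembl
        attribute dialect).
    flank_bp
        Extension added to each side of the gene span (clipped at
        chromosome bounds).
    biotypes
        Gene biotypes to phenotype. Foreign exons are collected from ALL
        genes in the file regardless of biotype, since any transcript can
        contaminate coverage.
    chrom_sizes
        Optional chromosome lengths for clipping the right edge of regions.

    Returns
    -------
    list of GeneRegion, in file order of the gene records.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: list[tuple[str, str, str, int, int, str]] = []
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    exon_chrom: dict[str, str] = {}

    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = _attr(f, "gene_id")
        if gid is None:
            raise AnnotationError(f"gene record without gene_id at {f.seqid}:{f.start}")
        bt = _attr(f, *_BIOTYPE_KEYS)
        if bt is None:
            raise AnnotationError(f"gene {gid}: missing gene_type/gene_biotype attribute")
        # GTF 1-based inclusive -> 0-based half-open
        genes.append((gid, f.seqid, f.strand, f.start - 1, f.end, bt))

    for f in db.features_of_type("exon"):
        gid = _attr(f, "gene_id")
        if gid is None:
            raise AnnotationError(f"exon record without gene_id at {f.seqid}:{f.start}")
        exons_by_gene.setdefault(gid, []).append((f.start - 1, f.end))
        exon_chrom[gid] = f.seqid

    merged_exons = {gid: merge_intervals(ivs) for gid, ivs in exons_by_gene.items()}

    regions = []
    for gid, chrom, strand, gstart, gend, bt in genes:
        if bt not in biotypes:
            continue
        rstart = max(0, gstart - flank_bp)
        rend = gend + flank_bp
        if chrom_sizes and chrom in chrom_sizes:
            rend = min(rend, chrom_sizes[chrom])
        foreign: list[tuple[int, int]] = []
        for other_gid, ivs in merged_exons.items():
            if other_gid == gid or exon_chrom[other_gid] != chrom:
                continue
            for s, e in ivs:
                if s < rend and e > rstart:
                    foreign.append((s, e))
        regions.append(
            GeneRegion(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                gene_start=gstart,
                gene_end=gend,
                region_start=rstart,
                region_end=rend,
                biotype=bt,
                foreign_exons=merge_intervals(foreign),
            )
        )
    return regions
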