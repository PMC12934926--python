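"""Synthetic population RNA-seq coverage with known latent structure.

The generator emulates what the phenotyping pipeline consumes: a gene
annotation (GTF), per-sample base-level coverage (bigWig or in-memory),
and matched knowledge-driven phenotypes. Each gene is an isoform
mixture; two latent factors per gene and sample drive the data: an
expression factor e_gs (log2-scale total output) and a usage factor
u_gs (softmax link to isoform weights). Observed coverage adds Poisson
noise on the expected per-base coverage, and each sample carries a
log-normal sequencing-depth multiplier d_s:

    expected_g(s, base) = d_s * 2^(e_gs) * sum_i w_i(u_gs) * baseline *
                          1[base in exons of isoform i of gene g]

Expression factors are per gene (not global) because a sample-wide
expression shift is indistinguishable from sequencing depth and would
be removed by depth scaling. Because the latent factors are known,
recovery of e by DDP1, of u by later components, and the behaviour of
residualization against exact KDPs are all testable without external
data.

All randomness derives from a single integer seed; coverage noise is
keyed per (gene, sample) so any subset of samples or genes reproduces
identical values, and genes can be realized lazily at population scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyBigWig

from .annotation import GeneRegion, merge_intervals
from .coverage import CoverageSource
from .residualization import KDPTable

__all__ = [
    "SimConfig",
    "SimGene",
    "SimTruth",
    "SimCoverageSource",
    "simulate_annotation",
    "simulate_truth",
    "simulate_coverage",
    "simulate_kdps",
    "write_bigwigs",
    "simulate_dataset",
]

# rng stream tags (kept distinct so draws never collide across purposes)
_STRUCT, _SAMPLES, _COV, _KDP = 1, 2, 3, 4

CHROM = "chr1"
_FLANK_MARGIN = 2000


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults give a small but realistic cohort: 10 genes of 5-50 kb,
    100 samples, moderate biological variation (sigma_e = sigma_u = 0.5
    on log2/usage scales), 20% depth variation, and ~20x baseline exon
    coverage with Poisson noise.
    """

    n_genes: int = 10
    n_samples: int = 100
    n_isoforms: int = 2
    baseline_depth: float = 20.0
    sigma_e: float = 0.5
    sigma_u: float = 0.5
    sigma_d: float = 0.2
    min_span: int = 5_000
    max_span: int = 50_000
    overlapping_pair: bool = False
    noise: str = "poisson"  # or "none"
    seed: int = 0
    # share gene structures across cohorts while drawing new samples:
    # defaults to `seed` when unset
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_isoforms < 1:
            raise ValueError("n_isoforms must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


@dataclass
class SimGene:
    """One simulated gene: exon layout and isoform exon subsets."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    exons: list[tuple[int, int]]
    isoforms: list[list[tuple[int, int]]]

    def isoform_masks(self) -> np.ndarray:
        """(n_isoforms, span) indicator of exonic bases per isoform."""
        span = self.end - self.start
        masks = np.zeros((len(self.isoforms), span))
        for i, exons in enumerate(self.isoforms):
            for s, e in exons:
                masks[i, s - self.start:e - self.start] = 1.0
        return masks


def _build_genes(config: SimConfig) -> list[SimGene]:
    struct_seed = (config.structure_seed if config.structure_seed is not None
                   else config.seed)
    rng = np.random.default_rng([struct_seed, _STRUCT])
    genes: list[SimGene] = []
    pos = 10_000
    for g in range(config.n_genes):
        span = int(rng.integers(config.min_span, config.max_span + 1))
        if config.overlapping_pair and g == 1 and genes:
            # second gene overlaps the first by ~2 kb to exercise
            # cross-gene exon exclusion
            pos = max(genes[0].end - 2_000, genes[0].start + 1_000)
        start, end = pos, pos + span

        n_exons = int(np.clip(span // 3_000, 2, 8))
        widths = rng.integers(200, 1_501, size=n_exons)
        total_exonic = int(widths.sum())
        intron_total = span - total_exonic
        if intron_total < n_exons - 1:  # very dense gene: shrink exons
            widths = np.maximum(widths * span // (2 * total_exonic), 50)
            intron_total = span - int(widths.sum())
        if n_exons > 1:
            fracs = rng.dirichlet(np.ones(n_exons - 1))
            introns = np.floor(fracs * intron_total).astype(int)
        else:
            introns = np.array([], dtype=int)
        exons = []
        cursor = start
        for i, w in enumerate(widths):
            exons.append((cursor, cursor + int(w)))
            if i < len(introns):
                cursor += int(w) + int(introns[i])
        # pin the last exon's end to the gene end
        exons[-1] = (exons[-1][0], end)
        exons = merge_intervals(exons)

        isoforms = [list(exons)]
        for i in range(1, config.n_isoforms):
            if len(exons) >= 3:
                drop = 1 + (i - 1) % (len(exons) - 2)  # skip an internal exon
                isoforms.append([e for j, e in enumerate(exons) if j != drop])
            else:
                isoforms.append(exons[:1])

        genes.append(
            SimGene(
                gene_id=f"SIMG{g:04d}",
                chrom=CHROM,
                strand="+" if g % 2 == 0 else "-",
                start=start,
                end=end,
                biotype="lncRNA" if g % 5 == 4 else "protein_coding",
                exons=exons,
                isoforms=isoforms,
            )
        )
        pos = end + int(rng.integers(4_000, 10_001))
    return genes


@dataclass
class SimTruth:
    """Ground truth: latent factors per sample and gene definitions.

    Sufficient to recompute expected per-base coverage exactly.
    """

    config: SimConfig
    genes: list[SimGene]
    sample_ids: list[str]
    e: np.ndarray  # (n_genes, n_samples) expression factors
    u: np.ndarray  # (n_genes, n_samples) isoform-usage factors
    d: np.ndarray  # (n_samples,) sequencing-depth multipliers
    _gene_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}

    def factors(self, gene: SimGene | str) -> tuple[np.ndarray, np.ndarray]:
        """(expression, usage) factor vectors for one gene."""
        gi = self._gene_index[gene if isinstance(gene, str) else gene.gene_id]
        return self.e[gi], self.u[gi]

    def usage_weights(self, gene: SimGene) -> np.ndarray:
        """(n_samples, n_isoforms) softmax isoform weights from u_gs."""
        n_iso = len(gene.isoforms)
        _, u = self.factors(gene)
        if n_iso == 1:
            return np.ones((len(u), 1))
        contrasts = np.linspace(1.0, -1.0, n_iso)
        logits = np.outer(u, contrasts)
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        return w / w.sum(axis=1, keepdims=True)

    def expected_coverage(self, gene: SimGene,
                          sample_index: int | None = None) -> np.ndarray:
        """Expected per-base coverage over the gene span.

        (n_samples, span) for all samples, or one sample's row.
        """
        masks = gene.isoform_masks()
        w = self.usage_weights(gene)
        e, _ = self.factors(gene)
        amplitude = self.d * np.exp2(e) * self.config.baseline_depth
        if sample_index is not None:
            return amplitude[sample_index] * (w[sample_index] @ masks)
        return amplitude[:, None] * (w @ masks)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the population's latent factors (seeded from config.seed)."""
    rng = np.random.default_rng([config.seed, _SAMPLES])
    shape = (config.n_genes, config.n_samples)
    e = rng.normal(0.0, config.sigma_e, shape)
    u = rng.normal(0.0, config.sigma_u, shape)
    d = (rng.lognormal(0.0, config.sigma_d, config.n_samples)
         if config.sigma_d > 0 else np.ones(config.n_samples))
    return SimTruth(config, _build_genes(config), config.sample_ids, e, u, d)


def simulate_annotation(config: SimConfig) -> tuple[str, list[SimGene]]:
    """GTF text (1-based inclusive coordinates) for the simulated genes."""
    genes = _build_genes(config)
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
        lines.append(
            f"{g.chrom}\tddpheno_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\t{attrs}"
        )
        for i, exons in enumerate(g.isoforms):
            tid = f"{g.gene_id}.t{i + 1}"
            tattrs = attrs + f' transcript_id "{tid}";'
            lines.append(
                f"{g.chrom}\tddpheno_sim\ttranscript\t{exons[0][0] + 1}\t"
                f"{exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}"
            )
            for s, e in exons:
                lines.append(
                    f"{g.chrom}\tddpheno_sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{tattrs}"
                )
    return "\n".join(lines) + "\n", genes


class SimCoverageSource(CoverageSource):
    """Lazy coverage provider over the simulated genome.

    Observed coverage at a base is the sum, over genes covering it, of a
    Poisson realization of that gene's expected contribution. Noise is
    keyed per (gene, sample), so values are reproducible for any subset
    of samples or regions and genes never need to be held in memory
    simultaneously.
    """

    def __init__(self, truth: SimTruth):
        self.truth = truth
        self.sample_ids = list(truth.sample_ids)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    def gene_contribution(self, gene: SimGene, sample_id: str) -> np.ndarray:
        """Observed coverage from one gene over its own span, one sample."""
        si = self._sample_index[sample_id]
        gi = self.truth._gene_index[gene.gene_id]
        expected = self.truth.expected_coverage(gene, si)
        if self.truth.config.noise == "none":
            return expected
        rng = np.random.default_rng([self.truth.config.seed, _COV, gi, si])
        return rng.poisson(expected).astype(float)

    def per_base(self, sample_id: str, region: GeneRegion) -> np.ndarray:
        out = np.zeros(region.span)
        for gene in self.truth.genes:
            if gene.chrom != region.chrom:
                continue
            lo = max(gene.start, region.region_start)
            hi = min(gene.end, region.region_end)
            if lo >= hi:
                continue
            contrib = self.gene_contribution(gene, sample_id)
            out[lo - region.region_start:hi - region.region_start] += \
                contrib[lo - gene.start:hi - gene.start]
        return out


def simulate_coverage(config: SimConfig) -> tuple[SimCoverageSource, SimTruth]:
    """Latent truth plus a coverage source over the simulated genome."""
    truth = simulate_truth(config)
    return SimCoverageSource(truth), truth


def chrom_sizes(truth: SimTruth) -> dict[str, int]:
    end = max(g.end for g in truth.genes) + _FLANK_MARGIN
    return {CHROM: end}


def write_bigwigs(source: SimCoverageSource,
                  directory: str | os.PathLike) -> dict[str, Path]:
    """One bigWig per sample over the whole simulated chromosome.

    Values equal what :meth:`SimCoverageSource.per_base` returns for any
    region, so file-based and in-memory pipelines agree exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sizes = chrom_sizes(source.truth)
    size = sizes[CHROM]
    paths = {}
    for sid in source.sample_ids:
        track = np.zeros(size)
        for gene in source.truth.genes:
            track[gene.start:gene.end] += source.gene_contribution(gene, sid)
        path = directory / f"{sid}.bw"
        bw = pyBigWig.open(str(path), "w")
        bw.addHeader([(CHROM, size)])
        bw.addEntries(CHROM, 0, values=track, span=1, step=1)
        bw.close()
        paths[sid] = path
    return paths


def simulate_kdps(
    truth: SimTruth,
    modalities: tuple[str, ...] = ("expression", "isoform_ratio"),
    noise_sd: float = 0.0,
) -> KDPTable:
    """Knowledge-driven phenotypes consistent with the simulated truth.

    ``expression`` is log2 expected total gene output (depth multiplier
    excluded, as a depth-normalized quantifier would produce);
    ``isoform_ratio`` is the first isoform's usage weight. Optional
    Normal(0, noise_sd) noise emulates quantification error.
    """
    rng = np.random.default_rng([truth.config.seed, _KDP])
    rows, meta = [], []
    for gene in truth.genes:
        masks = gene.isoform_masks()
        w = truth.usage_weights(gene)
        e, _ = truth.factors(gene)
        iso_mass = masks.sum(axis=1)
        for modality in modalities:
            if modality == "expression":
                vals = np.log2(np.exp2(e) * (w @ iso_mass)
                               * truth.config.baseline_depth)
            elif modality == "isoform_ratio":
                vals = w[:, 0].copy()
            else:
                raise ValueError(f"unknown KDP modality {modality!r}")
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, len(vals))
            rows.append(vals)
            meta.append((f"{gene.gene_id}:{modality}", gene.gene_id, modality))
    index = [m[0] for m in meta]
    values = pd.DataFrame(rows, index=index, columns=truth.sample_ids)
    meta_df = pd.DataFrame(
        {"gene_id": [m[1] for m in meta], "modality": [m[2] for m in meta]},
        index=index,
    )
    return KDPTable(values, meta_df)


def simulate_dataset(config: SimConfig, outdir: str | os.PathLike,
                     kdp_noise_sd: float = 0.0) -> dict[str, Path]:
    """Write a complete toy dataset: annotation.gtf, cov/*.bw, truth.tsv,
    kdps.tsv. Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_text, _ = simulate_annotation(config)
    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text(gtf_text)
    source, truth = simulate_coverage(config)
    write_bigwigs(source, outdir / "cov")
    truth_path = outdir / "truth.tsv"
    records = []
    for gene in truth.genes:
        e, u = truth.factors(gene)
        for s, sid in enumerate(truth.sample_ids):
            records.append((gene.gene_id, sid, e[s], u[s], truth.d[s]))
    pd.DataFrame(
        records, columns=["gene_id", "sample_id", "e", "u", "d"]
    ).to_csv(truth_path, sep="\t", index=False, float_format="%.17g")
    kdps = simulate_kdps(truth, noise_sd=kdp_noise_sd)
    kdp_path = outdir / "kdps.tsv"
    from .residualization import write_kdps
    write_kdps(kdps, kdp_path)
    return {"gtf": gtf_path, "cov": outdir / "cov", "truth": truth_path,
            "kdps": kdp_path}
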