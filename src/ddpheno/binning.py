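"""Variance-adaptive segmentation of gene regions into coverage bins.

The segmentation statistic is the per-base variance, across samples, of
the first difference of log2 pseudocounted coverage. Scanning left to
right, bases accumulate into the current bin until the running sum of
these variances reaches a global threshold, at which point the bin is
closed and the accumulator resets. Regions and genes with more
coverage variation therefore receive a higher density of smaller bins.

The threshold is shared by all genes and calibrated by bisection on a
random sample of genes and samples to hit a target mean bin count per
gene (256 by default). Oversized bins are subdivided to a maximum width
(1024 by default), and any bin overlapping an exon of a different gene
is removed to limit cross-gene contamination.

A uniform fixed-width alternative is provided for benchmarking.
"""

from __future__ import annotations

import json
import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneRegion
from .coverage import CoverageSource, CoverageStack

__all__ = [
    "VarianceProfile",
    "BinScheme",
    "CalibrationResult",
    "variance_profile",
    "segment",
    "subdivide",
    "exclude_foreign_exonic",
    "calibrate_threshold",
    "build_adaptive_scheme",
    "uniform_bins",
    "write_schemes",
    "read_schemes",
    "SchemeFormatError",
]

DEFAULT_PSEUDOCOUNT = 8.0
DEFAULT_MAX_BIN_SIZE = 1024
DEFAULT_TARGET_MEAN_BINS = 256
DEFAULT_N_CALIBRATION_GENES = 128
DEFAULT_N_BINNING_SAMPLES = 256


class SchemeFormatError(ValueError):
    """Malformed bin-scheme BED input."""


@dataclass
class VarianceProfile:
    """Per-base segmentation statistic for one gene.

    ``values[i]`` is the sample variance (ddof=1) of the per-sample
    difference of log2(coverage + pseudocount) between base i+1 and
    base i of the region; length = region span - 1.
    """

    gene_id: str
    values: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


def variance_profile(stack: CoverageStack,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> VarianceProfile:
    """Compute the adaptive-binning variance profile for one gene."""
    if stack.n_samples < 2:
        raise ValueError(
            f"{stack.gene_id}: variance profile requires >= 2 samples"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    log_cov = np.log2(stack.values + pseudocount)
    diffs = np.diff(log_cov, axis=1)
    return VarianceProfile(stack.gene_id, diffs.var(axis=0, ddof=1))


def segment(profile: VarianceProfile, threshold: float,
            region_start: int = 0) -> list[tuple[int, int]]:
    """Greedy left-to-right segmentation of a region into bins.

    Profile entries are summed into an accumulator; when it reaches
    ``threshold`` the current bin closes AFTER the base whose entry
    triggered it and the accumulator resets to zero (no carry-over).
    The final partial bin is kept. Implemented with searchsorted on the
    profile cumulative sum, which is exact for this restart rule.

    Returns half-open genomic intervals partitioning
    [region_start, region_start + span).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    values = np.asarray(profile.values, dtype=float)
    span = len(values) + 1
    cs = np.cumsum(values)
    cuts: list[int] = []
    base = 0.0
    while True:
        j = int(np.searchsorted(cs, base + threshold, side="left"))
        if j >= len(cs):
            break
        cut = j + 2  # entry j spans bases (j, j+1); base j+1 closes the bin
        if cut >= span:
            break
        cuts.append(cut)
        base = cs[j]
    edges = [0, *cuts, span]
    return [(region_start + a, region_start + b) for a, b in zip(edges, edges[1:])]


def subdivide(bins: list[tuple[int, int]],
              max_bin_size: int = DEFAULT_MAX_BIN_SIZE) -> list[tuple[int, int]]:
    """Split bins wider than ``max_bin_size`` into near-equal parts.

    A bin of width w becomes ceil(w / max_bin_size) contiguous bins whose
    widths differ by at most one base, longer bins first.
    """
    if max_bin_size < 1:
        raise ValueError("max_bin_size must be >= 1")
    out: list[tuple[int, int]] = []
    for s, e in bins:
        w = e - s
        if w <= max_bin_size:
            out.append((s, e))
            continue
        k = math.ceil(w / max_bin_size)
        width, rem = divmod(w, k)
        pos = s
        for i in range(k):
            nxt = pos + width + (1 if i < rem else 0)
            out.append((pos, nxt))
            pos = nxt
    return out


def exclude_foreign_exonic(
    bins: list[tuple[int, int]], region: GeneRegion
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Partition bins into (kept, removed) by foreign-exon overlap.

    A bin is removed iff it shares at least one base with any exon of a
    different gene (``region.foreign_exons``, disjoint and sorted).
    """
    exons = region.foreign_exons
    if not exons:
        return list(bins), []
    starts = [s for s, _ in exons]
    kept, removed = [], []
    for s, e in bins:
        # candidate exon: the last one starting before the bin ends
        i = bisect_right(starts, e - 1) - 1
        if i >= 0 and exons[i][1] > s:
            removed.append((s, e))
        else:
            kept.append((s, e))
    return kept, removed


@dataclass
class BinScheme:
    """Ordered genomic bins for one gene, with exclusion bookkeeping.

    ``bins`` (kept) plus ``removed_bins`` exactly tile
    [region_start, region_end). Bin IDs index the full tiling in genomic
    order so they are stable whether or not a bin survives exclusion.
    """

    gene_id: str
    chrom: str
    strand: str
    region_start: int
    region_end: int
    bins: list[tuple[int, int]]
    removed_bins: list[tuple[int, int]] = field(default_factory=list)
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tiling = sorted([*self.bins, *self.removed_bins])
        if not tiling:
            raise ValueError(f"{self.gene_id}: empty scheme")
        if tiling[0][0] != self.region_start or tiling[-1][1] != self.region_end:
            raise ValueError(f"{self.gene_id}: bins do not span the region")
        for (s1, e1), (s2, e2) in zip(tiling, tiling[1:]):
            if e1 != s2:
                raise ValueError(
                    f"{self.gene_id}: gap/overlap between [{s1},{e1}) and [{s2},{e2})"
                )
        if any(e <= s for s, e in tiling):
            raise ValueError(f"{self.gene_id}: empty bin in scheme")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_ids(self) -> list[str]:
        """IDs of kept bins: gene_id:index within the full tiling."""
        index = {iv: i for i, iv in enumerate(sorted([*self.bins, *self.removed_bins]))}
        return [f"{self.gene_id}:{index[iv]}" for iv in sorted(self.bins)]


def build_adaptive_scheme(
    region: GeneRegion,
    profile: VarianceProfile,
    threshold: float,
    max_bin_size: int = DEFAULT_MAX_BIN_SIZE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int | None = None,
) -> BinScheme:
    """Segment, subdivide, and exon-exclude one gene's region."""
    raw = segment(profile, threshold, region.region_start)
    sub = subdivide(raw, max_bin_size)
    kept, removed = exclude_foreign_exonic(sub, region)
    return BinScheme(
        gene_id=region.gene_id,
        chrom=region.chrom,
        strand=region.strand,
        region_start=region.region_start,
        region_end=region.region_end,
        bins=kept,
        removed_bins=removed,
        threshold=threshold,
        provenance={
            "method": "adaptive",
            "pseudocount": pseudocount,
            "max_bin_size": max_bin_size,
            "seed": seed,
        },
    )


def uniform_bins(region: GeneRegion, bin_width: int) -> BinScheme:
    """Fixed-width benchmarking alternative; last bin may be shorter.

    Foreign-exon exclusion is the same code path as the adaptive scheme.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    edges = list(range(region.region_start, region.region_end, bin_width))
    edges.append(region.region_end)
    bins = list(zip(edges, edges[1:]))
    kept, removed = exclude_foreign_exonic(bins, region)
    return BinScheme(
        gene_id=region.gene_id,
        chrom=region.chrom,
        strand=region.strand,
        region_start=region.region_start,
        region_end=region.region_end,
        bins=kept,
        removed_bins=removed,
        threshold=None,
        provenance={"method": "uniform", "bin_width": bin_width},
    )


@dataclass
class CalibrationResult:
    """Outcome of global threshold calibration."""

    threshold: float
    mean_bins: float
    gene_ids: list[str]
    sample_ids: list[str]
    n_iterations: int
    profiles: dict[str, VarianceProfile]

    def bins_per_gene(self) -> dict[str, int]:
        """Pre-subdivision bin count per calibration gene at the threshold."""
        return {
            gid: len(segment(p, self.threshold))
            for gid, p in self.profiles.items()
        }


def calibrate_threshold(
    regions: list[GeneRegion],
    source: CoverageSource,
    target_mean_bins: int = DEFAULT_TARGET_MEAN_BINS,
    n_calibration_genes: int = DEFAULT_N_CALIBRATION_GENES,
    n_binning_samples: int = DEFAULT_N_BINNING_SAMPLES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    tolerance: float = 0.02,
    max_iterations: int = 40,
) -> CalibrationResult:
    """Calibrate the global segmentation threshold by bisection.

    Draws up to ``n_calibration_genes`` genes and ``n_binning_samples``
    samples (one seeded RNG for both), computes each gene's variance
    profile, and bisects on log-threshold until the mean pre-subdivision,
    pre-exclusion bin count per gene is within ``tolerance`` of
    ``target_mean_bins`` or the iteration budget is exhausted. Mean bin
    count is monotone non-increasing in the threshold, so bisection
    converges on the step function's target-crossing plateau.
    """
    if not regions:
        raise ValueError("no genes available for calibration")
    rng = np.random.default_rng(seed)
    n_genes = min(n_calibration_genes, len(regions))
    gene_idx = sorted(rng.choice(len(regions), size=n_genes, replace=False))
    chosen = [regions[i] for i in gene_idx]
    all_samples = list(source.sample_ids)
    n_samp = min(n_binning_samples, len(all_samples))
    samp_idx = sorted(rng.choice(len(all_samples), size=n_samp, replace=False))
    samples = [all_samples[i] for i in samp_idx]
    if len(samples) < 2:
        raise ValueError("calibration requires >= 2 samples")

    profiles = {
        r.gene_id: variance_profile(source.stack(r, samples), pseudocount)
        for r in chosen
    }
    masses = [p.total_mass for p in profiles.values()]
    if max(masses) <= 0:
        raise ValueError(
            "all calibration genes have zero variance profiles; "
            "check that the input coverage varies across samples"
        )

    def mean_bins(thr: float) -> float:
        return float(np.mean([len(segment(p, thr)) for p in profiles.values()]))

    lo, hi = 1e-8, max(masses)
    mid, n_iter = hi, 0
    for n_iter in range(1, max_iterations + 1):
        mid = math.sqrt(lo * hi)  # bisection in log space
        m = mean_bins(mid)
        if abs(m - target_mean_bins) <= tolerance * target_mean_bins:
            break
        if m > target_mean_bins:
            lo = mid  # too many bins -> raise threshold
        else:
            hi = mid
    return CalibrationResult(
        threshold=mid,
        mean_bins=mean_bins(mid),
        gene_ids=[r.gene_id for r in chosen],
        sample_ids=samples,
        n_iterations=n_iter,
        profiles=profiles,
    )


def write_schemes(schemes: list[BinScheme], path: str | os.PathLike) -> None:
    """Write bin schemes as BED6+1 with per-gene provenance comment lines.

    Columns: chrom, start, end, name=gene_id:bin_index, score=0, strand,
    status in {kept, removed}. Provenance (threshold, method, parameters)
    is stored in '#scheme' comment lines so read_schemes round-trips.
    """
    with open(path, "w") as fh:
        for sch in schemes:
            meta = {
                "gene_id": sch.gene_id,
                "region_start": sch.region_start,
                "region_end": sch.region_end,
                "threshold": sch.threshold,
                "provenance": sch.provenance,
            }
            fh.write(f"#scheme {json.dumps(meta)}\n")
            tiling = sorted(
                [(iv, "kept") for iv in sch.bins]
                + [(iv, "removed") for iv in sch.removed_bins]
            )
            for i, ((s, e), status) in enumerate(tiling):
                fh.write(
                    f"{sch.chrom}\t{s}\t{e}\t{sch.gene_id}:{i}\t0\t"
                    f"{sch.strand}\t{status}\n"
                )


def read_schemes(path: str | os.PathLike) -> list[BinScheme]:
    """Read bin schemes written by :func:`write_schemes`."""
    schemes: list[BinScheme] = []
    meta: dict | None = None
    rows: list[tuple[str, int, int, str, str]] = []

    def flush() -> None:
        nonlocal meta, rows
        if meta is None:
            if rows:
                raise SchemeFormatError("BED rows before any #scheme header")
            return
        kept = [(s, e) for _, s, e, st, _ in rows if st == "kept"]
        removed = [(s, e) for _, s, e, st, _ in rows if st == "removed"]
        if not rows:
            raise SchemeFormatError(f"scheme {meta['gene_id']} has no bins")
        schemes.append(
            BinScheme(
                gene_id=meta["gene_id"],
                chrom=rows[0][0],
                strand=rows[0][4],
                region_start=meta["region_start"],
                region_end=meta["region_end"],
                bins=kept,
                removed_bins=removed,
                threshold=meta["threshold"],
                provenance=meta["provenance"],
            )
        )
        meta, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#scheme "):
                flush()
                meta = json.loads(line[len("#scheme "):])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise SchemeFormatError(f"expected 7 BED columns, got {len(fields)}")
            chrom, s, e, name, _score, strand, status = fields
            if status not in ("kept", "removed"):
                raise SchemeFormatError(f"unknown bin status {status!r}")
            rows.append((chrom, int(s), int(e), status, strand))
    flush()
    return schemes
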