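"""Base-level coverage access and per-bin summarization.

Coverage comes from one bigWig file per sample (bases without data read
as 0) or from in-memory arrays produced by the simulator. Both are
exposed through the same :class:`CoverageSource` interface so binning,
calibration, and phenotyping are agnostic to where coverage lives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pyBigWig

from .annotation import GeneRegion

__all__ = [
    "CoverageStack",
    "BinnedCoverage",
    "CoverageSource",
    "ArraySource",
    "BigWigSource",
    "read_coverage",
    "mean_coverage_per_bin",
]

STAGES = ("raw_mean", "scaled", "log2", "residual")
_STAGE_NEXT = {"raw_mean": "scaled", "scaled": "log2", "log2": "residual"}


@dataclass
class CoverageStack:
    """Per-base coverage for one gene region across samples.

    ``values`` has shape (n_samples, region span); all entries >= 0.
    """

    gene_id: str
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError(f"{self.gene_id}: values shape {self.values.shape} "
                             f"inconsistent with {len(self.sample_ids)} samples")
        if np.any(self.values < 0):
            raise ValueError(f"{self.gene_id}: negative coverage values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class BinnedCoverage:
    """Samples x bins matrix for one gene at a named processing stage."""

    gene_id: str
    bin_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage: str = "raw_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.sample_ids), len(self.bin_ids)):
            raise ValueError(
                f"{self.gene_id}: values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.bin_ids)})"
            )
        if self.stage in ("raw_mean", "scaled") and np.any(self.values < 0):
            raise ValueError(f"{self.gene_id}: negative values at stage {self.stage}")

    def advance(self, values: np.ndarray, stage: str) -> "BinnedCoverage":
        """New object at the next processing stage (raw_mean->scaled->log2->residual)."""
        if _STAGE_NEXT.get(self.stage) != stage:
            raise ValueError(f"invalid stage transition {self.stage} -> {stage}")
        return BinnedCoverage(self.gene_id, self.bin_ids, self.sample_ids, values, stage)


class CoverageSource:
    """Abstract per-sample coverage provider."""

    sample_ids: list[str]

    def per_base(self, sample_id: str, region: GeneRegion) -> np.ndarray:
        raise NotImplementedError

    def stack(self, region: GeneRegion,
              sample_ids: list[str] | None = None) -> CoverageStack:
        ids = list(sample_ids) if sample_ids is not None else list(self.sample_ids)
        mat = np.empty((len(ids), region.span))
        for i, sid in enumerate(ids):
            mat[i] = self.per_base(sid, region)
        return CoverageStack(region.gene_id, ids, mat)


class ArraySource(CoverageSource):
    """In-memory coverage: {chrom: {sample_id: per-chromosome array}}."""

    def __init__(self, arrays: dict[str, dict[str, np.ndarray]]):
        self._arrays = arrays
        first_chrom = next(iter(arrays.values()))
        self.sample_ids = list(first_chrom.keys())

    def per_base(self, sample_id: str, region: GeneRegion) -> np.ndarray:
        chrom_arrays = self._arrays.get(region.chrom)
        if chrom_arrays is None:
            raise KeyError(
                f"chromosome {region.chrom!r} not in coverage; "
                f"available: {sorted(self._arrays)}"
            )
        arr = chrom_arrays[sample_id]
        out = np.zeros(region.span)
        lo, hi = region.region_start, min(region.region_end, len(arr))
        if hi > lo:
            out[: hi - lo] = arr[lo:hi]
        return out


class BigWigSource(CoverageSource):
    """One bigWig file per sample.

    Files may use "chr"-prefixed or bare chromosome names; with
    ``alias_chr_prefix`` a region's chromosome is transparently mapped to
    whichever form the file contains.
    """

    def __init__(self, paths: dict[str, str | os.PathLike],
                 alias_chr_prefix: bool = True):
        self._paths = {sid: str(p) for sid, p in paths.items()}
        self.sample_ids = list(self._paths.keys())
        self._alias = alias_chr_prefix
        self._handles: dict[str, pyBigWig.pyBigWig] = {}

    @classmethod
    def from_dir(cls, directory: str | os.PathLike,
                 suffix: str = ".bw", **kwargs) -> "BigWigSource":
        paths = {p.name[: -len(suffix)]: p
                 for p in sorted(Path(directory).glob(f"*{suffix}"))}
        if not paths:
            raise FileNotFoundError(f"no *{suffix} files in {directory}")
        return cls(paths, **kwargs)

    def _open(self, sample_id: str) -> pyBigWig.pyBigWig:
        if sample_id not in self._handles:
            self._handles[sample_id] = pyBigWig.open(self._paths[sample_id])
        return self._handles[sample_id]

    def _resolve_chrom(self, bw: pyBigWig.pyBigWig, chrom: str) -> str:
        chroms = bw.chroms()
        if chrom in chroms:
            return chrom
        if self._alias:
            alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if alt in chroms:
                return alt
        raise KeyError(
            f"chromosome {chrom!r} not in bigWig; available: {sorted(chroms)}"
        )

    def per_base(self, sample_id: str, region: GeneRegion) -> np.ndarray:
        bw = self._open(sample_id)
        chrom = self._resolve_chrom(bw, region.chrom)
        size = bw.chroms()[chrom]
        out = np.zeros(region.span)
        hi = min(region.region_end, size)
        if hi > region.region_start:
            vals = bw.values(chrom, region.region_start, hi, numpy=True)
            out[: hi - region.region_start] = np.nan_to_num(vals, nan=0.0)
        return out

    def close(self) -> None:
        for h in self._handles.values():
            h.close()
        self._handles.clear()


def read_coverage(bigwig_path: str | os.PathLike, region: GeneRegion,
                  alias_chr_prefix: bool = True) -> np.ndarray:
    """Per-base coverage over a region from one bigWig; missing bases are 0."""
    src = BigWigSource({"_": bigwig_path}, alias_chr_prefix=alias_chr_prefix)
    try:
        return src.per_base("_", region)
    finally:
        src.close()


def mean_coverage_per_bin(stack: CoverageStack, scheme) -> BinnedCoverage:
    """Mean per-base coverage per kept bin per sample (stage=raw_mean)."""
    offset = scheme.region_start
    n_bins = len(scheme.bins)
    means = np.empty((stack.n_samples, n_bins))
    csum = np.concatenate(
        [np.zeros((stack.n_samples, 1)), np.cumsum(stack.values, axis=1)], axis=1
    )
    for j, (s, e) in enumerate(scheme.bins):
        lo, hi = s - offset, e - offset
        if not (0 <= lo < hi <= stack.values.shape[1]):
            raise ValueError(
                f"{stack.gene_id}: bin [{s},{e}) outside coverage region"
            )
        means[:, j] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return BinnedCoverage(
        stack.gene_id, scheme.bin_ids(), list(stack.sample_ids), means, "raw_mean"
    )
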