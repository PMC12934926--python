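"""Sequencing-depth scaling and variance-stabilizing transform.

Each sample's total binned coverage (summed over all phenotyped genes'
kept bins) is divided by the cohort median total to give a per-sample
scaling factor; dividing by it equalizes totals across samples. A
pseudocount is then added and values are log2-transformed so that
high-coverage bins do not dominate the per-gene PCA.

Factors are computed per dataset being quantified, since models are
applied one dataset at a time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import BinnedCoverage

__all__ = [
    "ScalingFactors",
    "scaling_factors",
    "apply_scaling",
    "log_transform",
    "write_factors",
    "read_factors",
]

DEFAULT_PSEUDOCOUNT = 8.0


@dataclass
class ScalingFactors:
    """Per-sample depth factors anchored at the median sample total."""

    sample_ids: list[str]
    factors: np.ndarray
    reference_level: float

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            bad = [s for s, f in zip(self.sample_ids, self.factors) if f <= 0]
            raise ValueError(f"non-positive scaling factors for samples {bad[:5]}")


def scaling_factors(raw_tables: list[BinnedCoverage]) -> ScalingFactors:
    """Depth factors from raw per-bin mean coverage across all genes.

    factor_s = T_s / median(T) where T_s sums sample s's raw bin means
    over every gene's kept bins.
    """
    if not raw_tables:
        raise ValueError("no binned coverage provided")
    sample_ids = list(raw_tables[0].sample_ids)
    totals = np.zeros(len(sample_ids))
    for bc in raw_tables:
        if bc.stage != "raw_mean":
            raise ValueError(f"{bc.gene_id}: expected stage raw_mean, got {bc.stage}")
        if list(bc.sample_ids) != sample_ids:
            raise ValueError(f"{bc.gene_id}: sample set differs across genes")
        totals += bc.values.sum(axis=1)
    if not np.all(np.isfinite(totals)):
        raise ValueError("non-finite sample totals")
    zero = [s for s, t in zip(sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total coverage: {zero[:5]}")
    ref = float(np.median(totals))
    return ScalingFactors(sample_ids, totals / ref, ref)


def apply_scaling(raw: BinnedCoverage, factors: ScalingFactors) -> BinnedCoverage:
    """Divide each sample's bin means by its depth factor (stage=scaled)."""
    if list(raw.sample_ids) != list(factors.sample_ids):
        raise ValueError(f"{raw.gene_id}: sample IDs do not match scaling factors")
    return raw.advance(raw.values / factors.factors[:, None], "scaled")


def log_transform(scaled: BinnedCoverage,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BinnedCoverage:
    """log2(value + pseudocount), variance-stabilizing (stage=log2)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if scaled.stage != "scaled":
        raise ValueError(f"{scaled.gene_id}: expected stage scaled, got {scaled.stage}")
    if np.any(scaled.values < 0):
        raise ValueError(f"{scaled.gene_id}: negative coverage upstream")
    return scaled.advance(np.log2(scaled.values + pseudocount), "log2")


def write_factors(factors: ScalingFactors, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": factors.sample_ids, "factor": factors.factors}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_factors(path: str | os.PathLike) -> ScalingFactors:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    factors = df["factor"].to_numpy(dtype=float)
    # reference level is not serialized; reconstructable only up to scale
    return ScalingFactors(df["sample_id"].tolist(), factors, float("nan"))
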