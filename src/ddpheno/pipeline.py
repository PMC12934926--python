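"""High-level orchestration: bins -> normalized coverage -> models -> phenotypes.

These functions wire the per-gene operations into the dataset-level
workflow: calibrate one global segmentation threshold, build a bin
scheme per gene, summarize and normalize coverage, fit PCA models on a
training dataset, and apply a model store to any dataset (the training
one or a new one). Genes are processed one at a time so memory stays
proportional to a single gene region.
"""

from __future__ import annotations

import logging

from .annotation import GeneRegion
from .binning import (
    BinScheme,
    CalibrationResult,
    build_adaptive_scheme,
    calibrate_threshold,
    variance_profile,
)
from .config import RunConfig
from .coverage import BinnedCoverage, CoverageSource, mean_coverage_per_bin
from .normalization import (
    ScalingFactors,
    apply_scaling,
    log_transform,
    scaling_factors,
)
from .phenotyping import (
    ModelStore,
    PhenotypeTable,
    apply_gene_model,
    filter_genes,
    fit_gene_model,
)
from .residualization import KDPTable, residualize_gene

__all__ = [
    "define_bins",
    "bin_dataset",
    "normalize_dataset",
    "fit_models",
    "apply_models",
]

log = logging.getLogger("ddpheno")


def define_bins(
    regions: list[GeneRegion],
    source: CoverageSource,
    config: RunConfig | None = None,
) -> tuple[dict[str, BinScheme], CalibrationResult]:
    """Calibrate the global threshold and build every gene's bin scheme.

    Variance profiles use the calibration sample subset (the same draw
    for every gene), so schemes are reproducible from (inputs, seed).
    """
    cfg = config or RunConfig()
    calib = calibrate_threshold(
        regions,
        source,
        target_mean_bins=cfg.target_mean_bins,
        n_calibration_genes=cfg.n_calibration_genes,
        n_binning_samples=cfg.n_binning_samples,
        pseudocount=cfg.pseudocount,
        seed=cfg.seed,
    )
    log.info(
        "calibrated threshold %.6g (mean %.1f bins over %d genes)",
        calib.threshold, calib.mean_bins, len(calib.gene_ids),
    )
    schemes: dict[str, BinScheme] = {}
    for region in regions:
        profile = calib.profiles.get(region.gene_id)
        if profile is None:
            profile = variance_profile(
                source.stack(region, calib.sample_ids), cfg.pseudocount
            )
        schemes[region.gene_id] = build_adaptive_scheme(
            region, profile, calib.threshold,
            max_bin_size=cfg.max_bin_size,
            pseudocount=cfg.pseudocount,
            seed=cfg.seed,
        )
    return schemes, calib


def bin_dataset(
    regions: list[GeneRegion],
    schemes: dict[str, BinScheme],
    source: CoverageSource,
    sample_ids: list[str] | None = None,
) -> dict[str, BinnedCoverage]:
    """Mean coverage per kept bin per sample for every gene (raw_mean)."""
    out: dict[str, BinnedCoverage] = {}
    for region in regions:
        scheme = schemes.get(region.gene_id)
        if scheme is None:
            raise KeyError(
                f"{region.gene_id}: no bin scheme; run define-bins first"
            )
        if not scheme.bins:
            log.warning("%s: all bins removed by exon exclusion; skipping",
                        region.gene_id)
            continue
        stack = source.stack(region, sample_ids)
        out[region.gene_id] = mean_coverage_per_bin(stack, scheme)
    return out


def normalize_dataset(
    raw: dict[str, BinnedCoverage],
    pseudocount: float = 8.0,
) -> tuple[dict[str, BinnedCoverage], ScalingFactors]:
    """Depth-scale (median-anchored) and log2-transform every gene."""
    factors = scaling_factors(list(raw.values()))
    normalized = {
        g: log_transform(apply_scaling(bc, factors), pseudocount)
        for g, bc in raw.items()
    }
    return normalized, factors


def fit_models(
    raw: dict[str, BinnedCoverage],
    schemes: dict[str, BinScheme],
    config: RunConfig | None = None,
    kdps: KDPTable | None = None,
) -> ModelStore:
    """Fit per-gene PCA models on a training dataset.

    Genes failing the nonzero-coverage filter are dropped. When a KDP
    table is given, coverage is residualized per gene before PCA
    (rDDP models); genes absent from the KDP table are skipped with a
    warning (``kdp_missing_genes='drop'`` drops them instead of
    emitting plain DDP models).
    """
    cfg = config or RunConfig()
    kept = filter_genes(raw, cfg.min_nonzero_fraction)
    dropped = sorted(set(raw) - kept)
    if dropped:
        log.info("gene filter dropped %d/%d genes", len(dropped), len(raw))
    filtered = {g: bc for g, bc in raw.items() if g in kept}
    if not filtered:
        raise ValueError("no genes passed the nonzero-coverage filter")
    normalized, _ = normalize_dataset(filtered, cfg.pseudocount)

    models = {}
    for gene_id, X in normalized.items():
        if kdps is not None:
            if gene_id not in set(kdps.meta["gene_id"]):
                if cfg.kdp_missing_genes == "drop":
                    log.warning("%s: no KDPs; gene dropped", gene_id)
                    continue
                log.warning("%s: no KDPs; fitting non-residual model", gene_id)
            else:
                X, _ = residualize_gene(X, kdps, cfg.retention_alpha)
        models[gene_id] = fit_gene_model(
            X, cfg.variance_target, cfg.max_components
        )
    used_schemes = {g: schemes[g] for g in models}
    return ModelStore(models, used_schemes, config=cfg.to_dict())


def apply_models(
    store: ModelStore,
    raw: dict[str, BinnedCoverage],
    config: RunConfig | None = None,
    kdps: KDPTable | None = None,
) -> PhenotypeTable:
    """Project a dataset onto a model store's components.

    The gene filter is re-applied on this dataset's samples; bin IDs
    must match the stored schemes exactly. rDDP models require the same
    residualization (pass the dataset's KDPs).
    """
    cfg = config or RunConfig()
    kept = filter_genes(raw, cfg.min_nonzero_fraction)
    filtered = {g: bc for g, bc in raw.items() if g in kept and g in store.models}
    if not filtered:
        raise ValueError("no genes shared between dataset and model store")
    normalized, _ = normalize_dataset(filtered, cfg.pseudocount)
    tables = []
    for gene_id, X in normalized.items():
        model = store.models[gene_id]
        if model.flavor == "rddp":
            if kdps is None:
                raise ValueError(
                    f"{gene_id}: rDDP model requires KDPs for the applied dataset"
                )
            X, _ = residualize_gene(X, kdps, cfg.retention_alpha)
        if model.n_components:
            tables.append(apply_gene_model(model, X))
    return PhenotypeTable.from_projections(tables)
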