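"""Per-gene PCA phenotyping: model fitting, application, and export.

Each gene's normalized (or residualized) bin matrix is standardized per
bin and decomposed with PCA. The sample projections onto the retained
components are the gene's data-driven phenotypes (DDPs; rDDPs when the
input was residualized against knowledge-driven phenotypes). Components
are retained until they explain a target fraction of variance (80% by
default), up to a hard cap (16), and never beyond the rank bound
min(#bins, #samples - 1).

Models store the training standardization parameters so that phenotype
dimensions correspond across datasets: new data is standardized with
the training means and SDs before projection.
"""

from __future__ import annotations

import io
import json
import os
import re
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .annotation import GeneRegion
from .binning import BinScheme
from .coverage import BinnedCoverage

__all__ = [
    "GenePCAModel",
    "PhenotypeTable",
    "ModelStore",
    "filter_genes",
    "fit_gene_model",
    "apply_gene_model",
    "save_models",
    "load_models",
    "export_bed",
]

DEFAULT_VARIANCE_TARGET = 0.80
DEFAULT_MAX_COMPONENTS = 16
DEFAULT_MIN_NONZERO_FRACTION = 0.5
STORE_FORMAT_VERSION = "ddpheno-store-1"

_PHENOTYPE_ID_RE = re.compile(r"^(?P<gene>.+):PC(?P<rank>[1-9]\d*)$")


def filter_genes(
    raw_tables: dict[str, BinnedCoverage],
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
) -> set[str]:
    """Genes with nonzero total coverage in at least the given sample fraction.

    Applied both before model fitting and again, on the target dataset,
    before model application. The threshold is inclusive (exactly 50%
    of samples nonzero keeps the gene at the default).
    """
    kept = set()
    for gene_id, bc in raw_tables.items():
        if bc.stage != "raw_mean":
            raise ValueError(f"{gene_id}: gene filter requires stage raw_mean")
        totals = bc.values.sum(axis=1)
        if np.mean(totals > 0) >= min_nonzero_fraction:
            kept.add(gene_id)
    return kept


@dataclass
class GenePCAModel:
    """Fitted per-gene PCA phenotyping model.

    ``loadings`` is (n_components, n_bins) with orthonormal rows;
    ``train_mean``/``train_sd`` standardize input per bin (zero-variance
    bins get sd=1 so they contribute a constant 0 after centering).
    """

    gene_id: str
    bin_ids: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float = DEFAULT_VARIANCE_TARGET
    max_components: int = DEFAULT_MAX_COMPONENTS
    flavor: str = "ddp"

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.train_mean) / self.train_sd


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|loading| bin of each
    component (ties -> lowest bin index) gets a positive loading."""
    out = loadings.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_gene_model(
    X: BinnedCoverage,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> GenePCAModel:
    """Fit one gene's PCA phenotyping model on normalized or residual data.

    Retains k = min(smallest k with cumulative explained-variance ratio
    >= variance_target, max_components, min(#bins, #samples - 1))
    components. Degenerate all-constant input yields a model with zero
    components (such genes are normally removed by :func:`filter_genes`).
    """
    if X.stage not in ("log2", "residual"):
        raise ValueError(f"{X.gene_id}: expected stage log2 or residual, got {X.stage}")
    n_samples, n_bins = X.values.shape
    if n_samples < 2:
        raise ValueError(f"{X.gene_id}: PCA requires >= 2 samples")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X.values - mean) / sd
    flavor = "rddp" if X.stage == "residual" else "ddp"

    rank_bound = min(n_bins, n_samples - 1)
    total_var = float(Z.var(axis=0, ddof=1).sum())
    if total_var <= 0:
        return GenePCAModel(
            X.gene_id, list(X.bin_ids), mean, sd,
            np.empty((0, n_bins)), np.empty(0), 0,
            variance_target, max_components, flavor,
        )

    pca = PCA(n_components=rank_bound, svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    k_var = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(k_var, max_components, rank_bound, len(evr))
    loadings = _fix_signs(pca.components_[:k])
    return GenePCAModel(
        X.gene_id, list(X.bin_ids), mean, sd,
        loadings, evr[:k].copy(), k,
        variance_target, max_components, flavor,
    )


def apply_gene_model(model: GenePCAModel, X_new: BinnedCoverage) -> pd.DataFrame:
    """Project a dataset onto a gene's components -> phenotype rows.

    Input bins must exactly match the model's (same scheme, same order).
    Returns a phenotypes x samples DataFrame with rows gene_id:PC<rank>.
    """
    if list(X_new.bin_ids) != list(model.bin_ids):
        raise ValueError(
            f"{model.gene_id}: bin IDs do not match the fitted model; "
            "re-bin the coverage with the stored bin scheme"
        )
    if X_new.stage not in ("log2", "residual"):
        raise ValueError(f"{model.gene_id}: expected stage log2 or residual")
    Z = model.standardize(X_new.values)
    proj = Z @ model.loadings.T
    index = [f"{model.gene_id}:PC{r}" for r in range(1, model.n_components + 1)]
    return pd.DataFrame(proj.T, index=index, columns=list(X_new.sample_ids))


@dataclass
class PhenotypeTable:
    """Phenotype values (phenotype_id x samples) with gene grouping."""

    values: pd.DataFrame
    groups: pd.Series = field(default=None)  # phenotype_id -> gene_id

    def __post_init__(self) -> None:
        parsed = {}
        for pid in self.values.index:
            m = _PHENOTYPE_ID_RE.match(pid)
            if not m:
                raise ValueError(f"invalid phenotype ID {pid!r}")
            parsed[pid] = m.group("gene")
        if self.groups is None:
            self.groups = pd.Series(parsed, name="group_id", dtype=object)
        ranks: dict[str, list[int]] = {}
        for pid, gene in parsed.items():
            ranks.setdefault(gene, []).append(
                int(_PHENOTYPE_ID_RE.match(pid).group("rank"))
            )
        for gene, rs in ranks.items():
            if sorted(rs) != list(range(1, len(rs) + 1)):
                raise ValueError(f"{gene}: component ranks not contiguous from 1: {sorted(rs)}")

    @classmethod
    def from_projections(cls, tables: list[pd.DataFrame]) -> "PhenotypeTable":
        nonempty = [t for t in tables if len(t)]
        if not nonempty:
            return cls(pd.DataFrame())
        return cls(pd.concat(nonempty, axis=0))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ModelStore:
    """All per-gene models plus their bin schemes and shared configuration."""

    models: dict[str, GenePCAModel]
    schemes: dict[str, BinScheme]
    config: dict = field(default_factory=dict)
    version: str = STORE_FORMAT_VERSION


def _scheme_to_json(s: BinScheme) -> dict:
    return {
        "gene_id": s.gene_id, "chrom": s.chrom, "strand": s.strand,
        "region_start": s.region_start, "region_end": s.region_end,
        "bins": s.bins, "removed_bins": s.removed_bins,
        "threshold": s.threshold, "provenance": s.provenance,
    }


def _scheme_from_json(d: dict) -> BinScheme:
    return BinScheme(
        gene_id=d["gene_id"], chrom=d["chrom"], strand=d["strand"],
        region_start=d["region_start"], region_end=d["region_end"],
        bins=[tuple(b) for b in d["bins"]],
        removed_bins=[tuple(b) for b in d["removed_bins"]],
        threshold=d["threshold"], provenance=d["provenance"],
    )


def save_models(store: ModelStore, path: str | os.PathLike) -> None:
    """Serialize a model store to a single zip archive (atomic write)."""
    meta = {
        "format_version": store.version,
        "config": store.config,
        "schemes": {g: _scheme_to_json(s) for g, s in store.schemes.items()},
        "models": {
            g: {
                "bin_ids": m.bin_ids,
                "n_components": m.n_components,
                "variance_target": m.variance_target,
                "max_components": m.max_components,
                "flavor": m.flavor,
            }
            for g, m in store.models.items()
        },
    }
    tmp = str(path) + ".tmp"
    with zipfile.ZipFile(tmp, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for g, m in store.models.items():
            buf = io.BytesIO()
            np.savez(
                buf,
                train_mean=m.train_mean, train_sd=m.train_sd,
                loadings=m.loadings,
                explained_variance_ratio=m.explained_variance_ratio,
            )
            zf.writestr(f"arrays/{g}.npz", buf.getvalue())
    os.replace(tmp, path)


def load_models(path: str | os.PathLike) -> ModelStore:
    """Load a model store; rejects archives with a different format version."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != STORE_FORMAT_VERSION:
            raise ValueError(
                f"model store version {meta['format_version']!r} is not "
                f"supported (expected {STORE_FORMAT_VERSION!r})"
            )
        models = {}
        for g, mm in meta["models"].items():
            with zf.open(f"arrays/{g}.npz") as fh:
                arrays = np.load(io.BytesIO(fh.read()))
                models[g] = GenePCAModel(
                    gene_id=g,
                    bin_ids=mm["bin_ids"],
                    train_mean=arrays["train_mean"],
                    train_sd=arrays["train_sd"],
                    loadings=arrays["loadings"],
                    explained_variance_ratio=arrays["explained_variance_ratio"],
                    n_components=mm["n_components"],
                    variance_target=mm["variance_target"],
                    max_components=mm["max_components"],
                    flavor=mm["flavor"],
                )
    schemes = {g: _scheme_from_json(d) for g, d in meta["schemes"].items()}
    return ModelStore(models, schemes, meta["config"], meta["format_version"])


def export_bed(
    table: PhenotypeTable,
    regions: dict[str, GeneRegion],
    bed_path: str | os.PathLike,
    group_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Write a grouped-phenotype BED (+ phenotype->gene group file).

    Rows carry the gene TSS as the position (start=TSS, end=TSS+1) and
    are sorted by chromosome then start, as grouped cis-QTL mappers
    expect. Returns the BED as a DataFrame.
    """
    rows = []
    for pid in table.values.index:
        gene = table.groups[pid]
        region = regions.get(gene)
        if region is None:
            raise ValueError(f"{gene}: no region metadata (chrom/TSS) for BED export")
        tss = region.tss
        rows.append((region.chrom, tss, tss + 1, pid))
    bed = pd.DataFrame(rows, columns=["#chr", "start", "end", "phenotype_id"])
    bed = pd.concat(
        [bed, table.values.reset_index(drop=True)], axis=1
    ).sort_values(["#chr", "start", "phenotype_id"], kind="stable")
    bed.to_csv(bed_path, sep="\t", index=False, float_format="%.17g")
    if group_path is not None:
        groups = pd.DataFrame({
            "phenotype_id": bed["phenotype_id"],
            "group_id": [table.groups[p] for p in bed["phenotype_id"]],
        })
        groups.to_csv(group_path, sep="\t", index=False, header=False)
    return bed
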