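"""Regressing knowledge-driven phenotypes out of binned coverage.

Residual data-driven phenotypes (rDDPs) are meant to complement an
existing panel of knowledge-driven phenotypes (KDPs: expression,
isoform ratio, intron excision ratio, alternative TSS/polyA, RNA
stability, ...). Before PCA, each bin's normalized coverage is
residualized against the gene's KDPs with a two-pass screen: an OLS fit
on all KDPs selects those with coefficient p < 0.01, a second fit on
the selected KDPs produces the predictions that are subtracted.

Rank-deficient KDP matrices are handled with the pseudoinverse;
coefficients lying in the null space get p = 1 and are never retained.
If nothing is retained the residual is the mean-centered response.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import BinnedCoverage

__all__ = [
    "KDPTable",
    "OLSResult",
    "ResidualizationReport",
    "ols_with_pvalues",
    "two_pass_residualize",
    "residualize_gene",
    "holdout_modality",
    "read_kdps",
    "write_kdps",
]

DEFAULT_RETENTION_ALPHA = 0.01
MAX_MISSING_FRACTION = 0.20


@dataclass
class KDPTable:
    """Knowledge-driven phenotypes for many genes.

    ``values``: DataFrame indexed by phenotype_id, columns = samples.
    ``meta``: DataFrame indexed by phenotype_id with columns gene_id and
    modality (free-form labels).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("KDP values and metadata indexes differ")
        missing = {"gene_id", "modality"} - set(self.meta.columns)
        if missing:
            raise ValueError(f"KDP metadata missing columns: {sorted(missing)}")

    @property
    def modalities(self) -> list[str]:
        return sorted(self.meta["modality"].unique())

    def genes(self) -> list[str]:
        return sorted(self.meta["gene_id"].unique())

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        """Samples x KDPs matrix for one gene (empty if absent)."""
        idx = self.meta.index[self.meta["gene_id"] == gene_id]
        return self.values.loc[idx].T


def holdout_modality(kdps: KDPTable, modality: str) -> KDPTable:
    """Drop one modality's phenotypes (held-out-modality experiments)."""
    if modality not in set(kdps.meta["modality"]):
        raise ValueError(
            f"unknown modality {modality!r}; available: {kdps.modalities}"
        )
    keep = kdps.meta.index[kdps.meta["modality"] != modality]
    return KDPTable(kdps.values.loc[keep].copy(), kdps.meta.loc[keep].copy())


@dataclass
class OLSResult:
    coefficients: np.ndarray  # intercept first
    p_values: np.ndarray      # per non-intercept column
    fitted: np.ndarray
    rank: int


def ols_with_pvalues(y: np.ndarray, K: np.ndarray) -> OLSResult:
    """OLS of y on [intercept, K] with two-sided t-test p-values.

    Uses the pseudoinverse so collinear KDP sets degrade gracefully:
    the residual degrees of freedom are n - rank(design), and any
    coefficient whose estimated variance is ~0 (null-space direction)
    gets p = 1.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), K])
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    fitted = X @ beta
    resid = y - fitted
    rank = int(np.linalg.matrix_rank(X))
    df = n - rank
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={rank})")
    sigma2 = float(resid @ resid) / df
    # diag((X'X)^+): zero only for null-space (e.g. all-zero) columns,
    # judged on the design geometry alone so a perfect fit (sigma2 = 0)
    # still yields p ~ 0 for its true predictors
    g = np.einsum("ij,ij->i", pinv, pinv)
    null_space = g <= np.finfo(float).eps * max(float(g.max()), 1.0)
    se = np.sqrt(sigma2 * g)
    t = np.zeros_like(beta)
    nonzero_beta = np.abs(beta) > 1e-12 * max(1.0, float(np.abs(beta).max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(nonzero_beta, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[null_space] = 1.0
    return OLSResult(beta, p[1:], fitted, rank)


def two_pass_residualize(
    y: np.ndarray,
    K: pd.DataFrame,
    alpha: float = DEFAULT_RETENTION_ALPHA,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Screen-then-refit residualization of one bin feature.

    Pass 1 regresses y on all KDPs jointly; KDPs with p < alpha are
    retained; pass 2 refits on the retained set and its predictions are
    subtracted. An empty retained set yields the centered response.

    Returns (residual, retained KDP ids, pass-1 p-values).
    """
    y = np.asarray(y, dtype=float)
    if K.shape[1] == 0:
        return y - y.mean(), [], np.empty(0)
    if len(y) != K.shape[0]:
        raise ValueError("response and KDP matrix sample counts differ")
    if len(y) < 3:
        raise ValueError("residualization requires >= 3 samples")
    if np.all(y == y[0]):
        # constant response (e.g. a zero-coverage bin): regression is
        # degenerate and would return float-noise residuals
        return np.zeros_like(y), [], np.ones(K.shape[1])
    first = ols_with_pvalues(y, K.to_numpy(dtype=float))
    retained = [kid for kid, p in zip(K.columns, first.p_values) if p < alpha]
    if not retained:
        return y - y.mean(), [], first.p_values
    second = ols_with_pvalues(y, K[retained].to_numpy(dtype=float))
    return y - second.fitted, retained, first.p_values


@dataclass
class ResidualizationReport:
    """Per-bin bookkeeping from residualizing one gene."""

    gene_id: str
    kdp_ids: list[str]
    retained: dict[str, list[str]] = field(default_factory=dict)
    first_pass_p: dict[str, np.ndarray] = field(default_factory=dict)
    residual_variance_fraction: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bin_id in self.retained:
            rows.append({
                "bin_id": bin_id,
                "n_retained": len(self.retained[bin_id]),
                "retained": ",".join(self.retained[bin_id]),
                "residual_variance_fraction":
                    self.residual_variance_fraction[bin_id],
            })
        return pd.DataFrame(rows)


def residualize_gene(
    X: BinnedCoverage,
    kdps: KDPTable,
    alpha: float = DEFAULT_RETENTION_ALPHA,
) -> tuple[BinnedCoverage, ResidualizationReport]:
    """Residualize every bin of one gene against the gene's KDPs.

    Bins are processed independently. Samples with missing KDP values
    are excluded from the fits; predictions for them use mean-imputed
    KDPs. More than 20% missing samples is refused. A gene with no
    KDPs yields the column-centered matrix.
    """
    if X.stage != "log2":
        raise ValueError(f"{X.gene_id}: expected stage log2, got {X.stage}")
    K = kdps.for_gene(X.gene_id)
    if len(K.columns):
        K = K.loc[list(X.sample_ids)]  # raises on misaligned samples
    else:
        K = pd.DataFrame(index=list(X.sample_ids))
    complete = ~K.isna().any(axis=1).to_numpy() if len(K.columns) else \
        np.ones(len(X.sample_ids), bool)
    frac_missing = 1.0 - complete.mean()
    if frac_missing > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{X.gene_id}: {frac_missing:.0%} of samples have missing KDPs "
            f"(limit {MAX_MISSING_FRACTION:.0%})"
        )
    K_imputed = K.fillna(K.mean()) if len(K.columns) else K

    report = ResidualizationReport(X.gene_id, list(K.columns))
    resid = np.empty_like(X.values)
    for j, bin_id in enumerate(X.bin_ids):
        y = X.values[:, j]
        if complete.all():
            r, kept, pvals = two_pass_residualize(y, K_imputed, alpha)
        else:
            _, kept, pvals = two_pass_residualize(
                y[complete], K_imputed.loc[complete], alpha
            )
            if kept:
                fit = ols_with_pvalues(
                    y[complete], K_imputed.loc[complete, kept].to_numpy(float)
                )
                design = np.column_stack(
                    [np.ones(len(y)), K_imputed[kept].to_numpy(float)]
                )
                r = y - design @ fit.coefficients
            else:
                r = y - y[complete].mean()
        resid[:, j] = r
        report.retained[bin_id] = kept
        report.first_pass_p[bin_id] = pvals
        var0 = float(np.var(y))
        report.residual_variance_fraction[bin_id] = (
            float(np.var(r)) / var0 if var0 > 0 else 0.0
        )
    return X.advance(resid, "residual"), report


def read_kdps(path: str | os.PathLike) -> KDPTable:
    """Read KDPs from TSV: gene_id, phenotype_id, modality, then samples."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "phenotype_id": str,
                                            "modality": str})
    required = ["gene_id", "phenotype_id", "modality"]
    if df.columns.tolist()[:3] != required:
        raise ValueError(f"KDP file must start with columns {required}")
    if df["phenotype_id"].duplicated().any():
        raise ValueError("duplicate KDP phenotype IDs")
    df = df.set_index("phenotype_id")
    meta = df[["gene_id", "modality"]]
    values = df.drop(columns=["gene_id", "modality"]).astype(float)
    return KDPTable(values, meta)


def write_kdps(kdps: KDPTable, path: str | os.PathLike) -> None:
    out = pd.concat([kdps.meta, kdps.values], axis=1)
    out.index.name = "phenotype_id"
    out = out.reset_index()[["gene_id", "phenotype_id", "modality",
                             *kdps.values.columns]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
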