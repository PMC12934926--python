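"""Tab-delimited matrix round-trip for binned coverage and phenotype tables.

Layout: rows = features, columns = samples, header row of sample IDs,
first column = feature ID. Floats are serialized with 17 significant
digits so read(write(x)) reproduces x to well below 1e-9.
"""

from __future__ import annotations

import os

import pandas as pd

__all__ = ["write_matrix", "read_matrix", "MatrixFormatError"]

FEATURE_COL = "feature_id"


class MatrixFormatError(ValueError):
    """Malformed matrix file: ragged rows or duplicate feature IDs."""


def write_matrix(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a features x samples DataFrame (index = feature IDs) as TSV."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate feature IDs: {dups[:5]}")
    out = table.copy()
    out.index.name = FEATURE_COL
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_matrix`; validates shape and IDs."""
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"{path}: duplicate feature IDs: {dups[:5]}")
    table.index.name = FEATURE_COL
    table.index = table.index.astype(str)
    return table
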