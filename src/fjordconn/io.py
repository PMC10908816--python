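"""Readers and writers for ASV tables, metadata and long-format matrices.

Dialects: TSV (tab-delimited, UTF-8, '.' decimal) for ASV tables (rows =
ASV ids, columns = sample ids, integer counts) and metadata; long-format CSV
for connectivity and distance tables; NetCDF-style gridded files for
velocity fields (see :class:`fjordconn.advection.VelocityField`).
"""

from __future__ import annotations

import logging
from pathlib import Path
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .composition import AsvTable

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def write_asv_table(table: AsvTable, path: str | Path,
                    annotation_path: str | Path | None = None) -> None:
    """Write counts as TSV with ASV rows and sample columns (and optionally
    the annotation table alongside)."""
    table.counts.T.rename_axis("asv_id").to_csv(path, sep="\t")
    if annotation_path is not None and table.annotations is not None:
        ann = table.annotations.copy()
        if table.taxonomy is not None:
            for c in table.taxonomy.columns:
                if c not in ann.columns:
                    ann[c] = table.taxonomy[c]
        ann.rename_axis("asv_id").to_csv(annotation_path, sep="\t")


def read_asv_table(path: str | Path, marker: str,
                   annotation_path: str | Path | None = None) -> AsvTable:
    """Read and validate a TSV ASV table (ASV rows × sample columns).

    Rejects duplicate ids, non-integer and negative cells with errors naming
    the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate ASV id(s) {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample id(s) {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number)
                          for t in df.dtypes]].tolist()
        raise ParseError(f"{path}: non-numeric column(s) {bad}")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ParseError(f"{path}: negative count at ASV {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ParseError(f"{path}: non-integer count at ASV {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    counts = df.T.astype(int)
    counts.index.name = "sample_id"
    ann = None
    tax = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        if "lineage" in ann.columns:
            tax = ann[["lineage"]]
    return AsvTable(counts=counts, marker=marker, taxonomy=tax,
                    annotations=ann)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("site_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise ParseError(f"{path}: duplicate site ids")
    return meta


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Symmetric distance matrix as long-format CSV (site_a, site_b, value)."""
    rows = [(a, b, dm[a, b]) for i, a in enumerate(dm.ids)
            for b in list(dm.ids)[i + 1:]]
    pd.DataFrame(rows, columns=["site_a", "site_b", "distance"]).to_csv(
        path, index=False)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path)
    ids = sorted(set(df["site_a"]) | set(df["site_b"]))
    idx = {s: i for i, s in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for row in df.itertuples(index=False):
        i, j = idx[row.site_a], idx[row.site_b]
        mat[i, j] = mat[j, i] = row.distance
    return DistanceMatrix(mat, ids=ids)
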