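"""Compositional treatment of ASV tables: filtering, zero replacement, CLR, Aitchison.

Amplicon counts are compositions: only relative information is meaningful.
The stack here is the standard one — drop uninformative or off-target ASVs,
replace count zeros by small positive proportions with a Bayesian-
multiplicative imputation, centre-log-ratio (CLR) transform, and measure
between-sample differences as Euclidean distance on CLR vectors (the
Aitchison distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: annotation flags that mark off-target ASVs per marker gene
OFFTARGET_FLAGS = {
    "16S": ("mitochondria", "chloroplast"),
    "18S": ("metazoa",),
}


class CompositionError(ValueError):
    pass


@dataclass
class AsvTable:
    """Samples × ASVs count table with optional taxonomy and annotations.

    ``counts`` is a pandas DataFrame (index = sample ids, columns = ASV ids,
    non-negative integers).  ``annotations`` (index = ASV id) may carry a
    ``flag`` column (off-target labels such as 'chloroplast') and a
    ``trophic_group`` column; ``taxonomy`` a ranked lineage per ASV.
    """

    counts: pd.DataFrame
    marker: str = "16S"
    taxonomy: Optional[pd.DataFrame] = None
    annotations: Optional[pd.DataFrame] = None
    dropped_samples: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise CompositionError("negative counts in ASV table")
        if self.counts.index.has_duplicates:
            raise CompositionError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise CompositionError("duplicate ASV ids")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asvs(self) -> list[str]:
        return list(self.counts.columns)


def filter_asvs(table: AsvTable) -> AsvTable:
    """ASV-table hygiene.

    Removes ASVs with total count ≤ 1 across all samples (singletons carry no
    reproducible signal), and ASVs flagged as organellar (mitochondria /
    chloroplast, 16S) or metazoan (18S).  Samples left with zero total reads
    are dropped and logged by id — never silently.
    """
    counts = table.counts
    keep = counts.sum(axis=0) > 1
    flags = OFFTARGET_FLAGS.get(table.marker, ())
    if table.annotations is not None and "flag" in table.annotations.columns:
        flagged = table.annotations["flag"].reindex(counts.columns)
        bad = flagged.isin(flags).fillna(False)
        keep &= ~bad
    filtered = counts.loc[:, keep]
    empty = filtered.sum(axis=1) == 0
    dropped = list(filtered.index[empty])
    if dropped:
        logger.warning("%s table: dropping %d empty sample(s) after "
                       "filtering: %s", table.marker, len(dropped), dropped)
        filtered = filtered.loc[~empty]
    tax = (table.taxonomy.loc[table.taxonomy.index.isin(filtered.columns)]
           if table.taxonomy is not None else None)
    ann = (table.annotations.loc[table.annotations.index.isin(filtered.columns)]
           if table.annotations is not None else None)
    return AsvTable(counts=filtered, marker=table.marker, taxonomy=tax,
                    annotations=ann, dropped_samples=dropped)


def replace_zeros(table: AsvTable | pd.DataFrame,
                  method: str = "GBM") -> pd.DataFrame:
    """Replace count zeros by positive proportions (Bayesian-multiplicative).

    Default is the geometric Bayesian-multiplicative (GBM) treatment: a zero
    of sample *i*, part *j* is imputed by its posterior expectation under a
    Dirichlet prior whose part proportions ``t_j`` follow the across-sample
    geometric mean of the observed proportions and whose strength is
    ``s_i = sqrt(n_i)`` (square-root prior), i.e. ``t_j * s_i / (n_i + s_i)``.
    Imputed values are capped below the sample's smallest observed nonzero
    proportion (at 65% of it, as is conventional) and the nonzero parts are
    shrunk multiplicatively so every row sums to 1.

    ``method='multiplicative'`` applies simple multiplicative replacement
    with a fixed imputed proportion (0.65 × the sample minimum); see also
    :func:`multiplicative_replacement` for an explicit delta.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    X = counts.to_numpy(dtype=float)
    n = X.sum(axis=1)
    nonzero_per_sample = (X > 0).sum(axis=1)
    if (nonzero_per_sample < 2).any():
        bad = counts.index[nonzero_per_sample < 2].tolist()
        raise CompositionError(f"degenerate sample(s) with < 2 nonzero ASVs: {bad}")
    P = X / n[:, None]

    if method == "multiplicative":
        out = P.copy()
        for i in range(P.shape[0]):
            row = P[i]
            z = row == 0
            if z.any():
                delta = 0.65 * row[row > 0].min()
                out[i] = _mult_replace_row(row, delta)
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    if method != "GBM":
        raise ValueError(f"unknown zero-replacement method {method!r}")

    # prior proportions: geometric mean of observed (nonzero) proportions
    logP = np.where(X > 0, np.log(P, where=X > 0,
                                  out=np.zeros_like(P)), np.nan)
    with np.errstate(invalid="ignore"):
        g = np.exp(np.nanmean(logP, axis=0))
    g = np.where(np.isfinite(g), g, np.nanmin(g[np.isfinite(g)]))
    t = g / g.sum()

    out = P.copy()
    s = np.sqrt(n)
    for i in range(P.shape[0]):
        row = P[i]
        z = row == 0
        if not z.any():
            continue
        repl = t[z] * s[i] / (n[i] + s[i])
        cap = 0.65 * row[~z].min()
        repl = np.minimum(repl, cap)
        new = row.copy()
        new[z] = repl
        new[~z] = row[~z] * (1.0 - repl.sum())
        out[i] = new
    result = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    assert (result.to_numpy() > 0).all()
    return result


def _mult_replace_row(row: np.ndarray, delta: float) -> np.ndarray:
    """Simple multiplicative replacement of one composition row."""
    z = row == 0
    new = row.copy()
    new[z] = delta
    new[~z] = row[~z] * (1.0 - delta * z.sum())
    return new


def multiplicative_replacement(row: np.ndarray, delta: float) -> np.ndarray:
    """Closed-form multiplicative zero replacement with an explicit delta.

    Zeros become ``delta``; nonzero parts are scaled by ``1 − z·delta`` where
    ``z`` is the number of zeros, so the row still sums to 1.
    """
    row = np.asarray(row, dtype=float)
    row = row / row.sum()
    return _mult_replace_row(row, delta)


def clr(proportions: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform, natural log.

    Each row is mapped to ``ln(part / geometric mean of the row)``; rows of
    the result sum to zero.  All entries must be strictly positive.
    """
    X = proportions.to_numpy(dtype=float)
    if (X <= 0).any():
        raise CompositionError("CLR requires strictly positive entries")
    L = np.log(X)
    L -= L.mean(axis=1, keepdims=True)
    return pd.DataFrame(L, index=proportions.index, columns=proportions.columns)


def aitchison(clr_matrix: pd.DataFrame) -> DistanceMatrix:
    """Aitchison distance: pairwise Euclidean distance between CLR rows."""
    d = squareform(pdist(clr_matrix.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in clr_matrix.index])


def aitchison_from_counts(table: AsvTable, method: str = "GBM",
                          ) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Counts → (CLR matrix, Aitchison distances) via filtering-free transform.

    Convenience chain: zero replacement then CLR then pairwise distances.
    Filtering is deliberately separate (see :func:`filter_asvs`).
    """
    p = replace_zeros(table, method=method)
    c = clr(p)
    return c, aitchison(c)
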