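"""Drifter concentration fields, connectivity matrices and hydrodynamic distance.

Trajectories are turned into ensemble-mean, age-binned concentration fields
(fraction of drifter-observations of a given age per grid cell, pooled over
cohorts and snapshots), then into release-site × receiving-site connectivity
by averaging the release site's concentration over a square window centred on
the receiver, and finally into the hydrodynamic-distance statistic: the
negative log10 of the symmetrized windowed concentration, min–max normalized
to [0, 1] within each age bin over the oceanographically connected pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .advection import STATUS_OUT, TrajectorySet, VelocityField


class ConnectivityError(RuntimeError):
    pass


@dataclass
class ConcentrationField:
    """Age-binned ensemble drifter concentration for one release site.

    ``conc[iy, ix]`` is the fraction of all pooled drifter-observations whose
    age fell in ``age_bin`` that were located in cell (iy, ix).  Observations
    of drifters that had left the domain enter the denominator only, so the
    field sums to 1 exactly when no drifter of that age was lost.
    """

    release_site: str
    age_bin: tuple[float, float]          # (min, max] days
    conc: np.ndarray                      # (ny, nx) fractions
    n_in_domain: int
    n_total: int

    @property
    def empty(self) -> bool:
        return self.n_total == 0


def concentration_field(trajectories: Iterable[TrajectorySet],
                        age_bin: tuple[float, float],
                        field: VelocityField) -> ConcentrationField:
    """Pool drifters of one release site into an age-binned concentration field.

    At every stored snapshot, drifters whose age lies in ``(lo, hi]`` are
    binned to the grid cell containing their position (beached drifters sit
    frozen at their beaching cell and are counted there); out-of-domain
    drifters are counted in the denominator only.
    """
    lo, hi = age_bin
    ny, nx = field.mask.shape
    counts = np.zeros((ny, nx), dtype=float)
    n_total = 0
    n_in = 0
    site = None
    for traj in trajectories:
        if site is None:
            site = traj.release_site
        ages = traj.ages
        sel = (ages > lo) & (ages <= hi)
        if not sel.any():
            continue
        pos = traj.positions[:, sel, :].reshape(-1, 2)
        stat = traj.status[:, sel].reshape(-1)
        n_total += stat.size
        in_dom = stat != STATUS_OUT
        n_in += int(in_dom.sum())
        if in_dom.any():
            iy, ix = field.cell_index(pos[in_dom])
            np.add.at(counts, (iy, ix), 1.0)
    conc = counts / n_total if n_total > 0 else counts
    return ConcentrationField(release_site=site or "", age_bin=(lo, hi),
                              conc=conc, n_in_domain=n_in, n_total=n_total)


def window_mean(conc: np.ndarray, center: tuple[int, int],
                window_size: int) -> float:
    """Mean concentration over a window centred on a cell.

    Land cells count in the denominator; windows are clipped at domain edges,
    which shrinks the averaging area.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be a positive odd integer")
    ny, nx = conc.shape
    iy, ix = center
    half = window_size // 2
    y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
    x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
    patch = conc[y0:y1, x0:x1]
    return float(patch.sum() / patch.size)


def connectivity_matrix(fields: Mapping[tuple[str, tuple[float, float]],
                                        ConcentrationField],
                        site_cells: Mapping[str, tuple[int, int]],
                        window_size: int = 15,
                        grid_shape: tuple[int, int] | None = None,
                        ) -> pd.DataFrame:
    """Windowed release→receive connectivity, long format.

    Parameters
    ----------
    fields : mapping (release_site, age_bin) -> ConcentrationField
    site_cells : mapping site id -> (iy, ix) grid cell of the site
    window_size : odd cell count of the averaging window (auto-capped at the
        grid's smaller dimension for toy grids).

    Returns a DataFrame with columns ``release``, ``receive``, ``bin_lo``,
    ``bin_hi``, ``concentration``.
    """
    rows = []
    for (release, age_bin), cf in fields.items():
        shape = grid_shape or cf.conc.shape
        w = min(window_size, (min(shape) - 1) | 1)  # odd, fits in grid
        for receive, cell in site_cells.items():
            if not (0 <= cell[0] < cf.conc.shape[0]
                    and 0 <= cell[1] < cf.conc.shape[1]):
                raise ConnectivityError(f"site {receive!r} cell {cell} "
                                        "outside the grid")
            rows.append({"release": release, "receive": receive,
                         "bin_lo": age_bin[0], "bin_hi": age_bin[1],
                         "concentration": window_mean(cf.conc, cell, w)})
    return pd.DataFrame(rows)


def hydrodynamic_distance(cm: pd.DataFrame, symmetrize: str = "max",
                          transform: str = "neglog") -> pd.DataFrame:
    """Hydrodynamic distance per unordered site pair and age bin.

    For each (pair, bin): the two directed windowed concentrations are
    symmetrized (default: their maximum — transport in either direction can
    homogenize communities); pairs with zero concentration both ways are
    marked unconnected and excluded from normalization.  The raw distance is
    −log10 of the symmetrized concentration (or 1/log10 with
    ``transform='reciprocal'``), min–max normalized to [0, 1] within each age
    bin over the connected pairs: 0 for the best-connected pair, 1 for the
    most weakly connected one.

    Returns a DataFrame with columns ``site_a``, ``site_b``, ``bin_lo``,
    ``bin_hi``, ``concentration``, ``distance``, ``connected``; unconnected
    pairs carry NaN distance.
    """
    if symmetrize not in ("max", "mean"):
        raise ValueError("symmetrize must be 'max' or 'mean'")
    if transform not in ("neglog", "reciprocal"):
        raise ValueError("transform must be 'neglog' or 'reciprocal'")
    df = cm[cm["release"] != cm["receive"]].copy()
    a = np.minimum(df["release"], df["receive"])
    b = np.maximum(df["release"], df["receive"])
    df["site_a"], df["site_b"] = a, b
    agg = "max" if symmetrize == "max" else "mean"
    sym = (df.groupby(["site_a", "site_b", "bin_lo", "bin_hi"],
                      as_index=False)["concentration"].agg(agg))
    out = []
    for (lo, hi), grp in sym.groupby(["bin_lo", "bin_hi"]):
        grp = grp.copy()
        connected = grp["concentration"] > 0
        raw = np.full(len(grp), np.nan)
        c = grp.loc[connected, "concentration"].to_numpy()
        if connected.any():
            if transform == "neglog":
                r = -np.log10(c)
            else:
                with np.errstate(divide="ignore"):
                    r = 1.0 / np.log10(c)
            rmin, rmax = r.min(), r.max()
            norm = (r - rmin) / (rmax - rmin) if rmax > rmin else np.zeros_like(r)
            raw[connected.to_numpy()] = norm
        else:
            warnings.warn(f"no connected pairs in age bin ({lo}, {hi}]")
        grp["distance"] = raw
        grp["connected"] = connected.to_numpy()
        out.append(grp)
    res = pd.concat(out, ignore_index=True)
    return res[["site_a", "site_b", "bin_lo", "bin_hi",
                "concentration", "distance", "connected"]]


def compute_connectivity(trajectories_by_site: Mapping[str, Sequence[TrajectorySet]],
                         field: VelocityField,
                         site_cells: Mapping[str, tuple[int, int]],
                         age_bins: Sequence[tuple[float, float]],
                         window_size: int = 15,
                         symmetrize: str = "max") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: trajectories → connectivity matrix → hydrodynamic distance.

    Returns ``(connectivity, hydro_distance)`` long-format tables.
    """
    fields = {}
    for site, trajs in trajectories_by_site.items():
        for age_bin in age_bins:
            fields[(site, tuple(age_bin))] = concentration_field(
                trajs, tuple(age_bin), field)
    cm = connectivity_matrix(fields, site_cells, window_size=window_size,
                             grid_shape=field.mask.shape)
    hd = hydrodynamic_distance(cm, symmetrize=symmetrize)
    return cm, hd


def hd_lookup(hd: pd.DataFrame) -> dict[tuple[str, str, float, float], float]:
    """Dict view of a hydrodynamic-distance table keyed by (a, b, lo, hi)."""
    out = {}
    for row in hd.itertuples(index=False):
        key = (row.site_a, row.site_b, row.bin_lo, row.bin_hi)
        out[key] = float(row.distance) if row.connected else np.nan
        out[(row.site_b, row.site_a, row.bin_lo, row.bin_hi)] = out[key]
    return out
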