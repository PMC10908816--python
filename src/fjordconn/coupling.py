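"""Connectivity–community coupling and trophic functional-group profiles.

The headline analyses: pick one representative (fjord-mouth) site per fjord,
tabulate every unordered representative-site pair with its Aitchison
distances (16S and 18S), per-age-bin hydrodynamic distance and absolute
temperature difference, then (i) correlate hydrodynamic with Aitchison
distance per temporal bin over the oceanographically connected pairs,
(ii) regress Aitchison distance on ΔT within and across bioclimatic
subzones, and (iii) aggregate CLR signal into trophic functional-group ×
domain profiles and test them between subzones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .diversity import TestResult, group_tests

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# representative sites and the pair table
# --------------------------------------------------------------------------

def select_representative_sites(meta: pd.DataFrame,
                                exclude: tuple[str, ...] = ()) -> list[str]:
    """One site per fjord: the one closest to the fjord mouth.

    Ties are broken deterministically by site id (and logged).  Sites listed
    in ``exclude`` are ignored (the field study excluded stations its ocean
    model's coastline could not resolve).
    """
    if "distance_to_mouth_km" not in meta.columns:
        raise KeyError("metadata must record distance_to_mouth_km")
    meta = meta.loc[~meta.index.isin(exclude)]
    chosen = []
    for fjord, grp in meta.groupby("fjord", sort=True):
        dmin = grp["distance_to_mouth_km"].min()
        cands = sorted(grp.index[grp["distance_to_mouth_km"] == dmin])
        if len(cands) > 1:
            logger.info("fjord %s: distance tie between %s; picking %s",
                        fjord, cands, cands[0])
        chosen.append(cands[0])
    return chosen


def build_pair_table(sites: list[str], d16: DistanceMatrix,
                     d18: DistanceMatrix, hd: pd.DataFrame,
                     meta: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered representative-site pair.

    Columns: ``site_a``, ``site_b``, ``aitchison_16s``, ``aitchison_18s``,
    ``delta_t`` (absolute temperature difference, °C), ``relation``
    (``within`` a bioclimatic subzone or ``crossing``), ``subzone_pair``,
    ``temp_a``/``temp_b`` and one ``hd_<lo>_<hi>`` column per age bin (NaN
    where the pair is not oceanographically connected).  Unconnected pairs
    stay in the table; they are excluded only inside correlations.
    """
    for s in sites:
        for dm, tag in ((d16, "16S"), (d18, "18S")):
            if s not in dm.ids:
                raise KeyError(f"site {s!r} missing from the {tag} "
                               "distance matrix")
        if s not in meta.index:
            raise KeyError(f"site {s!r} missing from metadata")
    lut = {}
    bins = sorted({(lo, hi) for lo, hi in
                   zip(hd["bin_lo"], hd["bin_hi"])})
    for row in hd.itertuples(index=False):
        key = (min(row.site_a, row.site_b), max(row.site_a, row.site_b),
               row.bin_lo, row.bin_hi)
        lut[key] = row.distance if row.connected else np.nan

    rows = []
    for a, b in itertools.combinations(sorted(sites), 2):
        rec = {
            "site_a": a, "site_b": b,
            "aitchison_16s": float(d16[a, b]),
            "aitchison_18s": float(d18[a, b]),
            "temp_a": float(meta.loc[a, "temperature_c"]),
            "temp_b": float(meta.loc[b, "temperature_c"]),
        }
        rec["delta_t"] = abs(rec["temp_a"] - rec["temp_b"])
        za, zb = meta.loc[a, "subzone"], meta.loc[b, "subzone"]
        rec["relation"] = "within" if za == zb else "crossing"
        rec["subzone_pair"] = " | ".join(sorted([za, zb]))
        for lo, hi in bins:
            rec[f"hd_{int(lo)}_{int(hi)}"] = lut.get((a, b, lo, hi), np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# coupling statistics
# --------------------------------------------------------------------------

@dataclass
class CorrelationRecord:
    bin_lo: float
    bin_hi: float
    marker: str
    r: float
    p: float
    n_pairs: int


def correlate_hd_beta(pairs: pd.DataFrame, marker: str,
                      bins=None) -> list[CorrelationRecord]:
    """Pearson correlation of hydrodynamic vs Aitchison distance per age bin.

    Only oceanographically connected pairs enter each bin's correlation;
    bins with fewer than 3 connected pairs, or with zero variance in
    hydrodynamic distance, are skipped with a warning.
    """
    col = _marker_column(marker)
    hd_cols = [c for c in pairs.columns if c.startswith("hd_")]
    if bins is not None:
        wanted = {f"hd_{int(lo)}_{int(hi)}" for lo, hi in bins}
        hd_cols = [c for c in hd_cols if c in wanted]
    out = []
    for c in hd_cols:
        lo, hi = (float(v) for v in c.split("_")[1:])
        sub = pairs[[c, col]].dropna()
        if len(sub) < 3:
            logger.warning("bin (%g, %g]: only %d connected pairs, skipped",
                           lo, hi, len(sub))
            continue
        if sub[c].nunique() == 1:
            logger.warning("bin (%g, %g]: hydrodynamic distance constant, "
                           "correlation undefined", lo, hi)
            out.append(CorrelationRecord(lo, hi, marker, np.nan, np.nan,
                                         len(sub)))
            continue
        r, p = stats.pearsonr(sub[c], sub[col])
        out.append(CorrelationRecord(lo, hi, marker, float(r), float(p),
                                     len(sub)))
    return out


@dataclass
class RegressionRecord:
    marker: str
    scope: str
    slope: float
    intercept: float
    r: float
    slope_ci_low: float
    slope_ci_high: float
    p: float
    n: int


def _marker_column(marker: str) -> str:
    m = marker.lower().replace(" ", "")
    if m in ("16s", "pro", "prokaryote"):
        return "aitchison_16s"
    if m in ("18s", "euk", "eukaryote"):
        return "aitchison_18s"
    raise ValueError(f"unknown marker {marker!r}")


def beta_vs_deltaT(pairs: pd.DataFrame, marker: str,
                   scope: str = "all") -> RegressionRecord:
    """OLS regression of Aitchison distance on |ΔT| for one pair scope.

    ``scope`` is ``'all'``, ``'within'`` (same-subzone pairs),
    ``'crossing'``, or a specific ``subzone_pair`` label.  The 95% CI of the
    slope uses the t distribution on n − 2 degrees of freedom.
    """
    col = _marker_column(marker)
    if scope == "all":
        sub = pairs
    elif scope in ("within", "crossing"):
        sub = pairs[pairs["relation"] == scope]
    else:
        sub = pairs[pairs["subzone_pair"] == scope]
    sub = sub[["delta_t", col]].dropna()
    if len(sub) < 3:
        raise ValueError(f"scope {scope!r}: fewer than 3 pairs")
    if sub["delta_t"].nunique() == 1:
        logger.warning("scope %r: ΔT has zero variance, slope undefined",
                       scope)
        return RegressionRecord(marker, scope, np.nan, np.nan, np.nan,
                                np.nan, np.nan, np.nan, len(sub))
    res = stats.linregress(sub["delta_t"], sub[col])
    tcrit = stats.t.ppf(0.975, len(sub) - 2)
    return RegressionRecord(
        marker=marker, scope=scope, slope=float(res.slope),
        intercept=float(res.intercept), r=float(res.rvalue),
        slope_ci_low=float(res.slope - tcrit * res.stderr),
        slope_ci_high=float(res.slope + tcrit * res.stderr),
        p=float(res.pvalue), n=len(sub))


# --------------------------------------------------------------------------
# trophic functional-group profiles
# --------------------------------------------------------------------------

TROPHIC_GROUPS = ("autotroph", "mixotroph", "heterotroph", "unknown")
DOMAINS = ("prokaryote", "eukaryote")


def trophic_profiles(clr16: pd.DataFrame, clr18: pd.DataFrame,
                     annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample trophic functional-group × domain signal fractions.

    The two independently CLR-transformed tables are concatenated per
    sample; the concatenated vector is shifted by its minimum (making all
    contributions non-negative) and divided by its total, so contributions
    sum to 1; shifted-normalized contributions are then summed within each
    (trophic group × domain) cell.  Unknown-trophy ASVs form explicit
    ``unknown`` cells so the normalization is preserved.

    ``annotations`` must index every ASV of both matrices and carry
    ``trophic_group`` and ``domain`` columns.
    """
    if list(clr16.index) != list(clr18.index):
        common = clr16.index.intersection(clr18.index)
        missing = set(clr16.index).symmetric_difference(clr18.index)
        if missing:
            raise KeyError(f"samples present in only one matrix: "
                           f"{sorted(missing)}")
        clr18 = clr18.loc[common]
    merged = pd.concat([clr16, clr18], axis=1)
    unknown_asvs = [a for a in merged.columns if a not in annotations.index]
    if unknown_asvs:
        raise KeyError(f"unannotated ASV(s): {unknown_asvs[:5]}")
    ann = annotations.loc[merged.columns]
    groups = ann["trophic_group"].to_numpy()
    domains = ann["domain"].to_numpy()

    X = merged.to_numpy(dtype=float)
    X = X - X.min(axis=1, keepdims=True)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = X / totals

    cols = {}
    for g in TROPHIC_GROUPS:
        for d in DOMAINS:
            sel = (groups == g) & (domains == d)
            cols[f"{g}_{d}"] = X[:, sel].sum(axis=1)
    prof = pd.DataFrame(cols, index=merged.index)
    prof.attrs["normalization"] = "min-shift then sum-to-1 per sample"
    return prof


def eukaryote_share(profiles: pd.DataFrame) -> pd.DataFrame:
    """Eukaryote fraction of each trophic group's signal, per sample."""
    out = {}
    for g in TROPHIC_GROUPS[:3]:
        e = profiles[f"{g}_eukaryote"]
        p = profiles[f"{g}_prokaryote"]
        tot = e + p
        out[g] = (e / tot).where(tot > 0)
    return pd.DataFrame(out, index=profiles.index)


def trophic_group_tests(profiles: pd.DataFrame, subzones: pd.Series,
                        merge_arctic: bool = True,
                        scheme: str = "anova_welch",
                        ) -> dict[str, list[TestResult]]:
    """Group tests of each trophic × domain cell between bioclimatic subzones.

    With ``merge_arctic`` (default), high and low Arctic samples merge into
    one ``Arctic`` class before testing — the conventional remedy for small
    polar sample sizes.  Bonferroni adjustment is applied within each cell's
    pairwise family by :func:`fjordconn.diversity.group_tests`.
    """
    zones = subzones.loc[profiles.index].astype(str)
    if merge_arctic:
        zones = zones.replace({"high Arctic": "Arctic", "low Arctic": "Arctic"})
    counts = zones.value_counts()
    usable = counts[counts >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 subzones with >= 2 samples each")
    results = {}
    for cell in profiles.columns:
        results[cell] = group_tests(profiles[cell].to_numpy(),
                                    zones.to_numpy(), scheme=scheme)
    return results
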