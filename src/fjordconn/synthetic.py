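"""Synthetic fjord-chain scenarios with planted community structure.

A scenario is a desk-scale caricature of a high-latitude fjord system: a
chain of fjords notched into a coastline, strung along a boundary current
that flows from the warm (temperate) end of the domain to the cold (high
Arctic) end; a monotone along-path temperature gradient with one sharp
inter-subzone step; and two marker-gene ASV tables (16S prokaryotes, 18S
picoeukaryotes) whose between-site compositional divergence is *planted*:
the latent per-site CLR vectors follow a Gaussian random walk along the
chain of fjord-mouth sites whose step variance is a linear function of
hydrodynamic distance and temperature difference, so the expected Aitchison
distance between sites grows with
``decay_rate × hydrodynamic distance + temp_sensitivity × |ΔT|``.

Two further features mimic the contrast between the domains: a fraction of
prokaryotic ASVs is excluded entirely at cold sites (a planted richness
penalty that grows with site coldness), and each ASV carries a thermal-niche
value that both tilts its abundance along the gradient (scaled by the
domain's temperature sensitivity) and biases its trophic annotation, so that
cold sites end up eukaryote-heavy within each trophic group.

Everything is reproducible bit-for-bit from the :class:`ScenarioConfig`
seed, and the planted truth is returned alongside the tables so recovery
tests can compute expected divergences without rerunning generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .advection import VelocityField, run_site, TrajectorySet
from .composition import AsvTable
from .config import ConfigError, ScenarioConfig, SeedingSchedule, DEFAULT_AGE_BINS
from .connectivity import compute_connectivity, hd_lookup

SUBZONES = ("temperate", "subarctic", "low Arctic", "high Arctic")

#: land rows at the bottom ("coast") edge of the grid
COAST_ROWS = 4
#: how far (cells) the fjord notch cuts into the land strip
NOTCH_DEPTH = 3
#: fjord notch width in cells
NOTCH_WIDTH = 2
#: CLR variance of within-fjord (head/middle vs mouth) jitter
WITHIN_FJORD_VAR = 0.05
#: scales the thermal-niche abundance tilt relative to temp_sensitivity
NICHE_TILT_SCALE = 25.0


class SizingError(ConfigError):
    pass


# --------------------------------------------------------------------------
# velocity field
# --------------------------------------------------------------------------

def _fjord_columns(config: ScenarioConfig) -> np.ndarray:
    """Along-shore grid column of each fjord notch (left edge)."""
    margin = 4
    usable = config.grid_nx - 2 * margin
    spacing = usable / config.n_fjords
    if spacing < NOTCH_WIDTH + 1:
        raise SizingError(
            f"grid_nx={config.grid_nx} too small for {config.n_fjords} fjords")
    return (margin + np.arange(config.n_fjords) * spacing).astype(int)


def generate_velocity_field(config: ScenarioConfig,
                            n_days: Optional[int] = None) -> VelocityField:
    """Boundary-current velocity field over a notched coastline.

    Land occupies the bottom ``COAST_ROWS`` rows except at fjord notches
    (2-cell-wide, 3-cell-deep indentations).  The along-shore current flows
    in +x with a smooth cross-shore profile peaking just off the coast, and
    meanders in time and space with amplitude ``meander_amplitude`` (also
    driving a weak outflow from each fjord).  All speeds stay below
    ``2 × current_speed``; with ``meander_amplitude = 0`` the flow is purely
    along-channel (v ≡ 0 everywhere off land).
    """
    nx, ny = config.grid_nx, config.grid_ny
    if nx < 16 or ny < 16:
        raise SizingError("velocity grid must be at least 16x16")
    cols = _fjord_columns(config)

    mask = np.ones((ny, nx), dtype=bool)
    mask[:COAST_ROWS, :] = False           # land strip along the coast edge
    notch_rows = slice(COAST_ROWS - NOTCH_DEPTH, COAST_ROWS)
    for c in cols:
        mask[notch_rows, c:c + NOTCH_WIDTH] = True   # fjord indentation

    if n_days is None:
        n_days = 60
    time = np.arange(n_days, dtype=float)
    x = (np.arange(nx) + 0.5) * config.cell_size
    y = (np.arange(ny) + 0.5) * config.cell_size

    c0 = config.current_speed
    # cross-shore jet profile: zero on the coast row, peak ~3 rows offshore
    yy = np.arange(ny, dtype=float)
    offshore = np.clip(yy - (COAST_ROWS - 1), 0.0, None)
    jet = (offshore / 3.0) * np.exp(1.0 - offshore / 3.0)
    jet = np.clip(jet, 0.0, 1.0)

    u = np.zeros((n_days, ny, nx))
    v = np.zeros((n_days, ny, nx))
    xx = np.arange(nx, dtype=float)
    wavelength = max(nx / 6.0, 8.0)
    amp = config.meander_amplitude * c0
    for it, t in enumerate(time):
        phase = 2.0 * np.pi * t / 60.0
        u[it] = c0 * jet[:, None]
        v[it] = (amp * np.sin(2.0 * np.pi * xx[None, :] / wavelength + phase)
                 * (jet[:, None] > 0.05))
        # weak fjord outflow pushing drifters out of the notch into the jet
        for c in cols:
            v[it, notch_rows, c:c + NOTCH_WIDTH] = 0.5 * amp
    u *= mask[None, :, :]
    v *= mask[None, :, :]
    np.clip(u, -2 * c0, 2 * c0, out=u)
    np.clip(v, -2 * c0, 2 * c0, out=v)
    return VelocityField(x=x, y=y, time=time, u=u, v=v, mask=mask)


# --------------------------------------------------------------------------
# site network
# --------------------------------------------------------------------------

def _subzone(frac: float, barrier: float) -> str:
    """Bioclimatic subzone from along-path fraction; the barrier separates
    subarctic from low Arctic."""
    if frac < barrier / 2:
        return "temperate"
    if frac < barrier:
        return "subarctic"
    if frac < (1 + barrier) / 2:
        return "low Arctic"
    return "high Arctic"


def generate_site_network(config: ScenarioConfig,
                          field: Optional[VelocityField] = None) -> pd.DataFrame:
    """Sample metadata for the fjord chain.

    Each fjord gets three sites (head / middle / mouth along the notch) with
    recorded distance to the fjord mouth; the mouth site is flagged
    ``representative``.  Temperature decreases monotonically downstream with
    one ``barrier_step`` °C drop at ``barrier_position``; nutrient
    concentrations are enriched toward fjord heads; subzone labels follow the
    along-path position.
    """
    if config.n_fjords < 3:
        raise ConfigError("need at least 3 fjords")
    if field is None:
        field = generate_velocity_field(config, n_days=1)
    cols = _fjord_columns(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cold, warm = config.temp_range
    smooth_drop = (warm - cold) - config.barrier_step

    rows = []
    n = config.n_fjords
    for k, c in enumerate(cols):
        frac = k / (n - 1) if n > 1 else 0.0
        t_fjord = warm - smooth_drop * frac
        if frac >= config.barrier_position:
            t_fjord -= config.barrier_step
        subzone = _subzone(frac, config.barrier_position)
        fjord = f"fjord_{k:02d}"
        region = f"region_{k // 4}"
        # sites along the notch: head (innermost) -> mouth (at the opening)
        site_rows = [COAST_ROWS - NOTCH_DEPTH, COAST_ROWS - 2, COAST_ROWS - 1]
        names = ["head", "middle", "mouth"]
        mouth_iy = site_rows[-1]
        for name, iy in zip(names, site_rows):
            ix = c
            dist = (mouth_iy - iy) * config.cell_size
            temp = t_fjord + 0.1 * (dist / config.cell_size) \
                + rng.normal(0.0, 0.05)
            coldness = (warm - t_fjord) / (warm - cold)
            head_frac = dist / ((NOTCH_DEPTH - 1) * config.cell_size)
            rows.append({
                "site_id": f"{fjord}_{name}",
                "fjord": fjord,
                "region": region,
                "subzone": subzone,
                "grid_ix": ix, "grid_iy": iy,
                "x_km": float(field.x[ix]), "y_km": float(field.y[iy]),
                "distance_to_mouth_km": float(dist),
                "temperature_c": float(temp),
                "salinity_psu": float(34.5 - 2.0 * head_frac
                                      - 0.5 * coldness
                                      + rng.normal(0, 0.1)),
                "no3_umol_l": float(max(0.05, 4.0 + 3.0 * head_frac
                                        + 2.0 * coldness
                                        + rng.normal(0, 0.4))),
                "po4_umol_l": float(max(0.01, 0.4 + 0.3 * head_frac
                                        + 0.2 * coldness
                                        + rng.normal(0, 0.05))),
                "si_umol_l": float(max(0.05, 3.0 + 2.5 * head_frac
                                       + 1.5 * coldness
                                       + rng.normal(0, 0.3))),
                "fluorescence": float(np.exp(rng.normal(0.5, 0.4))),
                "bottom_depth_m": float(rng.uniform(60, 320)),
                "sun_elevation_deg": float(35.0 - 20.0 * frac
                                           + rng.normal(0, 1.0)),
                "representative": name == "mouth",
            })
    meta = pd.DataFrame(rows).set_index("site_id")
    iy, ix = meta["grid_iy"].to_numpy(), meta["grid_ix"].to_numpy()
    assert field.mask[iy, ix].all(), "every site must sit on an ocean cell"
    return meta


# --------------------------------------------------------------------------
# ASV tables
# --------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted parameters of a scenario, for recovery tests.

    ``latent_pro`` / ``latent_euk`` hold the per-site latent log-abundance
    vectors (sites × ASVs); CLR-centring a row and differencing two rows
    gives the expected (noise-free) Aitchison geometry.  ``excluded`` maps a
    site to the prokaryotic ASV indices forced absent there.
    """

    config: ScenarioConfig
    site_order: list[str]
    coldness: pd.Series
    latent_pro: pd.DataFrame
    latent_euk: pd.DataFrame
    step_var_pro: pd.Series
    step_var_euk: pd.Series
    niche_pro: np.ndarray
    niche_euk: np.ndarray
    excluded: dict[str, np.ndarray]

    def expected_clr(self, domain: str) -> pd.DataFrame:
        z = self.latent_pro if domain == "pro" else self.latent_euk
        arr = z.to_numpy(dtype=float)
        return pd.DataFrame(arr - arr.mean(axis=1, keepdims=True),
                            index=z.index, columns=z.columns)

    def expected_aitchison(self, domain: str, site_a: str,
                           site_b: str) -> float:
        c = self.expected_clr(domain)
        diff = c.loc[site_a].to_numpy() - c.loc[site_b].to_numpy()
        return float(np.sqrt((diff ** 2).sum()))

    def save(self, path: str | Path) -> None:
        rec = {
            "config": self.config.to_dict(),
            "site_order": self.site_order,
            "coldness": self.coldness.to_dict(),
            "step_var_pro": self.step_var_pro.to_dict(),
            "step_var_euk": self.step_var_euk.to_dict(),
            "niche_pro": self.niche_pro.tolist(),
            "niche_euk": self.niche_euk.tolist(),
            "excluded": {k: v.tolist() for k, v in self.excluded.items()},
            "latent_pro": self.latent_pro.round(6).to_dict(orient="index"),
            "latent_euk": self.latent_euk.round(6).to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(rec))


def generate_asv_tables(meta: pd.DataFrame, hd: pd.DataFrame,
                        config: ScenarioConfig,
                        ) -> tuple[AsvTable, AsvTable, pd.DataFrame,
                                   SyntheticTruth]:
    """Two-domain ASV tables with planted distance-decay and thermal structure.

    The latent CLR-space vector of each representative (fjord-mouth) site
    follows a Gaussian random walk along the downstream site chain; the step
    variance per coordinate between consecutive representative sites is
    ``decay_rate × hd_step + temp_sensitivity × |ΔT_step|`` (hydrodynamic
    distance from the widest age bin of ``hd``; unconnected steps count as
    distance 1).  Head and middle sites jitter around their fjord's mouth
    vector.  Each ASV carries a thermal niche in [0, 1] that (i) tilts its
    latent abundance along the coldness gradient, scaled by the domain's
    temperature sensitivity, and (ii) biases its trophic annotation
    (cold-niche eukaryotes are more often annotated, cold-niche prokaryotes
    more often unknown).  At cold sites a coldness-proportional fraction of
    prokaryotic ASVs — up to ``richness_cold_penalty_pro`` at the coldest
    site — is excluded before multinomial sampling at ``seq_depth`` reads.

    Returns ``(asv_pro, asv_euk, trophic_annotation, truth)``.
    """
    reps = meta[meta["representative"]].copy()
    reps = reps.sort_values("grid_ix")
    rep_ids = list(reps.index)
    widest = hd.loc[hd["bin_hi"] == hd["bin_hi"].max()]
    lut = hd_lookup(widest)
    missing = [s for s in rep_ids
               if not any(k[0] == s for k in lut)]
    if missing:
        raise KeyError(f"connectivity table missing site(s): {missing}")

    temps = meta["temperature_c"]
    cold_t, warm_t = temps.min(), temps.max()
    coldness = ((warm_t - temps) / (warm_t - cold_t)
                if warm_t > cold_t else temps * 0.0)

    def hd_step(a: str, b: str) -> float:
        key = (min(a, b), max(a, b),
               float(widest["bin_lo"].iloc[0]), float(widest["bin_hi"].iloc[0]))
        val = lut.get(key, np.nan)
        return float(val) if np.isfinite(val) else 1.0

    tables: dict[str, pd.DataFrame] = {}
    latents: dict[str, pd.DataFrame] = {}
    step_vars: dict[str, pd.Series] = {}
    niches: dict[str, np.ndarray] = {}
    excluded: dict[str, np.ndarray] = {}
    annot_rows = []

    domain_params = {
        "pro": (config.n_asv_pro, config.decay_rate_pro,
                config.temp_sensitivity_pro, 2),
        "euk": (config.n_asv_euk, config.decay_rate_euk,
                config.temp_sensitivity_euk, 3),
    }
    for domain, (n_asv, decay, sens, salt) in domain_params.items():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, salt]))
        niche = rng.random(n_asv)
        niches[domain] = niche

        # random walk along the representative-site chain
        z = {rep_ids[0]: rng.normal(0.0, 1.0, size=n_asv)}
        svar = {}
        for a, b in zip(rep_ids[:-1], rep_ids[1:]):
            dT = abs(temps[a] - temps[b])
            var = decay * hd_step(a, b) + sens * dT
            svar[b] = var
            z[b] = z[a] + rng.normal(0.0, np.sqrt(max(var, 0.0)), size=n_asv)
        step_vars[domain] = pd.Series(svar)

        # all sites: mouth vector + within-fjord jitter + thermal-niche tilt
        tilt_mag = NICHE_TILT_SCALE * sens
        rows = {}
        for fjord, grp in meta.groupby("fjord", sort=False):
            mouth = grp.index[grp["representative"]][0]
            for site in grp.index:
                base = z[mouth].copy()
                if site != mouth:
                    base = base + rng.normal(
                        0.0, np.sqrt(WITHIN_FJORD_VAR), size=n_asv)
                base = base + (tilt_mag * (niche - 0.5)
                               * (coldness[site] - 0.5))
                rows[site] = base
        latent = pd.DataFrame.from_dict(rows, orient="index")
        latent = latent.loc[meta.index]
        latent.columns = [f"{domain}_{i:04d}" for i in range(n_asv)]
        latents[domain] = latent

        # occupancy exclusion (prokaryotes only): nested, coldness-scaled
        perm = rng.permutation(n_asv)
        probs = np.exp(latent.to_numpy()
                       - latent.to_numpy().max(axis=1, keepdims=True))
        for si, site in enumerate(latent.index):
            if domain == "pro" and config.richness_cold_penalty_pro > 0:
                frac = config.richness_cold_penalty_pro * coldness[site]
                n_out = int(round(frac * n_asv))
                out_idx = perm[:n_out]
                probs[si, out_idx] = 0.0
                if site not in excluded or domain == "pro":
                    excluded[site] = np.sort(out_idx)
        probs /= probs.sum(axis=1, keepdims=True)
        counts = np.vstack([
            rng.multinomial(config.seq_depth, probs[i])
            for i in range(probs.shape[0])])
        tables[domain] = pd.DataFrame(counts, index=latent.index,
                                      columns=latent.columns)

        # trophic annotation biased by thermal niche
        if domain == "euk":
            p_unknown = 0.85 - 0.75 * niche     # cold-niche euks well annotated
            split = np.array([0.35, 0.25, 0.40])  # auto, mixo, hetero
            flag_label = "metazoa"
        else:
            p_unknown = 0.10 + 0.75 * niche     # cold-niche pros poorly known
            split = np.array([0.25, 0.15, 0.60])
            flag_label = "chloroplast"
        u = rng.random(n_asv)
        v = rng.random(n_asv)
        labels = np.where(u < p_unknown, "unknown", "")
        groups = np.array(["autotroph", "mixotroph", "heterotroph"])
        edges = np.cumsum(split)
        picked = groups[np.searchsorted(edges, v * edges[-1], side="right")
                        .clip(0, 2)]
        labels = np.where(labels == "", picked, labels)
        flags = np.where(rng.random(n_asv) < 0.02, flag_label, "")
        for i, asv in enumerate(latent.columns):
            annot_rows.append({
                "asv_id": asv,
                "domain": "prokaryote" if domain == "pro" else "eukaryote",
                "trophic_group": labels[i],
                "flag": flags[i],
                "lineage": f"{'Bacteria' if domain == 'pro' else 'Eukaryota'};"
                           f"clade_{i % 8};family_{i % 23}",
            })

    trophic = pd.DataFrame(annot_rows).set_index("asv_id")
    taxonomy = trophic[["lineage"]]
    asv_pro = AsvTable(counts=tables["pro"], marker="16S",
                       taxonomy=taxonomy.loc[tables["pro"].columns],
                       annotations=trophic.loc[tables["pro"].columns,
                                               ["flag", "trophic_group",
                                                "domain"]])
    asv_euk = AsvTable(counts=tables["euk"], marker="18S",
                       taxonomy=taxonomy.loc[tables["euk"].columns],
                       annotations=trophic.loc[tables["euk"].columns,
                                               ["flag", "trophic_group",
                                                "domain"]])
    truth = SyntheticTruth(
        config=config, site_order=rep_ids, coldness=coldness,
        latent_pro=latents["pro"], latent_euk=latents["euk"],
        step_var_pro=step_vars["pro"], step_var_euk=step_vars["euk"],
        niche_pro=niches["pro"], niche_euk=niches["euk"],
        excluded=excluded)
    return asv_pro, asv_euk, trophic, truth


# --------------------------------------------------------------------------
# full scenario
# --------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    field: VelocityField
    metadata: pd.DataFrame
    connectivity: pd.DataFrame
    hydro_distance: pd.DataFrame
    asv_pro: AsvTable
    asv_euk: AsvTable
    trophic: pd.DataFrame
    truth: SyntheticTruth
    trajectories: dict[str, list[TrajectorySet]] | None = None


def generate_scenario(config: ScenarioConfig,
                      schedule: SeedingSchedule | None = None,
                      age_bins=DEFAULT_AGE_BINS,
                      window_size: int = 15,
                      dt: float = 0.25,
                      keep_trajectories: bool = False) -> SyntheticScenario:
    """Generate a complete synthetic scenario.

    Runs the physical chain for the representative (fjord-mouth) sites —
    velocity field, drifter cohorts, connectivity, hydrodynamic distance —
    then plants the two-domain community structure on top of it.
    """
    schedule = schedule or SeedingSchedule()
    age_bins = [tuple(b) for b in age_bins
                if b[1] <= schedule.lifetime + 1e-9]
    if not age_bins:
        raise ConfigError("no age bin fits within the drifter lifetime")
    n_days = int(np.ceil(schedule.span)) + 2
    field = generate_velocity_field(config, n_days=n_days)
    meta = generate_site_network(config, field)
    reps = meta[meta["representative"]]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    trajs = {}
    for site in reps.index:
        pos = (float(reps.loc[site, "x_km"]), float(reps.loc[site, "y_km"]))
        trajs[site] = run_site(site, pos, field, schedule, rng, dt=dt)
    site_cells = {s: (int(reps.loc[s, "grid_iy"]), int(reps.loc[s, "grid_ix"]))
                  for s in reps.index}
    cm, hd = compute_connectivity(trajs, field, site_cells, age_bins,
                                  window_size=window_size)
    asv_pro, asv_euk, trophic, truth = generate_asv_tables(meta, hd, config)
    return SyntheticScenario(
        config=config, field=field, metadata=meta, connectivity=cm,
        hydro_distance=hd, asv_pro=asv_pro, asv_euk=asv_euk,
        trophic=trophic, truth=truth,
        trajectories=trajs if keep_trajectories else None)
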