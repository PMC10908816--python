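"""Synthetic scenario generation: fields, site networks, planted communities."""

import numpy as np
import pandas as pd
import pytest

from fjordconn import (ScenarioConfig, SeedingSchedule, generate_asv_tables,
                       generate_scenario, generate_site_network,
                       generate_velocity_field)
from fjordconn.config import ConfigError
from fjordconn.synthetic import SizingError


class TestVelocityField:
    def test_zero_meander_means_no_cross_flow(self):
        cfg = ScenarioConfig(n_fjords=5, grid_nx=48, grid_ny=16,
                             meander_amplitude=0.0)
        field = generate_velocity_field(cfg, n_days=5)
        assert np.all(field.v[:, field.mask] == 0.0)

    def test_speed_bounded_by_twice_current_speed(self):
        cfg = ScenarioConfig(n_fjords=8, grid_nx=64, grid_ny=20,
                             meander_amplitude=1.5, current_speed=7.0)
        field = generate_velocity_field(cfg, n_days=10)
        assert np.abs(field.u).max() <= 2 * 7.0 + 1e-12
        assert np.abs(field.v).max() <= 2 * 7.0 + 1e-12

    def test_deterministic_regeneration(self):
        cfg = ScenarioConfig(n_fjords=5, grid_nx=48, grid_ny=16, seed=3)
        f1 = generate_velocity_field(cfg, n_days=8)
        f2 = generate_velocity_field(cfg, n_days=8)
        np.testing.assert_array_equal(f1.u, f2.u)
        np.testing.assert_array_equal(f1.v, f2.v)
        np.testing.assert_array_equal(f1.mask, f2.mask)

    def test_land_strip_and_fjord_notches(self):
        cfg = ScenarioConfig(n_fjords=5, grid_nx=48, grid_ny=16)
        field = generate_velocity_field(cfg, n_days=2)
        assert not field.mask[0].any()          # coast edge is land
        assert field.mask[-1].all()             # open water offshore
        assert field.mask[1:4].any()            # fjord indentations exist

    def test_too_many_fjords_raises_sizing_error(self):
        with pytest.raises(SizingError):
            cfg = ScenarioConfig(n_fjords=30, grid_nx=48, grid_ny=16)
            generate_velocity_field(cfg, n_days=2)


class TestSiteNetwork:
    def test_21_fjords_give_21_representatives_210_pairs(self):
        cfg = ScenarioConfig(n_fjords=21, grid_nx=128, grid_ny=24)
        meta = generate_site_network(cfg)
        reps = meta[meta["representative"]]
        assert len(reps) == 21
        k = len(reps)
        assert k * (k - 1) // 2 == 210

    def test_one_representative_per_fjord_at_minimum_distance(self):
        cfg = ScenarioConfig(n_fjords=6, grid_nx=48, grid_ny=16)
        meta = generate_site_network(cfg)
        for _, grp in meta.groupby("fjord"):
            reps = grp[grp["representative"]]
            assert len(reps) == 1
            assert reps["distance_to_mouth_km"].iloc[0] == \
                grp["distance_to_mouth_km"].min()

    def test_monotone_temperature_with_barrier_step(self):
        cfg = ScenarioConfig(n_fjords=10, grid_nx=64, grid_ny=16,
                             barrier_step=3.0, barrier_position=0.5)
        meta = generate_site_network(cfg)
        reps = meta[meta["representative"]].sort_values("grid_ix")
        t = reps["temperature_c"].to_numpy()
        diffs = -np.diff(t)
        assert (diffs > 0).all()            # monotone decreasing downstream
        assert diffs.max() > 3.0            # the barrier step dominates

    def test_no_barrier_gives_smooth_increments(self):
        cfg = ScenarioConfig(n_fjords=10, grid_nx=64, grid_ny=16,
                             barrier_step=0.0)
        meta = generate_site_network(cfg)
        reps = meta[meta["representative"]].sort_values("grid_ix")
        diffs = -np.diff(reps["temperature_c"].to_numpy())
        smooth = (cfg.temp_range[1] - cfg.temp_range[0]) / (cfg.n_fjords - 1)
        assert np.abs(diffs - smooth).max() < 0.5   # site-level noise only

    def test_all_sites_on_ocean_and_subzones_ordered(self):
        cfg = ScenarioConfig(n_fjords=12, grid_nx=80, grid_ny=20)
        field = generate_velocity_field(cfg, n_days=2)
        meta = generate_site_network(cfg, field)
        assert field.mask[meta["grid_iy"], meta["grid_ix"]].all()
        zones = meta[meta["representative"]].sort_values("grid_ix")["subzone"]
        order = {"temperate": 0, "subarctic": 1, "low Arctic": 2,
                 "high Arctic": 3}
        codes = zones.map(order).to_numpy()
        assert (np.diff(codes) >= 0).all()
        assert codes[0] == 0 and codes[-1] == 3

    def test_nutrients_enriched_at_fjord_heads(self):
        cfg = ScenarioConfig(n_fjords=10, grid_nx=64, grid_ny=16)
        meta = generate_site_network(cfg)
        heads = meta[meta.index.str.endswith("head")]["no3_umol_l"].mean()
        mouths = meta[meta.index.str.endswith("mouth")]["no3_umol_l"].mean()
        assert heads > mouths


def flat_hd(meta, value=0.1):
    """Minimal hydrodynamic-distance table covering representative pairs."""
    reps = sorted(meta.index[meta["representative"]])
    rows = []
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            rows.append({"site_a": a, "site_b": b, "bin_lo": 0.0,
                         "bin_hi": 90.0, "concentration": 1e-3,
                         "distance": value, "connected": True})
    return pd.DataFrame(rows)


class TestAsvTables:
    @pytest.fixture
    def small_meta(self):
        cfg = ScenarioConfig(n_fjords=6, grid_nx=48, grid_ny=16,
                             n_asv_pro=60, n_asv_euk=60, seq_depth=3000,
                             seed=5)
        return cfg, generate_site_network(cfg)

    def test_row_sums_equal_seq_depth(self, small_meta):
        cfg, meta = small_meta
        pro, euk, _, _ = generate_asv_tables(meta, flat_hd(meta), cfg)
        assert (pro.counts.sum(axis=1) == cfg.seq_depth).all()
        assert (euk.counts.sum(axis=1) == cfg.seq_depth).all()

    def test_bitwise_determinism(self, small_meta):
        cfg, meta = small_meta
        a = generate_asv_tables(meta, flat_hd(meta), cfg)
        b = generate_asv_tables(meta, flat_hd(meta), cfg)
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1].counts, b[1].counts)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_null_case_no_planted_divergence(self):
        cfg = ScenarioConfig(n_fjords=6, grid_nx=48, grid_ny=16,
                             n_asv_pro=80, n_asv_euk=80, seq_depth=50000,
                             decay_rate_pro=0.0, decay_rate_euk=0.0,
                             temp_sensitivity_pro=0.0,
                             temp_sensitivity_euk=0.0,
                             richness_cold_penalty_pro=0.0, seed=2)
        meta = generate_site_network(cfg)
        _, _, _, truth = generate_asv_tables(meta, flat_hd(meta), cfg)
        reps = truth.site_order
        # expected (latent) distances between representative sites all zero
        for a in reps[1:]:
            assert truth.expected_aitchison("pro", reps[0], a) < 1e-9
            assert truth.expected_aitchison("euk", reps[0], a) < 1e-9

    def test_cold_richness_penalty_recovered(self):
        cfg = ScenarioConfig(n_fjords=8, grid_nx=64, grid_ny=16,
                             n_asv_pro=200, n_asv_euk=40, seq_depth=200000,
                             decay_rate_pro=0.0, decay_rate_euk=0.0,
                             temp_sensitivity_pro=0.0,
                             temp_sensitivity_euk=0.0,
                             richness_cold_penalty_pro=0.5, seed=4)
        meta = generate_site_network(cfg)
        pro, _, _, truth = generate_asv_tables(meta, flat_hd(meta), cfg)
        temps = meta["temperature_c"]
        coldest = temps.idxmin()
        warmest = temps.idxmax()
        # oracle: direct count of nonzero latent occupancies
        expect_cold = cfg.n_asv_pro - len(truth.excluded[coldest])
        rich_cold = (pro.counts.loc[coldest] > 0).sum()
        rich_warm = (pro.counts.loc[warmest] > 0).sum()
        assert rich_cold == pytest.approx(expect_cold, rel=0.05)
        assert rich_cold / rich_warm == pytest.approx(0.5, abs=0.07)

    def test_temp_sensitivity_separates_domains_on_latents(self):
        from scipy.stats import linregress
        cfg = ScenarioConfig(n_fjords=10, grid_nx=64, grid_ny=16,
                             n_asv_pro=150, n_asv_euk=150,
                             decay_rate_pro=0.0, decay_rate_euk=0.0,
                             temp_sensitivity_pro=0.5,
                             temp_sensitivity_euk=0.0,
                             richness_cold_penalty_pro=0.0, seed=6)
        meta = generate_site_network(cfg)
        _, _, _, truth = generate_asv_tables(meta, flat_hd(meta), cfg)
        reps = truth.site_order
        temps = meta["temperature_c"]
        rows = []
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                rows.append((abs(temps[a] - temps[b]),
                             truth.expected_aitchison("pro", a, b),
                             truth.expected_aitchison("euk", a, b)))
        dt, dp, de = map(np.array, zip(*rows))
        # oracle: regression on noise-free latent vectors
        slope_pro = linregress(dt, dp).slope
        slope_euk = linregress(dt, de).slope
        assert slope_pro > 0.5
        assert abs(slope_euk) < 0.2

    def test_missing_connectivity_site_raises(self, small_meta):
        cfg, meta = small_meta
        hd = flat_hd(meta)
        hd = hd[hd["site_a"] != sorted(meta.index[meta["representative"]])[0]]
        with pytest.raises(KeyError):
            generate_asv_tables(meta, hd, cfg)


class TestScenario:
    def test_scenario_end_to_end_determinism(self):
        cfg = ScenarioConfig(n_fjords=5, grid_nx=48, grid_ny=16,
                             n_asv_pro=40, n_asv_euk=40, seq_depth=2000,
                             seed=9)
        sched = SeedingSchedule(lifetime=30, n_cohorts=2,
                                floats_per_cohort=10)
        bins = [(0.0, 30.0)]
        s1 = generate_scenario(cfg, schedule=sched, age_bins=bins)
        s2 = generate_scenario(cfg, schedule=sched, age_bins=bins)
        pd.testing.assert_frame_equal(s1.metadata, s2.metadata)
        pd.testing.assert_frame_equal(s1.hydro_distance, s2.hydro_distance)
        pd.testing.assert_frame_equal(s1.asv_pro.counts, s2.asv_pro.counts)

    def test_no_fitting_age_bin_raises(self):
        cfg = ScenarioConfig(n_fjords=5, grid_nx=48, grid_ny=16)
        sched = SeedingSchedule(lifetime=20, n_cohorts=1)
        with pytest.raises(ConfigError):
            generate_scenario(cfg, schedule=sched, age_bins=[(0, 90)])
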