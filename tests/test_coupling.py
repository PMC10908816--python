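"""Representative-site pairing, coupling statistics and trophic profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from fjordconn import (beta_vs_deltaT, build_pair_table, correlate_hd_beta,
                       eukaryote_share, select_representative_sites,
                       trophic_group_tests, trophic_profiles)


def make_meta(n_fjords=5, sites_per_fjord=3):
    rows = []
    for k in range(n_fjords):
        for j in range(sites_per_fjord):
            rows.append({
                "site_id": f"f{k:02d}_s{j}",
                "fjord": f"f{k:02d}",
                "subzone": ["temperate", "subarctic", "low Arctic",
                            "high Arctic"][min(k * 4 // n_fjords, 3)],
                "distance_to_mouth_km": float(j * 2),
                "temperature_c": 10.0 - k * 2.0 + 0.1 * j,
            })
    return pd.DataFrame(rows).set_index("site_id")


def make_dm(ids, fn):
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(i, j)
    return DistanceMatrix(d, ids=ids)


def make_hd(sites, fn, bins=((0.0, 30.0),)):
    rows = []
    for lo, hi in bins:
        for i, j in itertools.combinations(range(len(sites)), 2):
            v = fn(i, j)
            rows.append({"site_a": min(sites[i], sites[j]),
                         "site_b": max(sites[i], sites[j]),
                         "bin_lo": lo, "bin_hi": hi,
                         "concentration": 10.0 ** (-v) if np.isfinite(v) else 0.0,
                         "distance": v if np.isfinite(v) else np.nan,
                         "connected": bool(np.isfinite(v))})
    return pd.DataFrame(rows)


class TestRepresentativeSites:
    def test_minimum_distance_site_selected(self):
        meta = make_meta()
        meta.loc["f00_s2", "distance_to_mouth_km"] = 0.5
        meta.loc["f00_s0", "distance_to_mouth_km"] = 3.0
        reps = select_representative_sites(meta)
        assert "f00_s2" in reps

    def test_23_candidates_minus_2_exclusions_is_21_sites_210_pairs(self):
        meta = make_meta(n_fjords=23)
        reps = select_representative_sites(
            meta, exclude=("f00_s0", "f01_s0"))
        # the two excluded mouths fall back to the next-closest site unless
        # the whole fjord is excluded; exclude all sites of two fjords
        meta2 = meta[~meta["fjord"].isin(["f00", "f01"])]
        reps = select_representative_sites(meta2)
        assert len(reps) == 21
        assert len(list(itertools.combinations(reps, 2))) == 210

    def test_single_site_fjord(self):
        meta = make_meta(n_fjords=4, sites_per_fjord=1)
        reps = select_representative_sites(meta)
        assert len(reps) == 4

    def test_tie_broken_by_site_id(self, caplog):
        meta = make_meta()
        meta["distance_to_mouth_km"] = 1.0
        with caplog.at_level("INFO"):
            reps = select_representative_sites(meta)
        assert all(r.endswith("_s0") for r in reps)


class TestPairTable:
    def build(self, n_fjords=5):
        meta = make_meta(n_fjords)
        reps = select_representative_sites(meta)
        d16 = make_dm(reps, lambda i, j: abs(i - j) * 1.0)
        d18 = make_dm(reps, lambda i, j: abs(i - j) * 0.5)
        hd = make_hd(reps, lambda i, j: abs(i - j) / 4.0)
        return meta, reps, d16, d18, hd

    def test_pair_count_is_k_choose_2(self):
        meta, reps, d16, d18, hd = self.build(7)
        pairs = build_pair_table(reps, d16, d18, hd, meta)
        assert len(pairs) == 21

    def test_delta_t_and_relation_labels(self):
        meta, reps, d16, d18, hd = self.build()
        pairs = build_pair_table(reps, d16, d18, hd, meta)
        same = pairs[pairs["site_a"].str[:3] == pairs["site_b"].str[:3]]
        row = pairs.iloc[0]
        assert row["delta_t"] == pytest.approx(
            abs(meta.loc[row["site_a"], "temperature_c"]
                - meta.loc[row["site_b"], "temperature_c"]))
        zones = meta["subzone"]
        for _, r in pairs.iterrows():
            expect = ("within" if zones[r["site_a"]] == zones[r["site_b"]]
                      else "crossing")
            assert r["relation"] == expect

    def test_unconnected_pairs_kept_as_rows(self):
        meta, reps, d16, d18, _ = self.build()
        hd = make_hd(reps, lambda i, j: np.inf if abs(i - j) > 2 else 0.1)
        pairs = build_pair_table(reps, d16, d18, hd, meta)
        assert len(pairs) == 10          # all pairs retained
        assert pairs["hd_0_30"].isna().sum() > 0

    def test_missing_site_in_distance_matrix_raises(self):
        meta, reps, d16, d18, hd = self.build()
        d16_small = make_dm(reps[:-1], lambda i, j: 1.0)
        with pytest.raises(KeyError):
            build_pair_table(reps, d16_small, d18, hd, meta)


class TestCorrelation:
    def test_perfectly_linear_gives_r_one(self):
        meta = make_meta(6)
        reps = select_representative_sites(meta)
        hd = make_hd(reps, lambda i, j: abs(i - j) / 5.0)
        d16 = make_dm(reps, lambda i, j: 2.0 + 3.0 * abs(i - j) / 5.0)
        d18 = make_dm(reps, lambda i, j: 1.0)
        pairs = build_pair_table(reps, d16, d18, hd, meta)
        recs = correlate_hd_beta(pairs, "16S")
        assert recs[0].r == pytest.approx(1.0)
        assert recs[0].n_pairs == 15

    def test_constant_hd_flagged_undefined(self, caplog):
        meta = make_meta(5)
        reps = select_representative_sites(meta)
        hd = make_hd(reps, lambda i, j: 0.4)
        d16 = make_dm(reps, lambda i, j: abs(i - j) * 1.0)
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        with caplog.at_level("WARNING"):
            recs = correlate_hd_beta(pairs, "16S")
        assert np.isnan(recs[0].r)

    def test_too_few_connected_pairs_skipped(self, caplog):
        meta = make_meta(5)
        reps = select_representative_sites(meta)
        hd = make_hd(reps, lambda i, j: 0.2 if i == 0 and j == 1 else np.inf)
        d16 = make_dm(reps, lambda i, j: abs(i - j) * 1.0)
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        with caplog.at_level("WARNING"):
            recs = correlate_hd_beta(pairs, "16S")
        assert recs == []

    def test_site_relabeling_invariance(self):
        meta = make_meta(6)
        reps = select_representative_sites(meta)
        rng = np.random.default_rng(0)
        vals = {frozenset((i, j)): rng.uniform(1, 4)
                for i, j in itertools.combinations(range(len(reps)), 2)}
        hd = make_hd(reps, lambda i, j: abs(i - j) / 5.0)
        d16 = make_dm(reps, lambda i, j: vals[frozenset((i, j))])
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        r1 = correlate_hd_beta(pairs, "16S")[0].r
        # relabel: permute which id carries which row (distances follow ids)
        perm = list(rng.permutation(len(reps)))
        relabeled = [reps[perm[i]] for i in range(len(reps))]
        d16b = make_dm(relabeled, lambda i, j: vals[frozenset((i, j))])
        hdb = make_hd(relabeled, lambda i, j: abs(i - j) / 5.0)
        pairs_b = build_pair_table(reps, d16b, d16b, hdb, meta)
        r2 = correlate_hd_beta(pairs_b, "16S")[0].r
        assert r1 == pytest.approx(r2)


class TestRegression:
    def test_exact_linear_recovery(self):
        meta = make_meta(6)
        reps = select_representative_sites(meta)
        temps = meta["temperature_c"]
        d16 = make_dm(reps, lambda i, j: 2.0 + 0.3 * abs(temps[reps[i]]
                                                         - temps[reps[j]]))
        hd = make_hd(reps, lambda i, j: 0.1)
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        rec = beta_vs_deltaT(pairs, "16S", "all")
        assert rec.slope == pytest.approx(0.3, abs=1e-9)
        assert rec.intercept == pytest.approx(2.0, abs=1e-9)
        assert rec.r == pytest.approx(1.0)

    def test_zero_variance_delta_t_flagged(self, caplog):
        meta = make_meta(5)
        meta["temperature_c"] = 5.0
        reps = select_representative_sites(meta)
        d16 = make_dm(reps, lambda i, j: 1.0 + abs(i - j))
        hd = make_hd(reps, lambda i, j: 0.1)
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        with caplog.at_level("WARNING"):
            rec = beta_vs_deltaT(pairs, "16S", "all")
        assert np.isnan(rec.slope)

    def test_scopes_partition_pairs(self):
        meta = make_meta(8)
        reps = select_representative_sites(meta)
        d16 = make_dm(reps, lambda i, j: 1.0 + abs(i - j))
        hd = make_hd(reps, lambda i, j: 0.1)
        pairs = build_pair_table(reps, d16, d16, hd, meta)
        n_within = beta_vs_deltaT(pairs, "16S", "within").n
        n_cross = beta_vs_deltaT(pairs, "16S", "crossing").n
        assert n_within + n_cross == len(pairs)


def make_clr(samples, asvs, values):
    df = pd.DataFrame(values, index=samples, columns=asvs)
    return df.sub(df.mean(axis=1), axis=0)


class TestTrophicProfiles:
    def make_annot(self, asvs16, asvs18, groups16, groups18):
        recs = []
        for a, g in zip(asvs16, groups16):
            recs.append({"asv_id": a, "domain": "prokaryote",
                         "trophic_group": g})
        for a, g in zip(asvs18, groups18):
            recs.append({"asv_id": a, "domain": "eukaryote",
                         "trophic_group": g})
        return pd.DataFrame(recs).set_index("asv_id")

    def test_fractions_sum_to_one(self, rng):
        c16 = make_clr(["s1", "s2"], ["p1", "p2", "p3"],
                       rng.normal(size=(2, 3)))
        c18 = make_clr(["s1", "s2"], ["e1", "e2"], rng.normal(size=(2, 2)))
        annot = self.make_annot(["p1", "p2", "p3"], ["e1", "e2"],
                                ["autotroph", "heterotroph", "unknown"],
                                ["mixotroph", "autotroph"])
        prof = trophic_profiles(c16, c18, annot)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        assert (prof.to_numpy() >= 0).all()

    def test_single_class_sample(self, rng):
        # all eukaryotic ASVs autotroph; prokaryote matrix contributes its
        # cells too, so restrict to a eukaryote-only profile check
        c18 = make_clr(["s1"], ["e1", "e2", "e3"], [[1.0, 2.0, 4.0]])
        c16 = pd.DataFrame(index=["s1"], columns=[], dtype=float)
        annot = self.make_annot([], ["e1", "e2", "e3"], [],
                                ["autotroph"] * 3)
        prof = trophic_profiles(c16, c18, annot)
        assert prof.loc["s1", "autotroph_eukaryote"] == pytest.approx(1.0)

    def test_invariant_to_asv_order(self, rng):
        asvs = ["p1", "p2", "p3", "p4"]
        vals = rng.normal(size=(3, 4))
        c18 = make_clr(["s1", "s2", "s3"], ["e1"], rng.normal(size=(3, 1)))
        annot = self.make_annot(asvs, ["e1"],
                                ["autotroph", "mixotroph", "heterotroph",
                                 "unknown"], ["autotroph"])
        p1 = trophic_profiles(make_clr(["s1", "s2", "s3"], asvs, vals),
                              c18, annot)
        perm = [2, 0, 3, 1]
        p2 = trophic_profiles(
            make_clr(["s1", "s2", "s3"], [asvs[i] for i in perm],
                     vals[:, perm]), c18, annot)
        pd.testing.assert_frame_equal(p1, p2)

    def test_sample_mismatch_raises(self, rng):
        c16 = make_clr(["s1", "s2"], ["p1", "p2"], rng.normal(size=(2, 2)))
        c18 = make_clr(["s1"], ["e1", "e2"], rng.normal(size=(1, 2)))
        annot = self.make_annot(["p1", "p2"], ["e1", "e2"],
                                ["autotroph"] * 2, ["autotroph"] * 2)
        with pytest.raises(KeyError):
            trophic_profiles(c16, c18, annot)

    def test_unannotated_asv_raises(self, rng):
        c16 = make_clr(["s1"], ["p1", "p2"], rng.normal(size=(1, 2)))
        c18 = make_clr(["s1"], ["e1"], rng.normal(size=(1, 1)))
        annot = self.make_annot(["p1"], ["e1"], ["autotroph"], ["autotroph"])
        with pytest.raises(KeyError):
            trophic_profiles(c16, c18, annot)


class TestTrophicGroupTests:
    def make_profiles(self, rng, n_per_zone=8, shift=0.0):
        zones, rows, idx = [], [], []
        for z in ("temperate", "subarctic", "high Arctic"):
            for i in range(n_per_zone):
                base = rng.dirichlet(np.ones(8))
                if z == "high Arctic" and shift:
                    base[0] += shift       # autotroph_eukaryote bump
                    base /= base.sum()
                rows.append(base)
                zones.append(z)
                idx.append(f"{z}_{i}")
        cols = [f"{g}_{d}" for g in ("autotroph", "mixotroph",
                                     "heterotroph", "unknown")
                for d in ("eukaryote", "prokaryote")]
        prof = pd.DataFrame(rows, index=idx, columns=cols)
        return prof, pd.Series(zones, index=idx)

    def test_identical_profiles_give_p_one(self):
        cols = [f"{g}_{d}" for g in ("autotroph", "mixotroph",
                                     "heterotroph", "unknown")
                for d in ("eukaryote", "prokaryote")]
        prof = pd.DataFrame([[0.125] * 8] * 12, columns=cols,
                            index=[f"s{i}" for i in range(12)])
        zones = pd.Series(["temperate"] * 6 + ["subarctic"] * 6,
                          index=prof.index)
        tests = trophic_group_tests(prof, zones, merge_arctic=False)
        for res in tests.values():
            for r in res:
                if r.method.startswith("welch"):
                    assert np.isnan(r.statistic) or r.p_raw == pytest.approx(1.0)

    def test_arctic_merge_reduces_groups(self, rng):
        prof, zones = self.make_profiles(rng)
        zones.iloc[-3:] = "low Arctic"
        merged = trophic_group_tests(prof, zones, merge_arctic=True)
        unmerged = trophic_group_tests(prof, zones, merge_arctic=False)
        cell = "autotroph_eukaryote"
        n_pairwise = lambda res: sum(r.method.startswith("welch")
                                     for r in res)
        assert n_pairwise(merged[cell]) == 3     # 3 zones -> 3 pairs
        assert n_pairwise(unmerged[cell]) == 6   # 4 zones -> 6 pairs

    def test_planted_effect_detected_in_right_cell(self, rng):
        prof, zones = self.make_profiles(rng, shift=0.4)
        tests = trophic_group_tests(prof, zones, merge_arctic=True)
        target = [r for r in tests["autotroph_eukaryote"]
                  if "Arctic" in r.comparison and "temperate" in r.comparison]
        assert target and all(r.p_adjusted < 0.05 for r in target)


class TestEukaryoteShare:
    def test_share_definition(self):
        prof = pd.DataFrame({"autotroph_eukaryote": [0.3],
                             "autotroph_prokaryote": [0.1],
                             "mixotroph_eukaryote": [0.0],
                             "mixotroph_prokaryote": [0.0],
                             "heterotroph_eukaryote": [0.2],
                             "heterotroph_prokaryote": [0.2],
                             "unknown_eukaryote": [0.1],
                             "unknown_prokaryote": [0.1]}, index=["s"])
        share = eukaryote_share(prof)
        assert share.loc["s", "autotroph"] == pytest.approx(0.75)
        assert np.isnan(share.loc["s", "mixotroph"])
        assert share.loc["s", "heterotroph"] == pytest.approx(0.5)
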