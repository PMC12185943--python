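"""Occurrence cleaning, thinning, ecoregion assignment and background
allocation contracts."""

import numpy as np
import pandas as pd
import pytest

from ecosdm import prep, synthetic
from ecosdm.landscape import EcoregionMap


def occ_frame(points, species="sp"):
    return pd.DataFrame([{"species": species, "x": x, "y": y} for x, y in points])


class TestCleanCoordinates:
    def test_missing_coordinate_dropped_as_incomplete(self, masked_landscape):
        occ = pd.DataFrame({"species": ["sp"], "x": [1.5], "y": [np.nan]})
        kept, dropped = prep.clean_coordinates(occ, masked_landscape)
        assert kept.empty
        assert dropped["drop_reason"].tolist() == ["incomplete"]

    def test_masked_cell_dropped_as_off_mask(self, masked_landscape):
        # (row 0, col 0) is masked: its center is (0.5, 7.5)
        kept, dropped = prep.clean_coordinates(occ_frame([(0.5, 7.5)]), masked_landscape)
        assert kept.empty
        assert dropped["drop_reason"].tolist() == ["off_mask"]

    def test_off_extent_dropped(self, masked_landscape):
        _, dropped = prep.clean_coordinates(occ_frame([(99.0, 1.0)]), masked_landscape)
        assert dropped["drop_reason"].tolist() == ["off_extent"]

    def test_duplicates_dropped(self, masked_landscape):
        pts = [(2.5, 2.5), (3.5, 3.5), (4.5, 4.5), (5.5, 5.5), (6.5, 6.5),
               (2.5, 2.5), (3.5, 3.5)]
        kept, dropped = prep.clean_coordinates(occ_frame(pts), masked_landscape)
        assert len(kept) == 5
        assert (dropped["drop_reason"] == "duplicate").sum() == 2

    def test_empty_input_is_not_an_error(self, masked_landscape):
        kept, dropped = prep.clean_coordinates(
            pd.DataFrame(columns=["species", "x", "y"]), masked_landscape)
        assert kept.empty and dropped.empty


class TestGeographicFilter:
    def test_one_record_per_cell(self, masked_landscape):
        # two points in the same cell (cell centers are at *.5)
        occ = occ_frame([(2.3, 2.3), (2.7, 2.6), (5.5, 5.5)])
        out = prep.geographic_filter(occ, masked_landscape)
        assert len(out) == 2

    def test_k_distinct_cells_keep_k(self, masked_landscape):
        occ = occ_frame([(float(i) + 0.5, 3.5) for i in range(5)])
        assert len(prep.geographic_filter(occ, masked_landscape)) == 5

    def test_idempotent(self, masked_landscape):
        occ = occ_frame([(2.3, 2.3), (2.7, 2.6), (5.5, 5.5), (5.6, 5.6)])
        once = prep.geographic_filter(occ, masked_landscape)
        twice = prep.geographic_filter(once, masked_landscape)
        pd.testing.assert_frame_equal(once, twice)

    def test_commutes_with_cleaning(self, landscape32):
        rng = np.random.default_rng(3)
        pts = [(rng.uniform(0, 32), rng.uniform(0, 32)) for _ in range(60)]
        pts += [pts[0], (np.nan, 1.0), (-5.0, 1.0)]
        occ = occ_frame(pts)
        a = prep.geographic_filter(prep.clean_coordinates(occ, landscape32)[0], landscape32)
        b = prep.clean_coordinates(prep.geographic_filter(occ, landscape32), landscape32)[0]
        pd.testing.assert_frame_equal(
            a.sort_values(["x", "y"]).reset_index(drop=True),
            b.sort_values(["x", "y"]).reset_index(drop=True))


def two_region_map(landscape):
    """West half region 0 ('A'), east half region 1 ('B')."""
    codes = np.zeros(landscape.shape, dtype=int)
    codes[:, landscape.n_cols // 2:] = 1
    return EcoregionMap(codes=codes, labels={0: "A", 1: "B"},
                        nodata_mask=landscape.nodata_mask)


class TestAssignment:
    def test_seventy_percent_case(self, landscape32):
        eco = two_region_map(landscape32)
        pts = [(float(i) + 0.5, 10.5) for i in range(7)]          # region A
        pts += [(float(20 + i) + 0.5, 10.5) for i in range(3)]    # region B
        a = prep.assign_to_ecoregions(occ_frame(pts), landscape32, eco)
        row = a.iloc[0]
        assert row["freq_A"] == pytest.approx(0.7)
        assert row["assigned_0.6"] == "A" and row["assigned_0.7"] == "A"
        assert pd.isna(row["assigned_0.8"]) and pd.isna(row["assigned_1.0"])

    def test_pure_species_assigned_at_full_threshold(self, landscape32):
        eco = two_region_map(landscape32)
        pts = [(float(i) + 0.5, 3.5) for i in range(10)]
        a = prep.assign_to_ecoregions(occ_frame(pts), landscape32, eco)
        assert a.iloc[0]["assigned_1.0"] == "A"

    def test_even_split_unassigned(self, landscape32):
        eco = two_region_map(landscape32)
        pts = [(5.5, 3.5), (8.5, 3.5), (20.5, 3.5), (25.5, 3.5)]
        a = prep.assign_to_ecoregions(occ_frame(pts), landscape32, eco)
        assert pd.isna(a.iloc[0]["assigned_0.6"])

    def test_assignment_nested_across_thresholds(self, landscape32, ecoregions32):
        rng = np.random.default_rng(0)
        pts = [(rng.uniform(0, 32), rng.uniform(0, 32)) for _ in range(40)]
        a = prep.assign_to_ecoregions(occ_frame(pts), landscape32, ecoregions32)
        row = a.iloc[0]
        taus = [0.6, 0.7, 0.8, 0.9, 1.0]
        assigned = [not pd.isna(row[f"assigned_{t}"]) for t in taus]
        # assignment at a high threshold implies assignment at all lower ones
        for lo, hi in zip(assigned, assigned[1:]):
            assert lo or not hi

    def test_richness_never_increases_with_threshold(self, landscape32, ecoregions32):
        rng = np.random.default_rng(1)
        frames = []
        for s in range(12):
            n = rng.integers(10, 40)
            frames.append(occ_frame(
                [(rng.uniform(0, 32), rng.uniform(0, 32)) for _ in range(n)],
                species=f"sp{s}"))
        occ = pd.concat(frames, ignore_index=True)
        a = prep.assign_to_ecoregions(occ, landscape32, ecoregions32)
        rich = prep.richness_table(a, ecoregions32)
        for label in ecoregions32.labels.values():
            counts = rich[label].to_numpy()
            assert (np.diff(counts) <= 0).all()


class TestEnvironmentalFilter:
    def test_identical_environments_keep_one(self, masked_landscape):
        occ = occ_frame([(2.3, 2.3), (2.4, 2.4), (2.6, 2.6)])  # same cell
        out = prep.environmental_filter(occ, masked_landscape, ["bio1", "SOC"], seed=0)
        assert len(out) == 1

    def test_bin_combination_count(self, masked_landscape):
        # 3 cells with distinct bio1 values at the extremes of the range ->
        # occupy distinct bins; count = number of occupied combinations
        occ = occ_frame([(2.5, 2.5), (3.5, 3.5), (4.5, 4.5), (2.5, 2.5)])
        occ = occ.drop_duplicates().reset_index(drop=True)
        vals = masked_landscape.values_at(occ.x.to_numpy(), occ.y.to_numpy(),
                                          ["bio1", "SOC"])
        expected = len({tuple(np.round(v, 9)) for v in vals})  # all distinct here
        out = prep.environmental_filter(occ, masked_landscape, ["bio1", "SOC"],
                                        n_bins=50, seed=1)
        # with 50 fine bins every distinct environment is its own combination
        assert len(out) == expected

    def test_single_bin_keeps_one_per_species(self, masked_landscape):
        occ = occ_frame([(2.5, 2.5), (3.5, 3.5), (4.5, 4.5)])
        out = prep.environmental_filter(occ, masked_landscape, ["bio1", "SOC"],
                                        n_bins=1, seed=0)
        assert len(out) == 1

    def test_deterministic_for_seed(self, landscape32):
        rng = np.random.default_rng(2)
        occ = occ_frame([(rng.uniform(0, 32), rng.uniform(0, 32)) for _ in range(50)])
        a = prep.environmental_filter(occ, landscape32, ["bio1", "bio12"], seed=9)
        b = prep.environmental_filter(occ, landscape32, ["bio1", "bio12"], seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestKdeBackground:
    def test_cap_at_unmasked_cells_with_warning(self):
        ls = synthetic.generate_env_layers(2, 1, (64, 64), seed=0)  # 4096 cells
        rng = np.random.default_rng(0)
        occ = occ_frame([(rng.uniform(0, 64), rng.uniform(0, 64)) for _ in range(30)])
        with pytest.warns(UserWarning, match="capped"):
            bg = prep.kde_background(occ, ls, n_points=10_000, seed=0)
        assert len(bg) == 4096

    def test_tight_cluster_concentrates_density_mass(self):
        # direct evaluation of the density raster: a tight presence cluster
        # keeps >= 80% of the background-weighting mass near the cluster
        ls = synthetic.generate_env_layers(2, 1, (64, 64), seed=1)
        rng = np.random.default_rng(1)
        occ = occ_frame([(30 + rng.normal(0, 1.0), 30 + rng.normal(0, 1.0))
                         for _ in range(40)])
        full = prep.kde_density(occ, ls)
        from ecosdm.prep import _nrd_bandwidth
        h = max(_nrd_bandwidth(occ.x.to_numpy()), _nrd_bandwidth(occ.y.to_numpy()))
        r = np.hypot(full.x - occ.x.mean(), full.y - occ.y.mean())
        radius = 3.0 * (max(occ.x.std(), occ.y.std()) + h)
        assert full.density[r < radius].sum() / full.density.sum() >= 0.8

    def test_uniform_presences_give_uniform_background(self):
        # quadrant counts pooled over seeds not rejected against uniformity
        # (presences at every cell center: a fully uniform, symmetric spread)
        from scipy.stats import chisquare
        ls = synthetic.generate_env_layers(2, 1, (32, 32), seed=2)
        grid = [(x + 0.5, y + 0.5) for x in range(32) for y in range(32)]
        occ = occ_frame(grid)
        counts = np.zeros(4)
        for seed in range(5):
            bg = prep.kde_background(occ, ls, n_points=200, seed=seed)
            qx = (bg.x >= 16).astype(int)
            qy = (bg.y >= 16).astype(int)
            for q in qx * 2 + qy:
                counts[q] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_density_fidelity_improves_with_draws(self):
        # pooled empirical cell frequencies approach the normalized density
        ls = synthetic.generate_env_layers(1, 1, (16, 16), seed=3)
        rng = np.random.default_rng(3)
        occ = occ_frame([(rng.uniform(2, 14), rng.uniform(2, 14)) for _ in range(25)])
        ref = prep.kde_background(occ, ls, n_points=256, seed=0)  # all cells
        dens = ref.sort_values(["x", "y"])["density"].to_numpy()
        dens = dens / dens.sum()

        def l1(n_draws):
            freq = {}
            for s in range(n_draws):
                bg = prep.kde_background(occ, ls, n_points=40, seed=100 + s)
                for x, y in zip(bg.x, bg.y):
                    freq[(x, y)] = freq.get((x, y), 0) + 1
            emp = np.array([freq.get((x, y), 0)
                            for x, y in zip(ref.sort_values(["x", "y"]).x,
                                            ref.sort_values(["x", "y"]).y)],
                           dtype=float)
            return np.abs(emp / emp.sum() - dens).sum()

        assert l1(60) < l1(6)

    def test_degenerate_spread_requires_explicit_bandwidth(self, masked_landscape):
        occ = occ_frame([(2.5, 2.5)] * 5)
        with pytest.raises(ValueError, match="bandwidth"):
            prep.kde_background(occ, masked_landscape, n_points=10, seed=0)

    def test_too_few_presences_rejected(self, masked_landscape):
        with pytest.raises(ValueError, match="at least 3"):
            prep.kde_background(occ_frame([(2.5, 2.5)]), masked_landscape, 10, seed=0)
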