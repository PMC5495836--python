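"""Seed extraction, connectivity, Fisher Z, maps, and extent thresholding."""
import numpy as np
import pytest
from scipy import stats

from oiconnect.datatypes import CortexMask, GroundTruth, GroupMapStats, SeedTimecourses
from oiconnect.seed_fc import (
    extract_seed_timecourses,
    fisher_z,
    group_tmap,
    homotopic_connectivity,
    seed_to_pixel_maps,
    seed_to_seed,
    threshold_map,
)
from oiconnect.synthetic import make_seed_atlas, simulate_chromophores


class TestTimecourses:
    def test_constant_frame_value(self, small_atlas):
        arr = np.full((5,) + small_atlas.mask.shape, 2.5)
        arr *= np.arange(1, 6)[:, None, None]
        tc = extract_seed_timecourses(arr, small_atlas)
        assert np.allclose(tc.data, 2.5 * np.arange(1, 6)[:, None])

    def test_seed_size_is_17(self, small_atlas, rng):
        arr = rng.normal(size=(10,) + small_atlas.mask.shape)
        tc = extract_seed_timecourses(arr, small_atlas)
        name = small_atlas.seed_names[0]
        px = small_atlas.seeds[name]
        assert len(px) == 17
        assert np.allclose(tc.data[:, 0], arr[:, px[:, 0], px[:, 1]].mean(axis=1))

    def test_single_pixel_seed(self, small_mask, rng):
        atlas = make_seed_atlas(small_mask, {"solo_L": (30, 25)}, n_pixels=1)
        arr = rng.normal(size=(8,) + small_mask.shape)
        tc = extract_seed_timecourses(arr, atlas)
        r, c = atlas.seeds["solo_L"][0]
        assert np.allclose(tc.data[:, 0], arr[:, r, c])


class TestSeedToSeed:
    def test_hand_computed_pearson(self):
        tc = SeedTimecourses(
            data=np.array([[1, 1], [2, 3], [3, 2], [4, 4]], float),
            seed_names=["a", "b"],
            fs=5.0,
        )
        m = seed_to_seed(tc)
        assert m.r[0, 1] == pytest.approx(0.8, abs=1e-12)
        assert np.allclose(np.diag(m.r), 1.0)

    def test_anticorrelation(self):
        x = np.arange(10.0)
        tc = SeedTimecourses(np.column_stack([x, -x]), ["a", "b"], 5.0)
        m = seed_to_seed(tc)
        assert m.r[0, 1] == pytest.approx(-1.0)
        assert np.isfinite(m.z).all()  # clipping keeps |r| = 1 finite

    def test_zero_variance_names_seed(self):
        tc = SeedTimecourses(
            np.column_stack([np.arange(5.0), np.ones(5)]), ["ok", "flat"], 5.0
        )
        with pytest.raises(ValueError, match="flat"):
            seed_to_seed(tc)

    def test_symmetry_unit_diagonal_random(self, rng):
        tc = SeedTimecourses(rng.normal(size=(50, 6)), list("abcdef"), 5.0)
        m = seed_to_seed(tc)
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)
        assert np.abs(m.r).max() <= 1.0


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_odd_symmetry(self):
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3), abs=1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)


class TestHomotopic:
    def test_identity_matrix_gives_zero(self, small_atlas):
        tc = SeedTimecourses(
            np.random.default_rng(0).normal(size=(500, 8)),
            small_atlas.seed_names,
            5.0,
        )
        m = seed_to_seed(tc)
        m.r[:] = np.eye(8)
        m.z[:] = 0.0
        vals = homotopic_connectivity(m, small_atlas)
        assert len(vals) == 4
        assert all(v == 0.0 for v in vals.values())

    def test_missing_partner_raises(self, small_mask):
        atlas = make_seed_atlas(small_mask, {"M_L": (25, 20), "M_R": (25, 43)})
        tc = SeedTimecourses(
            np.random.default_rng(0).normal(size=(50, 1)), ["M_L"], 5.0
        )
        m = seed_to_seed(tc)
        with pytest.raises(ValueError, match="partner"):
            homotopic_connectivity(m, atlas)


class TestSeedToPixelMaps:
    def test_normalization_moments(self, small_atlas, control_truth):
        movie = simulate_chromophores(
            small_atlas, control_truth, 300, 5.0, packed=True
        )
        tc = extract_seed_timecourses(movie, small_atlas, "HbO2")
        maps = seed_to_pixel_maps(movie, tc, small_atlas.mask, contrast="HbO2")
        for fm in maps.values():
            vals = fm.values[np.isfinite(fm.values)]
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std() - 1.0) < 1e-10

    def test_seed_pixels_near_top_prenormalization(self, small_atlas, control_truth):
        movie = simulate_chromophores(
            small_atlas, control_truth, 600, 5.0, packed=True
        )
        tc = extract_seed_timecourses(movie, small_atlas, "HbO2")
        maps = seed_to_pixel_maps(
            movie, tc, small_atlas.mask, contrast="HbO2", normalize=False
        )
        name = small_atlas.seed_names[0]
        fm = maps[name]
        px = small_atlas.seeds[name]
        seed_mean = fm.values[px[:, 0], px[:, 1]].mean()
        overall = np.nanmean(fm.values)
        assert seed_mean > overall + 0.5  # self-correlated region dominates

    def test_within_network_ranks_above_cross_network(self, small_atlas):
        """Pixels of a strongly coupled network pair outrank pixels of an
        uncoupled network in the seed map of either pair member."""
        c = np.eye(8)
        names = small_atlas.seed_names
        i, j = names.index("M_L"), names.index("M_R")
        c[i, j] = c[j, i] = 0.8
        truth = GroundTruth(
            coupling=c, seed_names=names, group="control", rng_seed=4
        )
        movie = simulate_chromophores(
            small_atlas, truth, 1500, 5.0, packed=True, coupling_jitter=0.0,
            center_jitter_px=0.0,
        )
        tc = extract_seed_timecourses(movie, small_atlas, "HbO2")
        maps = seed_to_pixel_maps(movie, tc, small_atlas.mask, contrast="HbO2")
        fm = maps["M_L"].values
        partner = small_atlas.seeds["M_R"]
        stranger = small_atlas.seeds["R_R"]
        assert (
            fm[partner[:, 0], partner[:, 1]].mean()
            > fm[stranger[:, 0], stranger[:, 1]].mean()
        )


def _stats_from_p(p_map, mask):
    return GroupMapStats(
        t_map=np.where(np.isfinite(p_map), 1.0, np.nan),
        p_map=p_map,
        mask=mask,
        n_subjects=5,
    )


class TestGroupTmap:
    def test_all_zero_maps(self, small_mask):
        from oiconnect.datatypes import FcMap

        maps = [
            FcMap(values=np.where(small_mask.mask, 0.0, np.nan), seed_name="s",
                  contrast="HbO2")
            for _ in range(4)
        ]
        # zero variance across subjects -> invalid, not infinite
        g = group_tmap(maps, small_mask)
        assert np.isnan(g.t_map[small_mask.mask]).all()

    def test_hand_computed_t(self, small_mask):
        from oiconnect.datatypes import FcMap

        vals = [0.9, 1.1, 1.0, 1.2]
        maps = []
        for v in vals:
            img = np.where(small_mask.mask, v, np.nan)
            img[32, 32] = v  # ensure deterministic pixel
            maps.append(FcMap(values=img, seed_name="s", contrast="HbO2"))
        # add pixel-level spread so only the probe pixel is exact
        g = group_tmap(maps, small_mask)
        x = np.array(vals)
        t_oracle = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert g.t_map[32, 32] == pytest.approx(t_oracle, abs=1e-10)
        assert t_oracle == pytest.approx(16.2665, abs=1e-3)
        t_sp, p_sp = stats.ttest_1samp(x, 0.0)
        assert g.t_map[32, 32] == pytest.approx(t_sp, abs=1e-10)
        assert g.p_map[32, 32] == pytest.approx(p_sp, abs=1e-12)


class TestThresholdMap:
    def test_no_survivors_zero_extent(self, small_mask):
        p = np.where(small_mask.mask, 0.9, np.nan)
        out = threshold_map(_stats_from_p(p, small_mask.mask))
        assert out.spatial_extent == 0.0

    def test_small_cluster_removed(self):
        mask = np.ones((40, 40), bool)
        p = np.ones((40, 40))
        p[5:11, 5:21] = 0.0  # 96-pixel cluster
        p[30:32, 30:32] = 0.0  # 4-pixel cluster (< 5% of 100)
        out = threshold_map(_stats_from_p(p, mask))
        assert out.supra_mask.sum() == 96
        assert sorted(out.cluster_sizes.tolist()) == [4, 96]

    def test_extent_definition(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True  # 100 cortex pixels
        p = np.full((20, 20), np.nan)
        p[mask] = 1.0
        p[0:5, 0:9] = 0.0  # 45 surviving pixels in one cluster
        out = threshold_map(_stats_from_p(p, mask))
        assert out.spatial_extent == pytest.approx(0.45)

    def test_monotone_in_extent_frac(self, rng):
        mask = np.ones((30, 30), bool)
        p = rng.uniform(size=(30, 30)) ** 4
        counts = []
        for frac in (0.0, 0.02, 0.05, 0.1, 0.3):
            out = threshold_map(_stats_from_p(p.copy(), mask), extent_frac=frac)
            counts.append(out.supra_mask.sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bh_family_is_in_mask_only(self):
        mask = np.zeros((10, 10), bool)
        mask[0, :4] = True
        p = np.full((10, 10), 1e-9)  # tiny p outside mask must not matter
        p[mask] = np.array([0.04, 0.5, 0.6, 0.7])
        out = threshold_map(_stats_from_p(p, mask), q=0.05, extent_frac=0.0)
        # only 0.04 <= 1 * 0.05 / 4 fails; step-up rejects nothing
        assert out.supra_mask.sum() == 0

    def test_four_vs_eight_connectivity(self):
        mask = np.ones((10, 10), bool)
        p = np.ones((10, 10))
        p[0, 0] = p[1, 1] = 0.0  # diagonal touch
        out8 = threshold_map(_stats_from_p(p, mask), connectivity=8, extent_frac=0.0)
        out4 = threshold_map(_stats_from_p(p.copy(), mask), connectivity=4,
                             extent_frac=0.0)
        assert len(out8.cluster_sizes) == 1
        assert len(out4.cluster_sizes) == 2
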