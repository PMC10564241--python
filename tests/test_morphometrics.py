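"""Islet morphometry: hulls, signed distances, irregularity index, paired test."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import dualeigen as de


def _disk_masks(radius=100, infiltration=0.0, n_glu=400, seed=0):
    return de.simulate_islet_masks(
        radius_px=radius, infiltration=infiltration, n_glucagon=n_glu, seed=seed
    )


class TestChannelMasks:
    def test_mask_mode_pass_through(self):
        ins, glu = _disk_masks()
        out_i, out_g = de.channel_masks((ins, glu))
        assert (out_i == ins).all() and (out_g == glu).all()

    def test_rgb_channel_dominance(self):
        img = np.zeros((10, 10, 3), np.uint8)
        img[2:5, 2:5, 1] = 200        # green -> insulin
        img[6:8, 6:8, 0] = 200        # red -> glucagon
        img[0, 0] = (120, 120, 0)     # R == G tie -> neither
        ins, glu = de.channel_masks(img, mode="rgb")
        assert ins[3, 3] and not glu[3, 3]
        assert glu[6, 6] and not ins[6, 6]
        assert not ins[0, 0] and not glu[0, 0]

    def test_empty_insulin_mask_is_error(self):
        with pytest.raises(ValueError, match="insulin"):
            de.channel_masks((np.zeros((5, 5), bool), np.ones((5, 5), bool)))

    def test_empty_glucagon_only_fails_distance_ops(self):
        ins = np.zeros((20, 20), bool)
        ins[5:15, 5:15] = True
        _, glu = de.channel_masks((ins, np.zeros((20, 20), bool)))
        hull = de.islet_hull(ins)
        with pytest.raises(ValueError, match="glucagon"):
            de.glucagon_distances(glu, hull)


class TestHull:
    def test_filled_square_hull_is_its_corners(self):
        mask = np.zeros((20, 20), bool)
        mask[4:10, 6:14] = True
        hull = de.islet_hull(mask)
        assert hull.equals(Polygon([(6, 4), (13, 4), (13, 9), (6, 9)]))

    def test_disk_hull_area_within_2pct(self):
        ins, _ = _disk_masks(radius=60)
        hull = de.islet_hull(ins)
        assert hull.area == pytest.approx(np.pi * 60**2, rel=0.02)

    def test_hull_ignores_interior_pixels(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        hull_full = de.islet_hull(mask)
        boundary_only = mask.copy()
        boundary_only[6:24, 6:24] = False
        assert de.islet_hull(boundary_only).equals(hull_full)

    def test_collinear_pixels_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 2:8] = True
        with pytest.raises(ValueError, match="degenerate|collinear"):
            de.islet_hull(mask)


class TestDistances:
    def test_center_pixel_distance_is_radius(self):
        ins, _ = _disk_masks(radius=50)
        hull = de.islet_hull(ins)
        glu = np.zeros_like(ins)
        c = ins.shape[0] // 2
        glu[c - 2 : c + 3, c - 2 : c + 3] = True  # 25 px block at the centroid
        d, _ = de.glucagon_distances(glu, hull)
        assert d.mean() == pytest.approx(50.0, rel=0.05)
        assert (d > 0).all()

    def test_outside_pixels_negative_signed_distance(self):
        ins = np.zeros((40, 40), bool)
        ins[10:30, 10:30] = True
        hull = de.islet_hull(ins)
        glu = np.zeros_like(ins)
        glu[15:25, 34] = True  # column at gap 5 px right of the hull edge x=29
        d, _ = de.glucagon_distances(glu, hull)
        assert d.max() < 0
        assert d.min() == pytest.approx(-5.0, abs=0.1)

    def test_uniform_disk_mean_distance_R_over_3(self):
        # pixel-enumeration oracle: mean of (R - r) over the uniform disk = R/3
        ins, glu = _disk_masks(radius=100, infiltration=1.0, n_glu=4000, seed=1)
        d, _ = de.glucagon_distances(glu, de.islet_hull(ins))
        assert d.mean() == pytest.approx(100 / 3, rel=0.02)

    def test_pixel_size_scales_distances(self):
        ins, glu = _disk_masks(radius=40, infiltration=0.5, seed=2)
        hull = de.islet_hull(ins)
        d1, _ = de.glucagon_distances(glu, hull, pixel_size=1.0)
        d2, _ = de.glucagon_distances(glu, hull, pixel_size=2.0)
        np.testing.assert_allclose(d2, 2 * d1)


class TestIndex:
    def test_all_zero_distances_give_zero(self):
        assert de.irregularity_index(np.zeros(50)) == 0.0

    def test_trimmed_mean_arithmetic_oracle(self):
        # {1..100}, trim 5 from each tail -> mean of {6..95} = 50.5
        assert de.irregularity_index(np.arange(1, 101.0), 0.05) == pytest.approx(50.5)

    def test_all_trimmed_is_error(self):
        with pytest.raises(ValueError):
            de.irregularity_index(np.arange(8.0), 0.49)

    def test_monotone_in_infiltration(self):
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        idx = []
        for lv in levels:
            ins, glu = _disk_masks(radius=80, infiltration=lv, n_glu=1500, seed=4)
            m = de.analyze_islet(ins, glu)
            idx.append(m.index)
        assert all(a < b for a, b in zip(idx, idx[1:]))

    def test_core_mantle_vs_mixed_reproduces_disease_gap(self):
        ins, glu = _disk_masks(radius=90, infiltration=0.0, n_glu=1500, seed=5)
        mantle = de.analyze_islet(ins, glu).index
        ins, glu = _disk_masks(radius=90, infiltration=1.0, n_glu=1500, seed=5)
        mixed = de.analyze_islet(ins, glu).index
        assert mantle < 3.0
        assert mixed == pytest.approx(90 / 3, rel=0.1)

    def test_rigid_motion_invariance(self):
        ins, glu = _disk_masks(radius=50, infiltration=0.4, n_glu=800, seed=6)
        base = de.analyze_islet(ins, glu).index
        shifted = de.analyze_islet(np.roll(ins, (3, -3), (0, 1)),
                                   np.roll(glu, (3, -3), (0, 1))).index
        assert shifted == pytest.approx(base, abs=1e-9)
        rot_i = np.rot90(ins)
        rot_g = np.rot90(glu)
        assert de.analyze_islet(rot_i, rot_g).index == pytest.approx(base, abs=1.0)


class TestPairedSignedRank:
    def test_five_concordant_pairs_one_sided(self):
        # all five differences positive: p = 1/2^5 = 0.03125 (printed 0.031)
        p = de.paired_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1], "greater")
        assert p == pytest.approx(1 / 32, abs=1e-12)

    def test_two_pairs_enumeration(self):
        # differences (+1, -1): W+ >= observed in 3 of 4 sign patterns
        p = de.paired_signed_rank([1.0, 0.0], [0.0, 1.0], "greater")
        assert p == pytest.approx(0.75, abs=1e-12)

    def test_negation_swaps_one_sided_pvalues(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert de.paired_signed_rank(a, b, "greater") == pytest.approx(
            de.paired_signed_rank(b, a, "less"), abs=1e-12
        )

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero differences"):
            p = de.paired_signed_rank([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], "greater")
        assert p == pytest.approx(1 / 32, abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(18)
        d = rng.normal(0.3, 1, 15)
        from scipy.stats import wilcoxon

        ours = de.paired_signed_rank(d, np.zeros(15), "greater")
        ref = wilcoxon(d, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)
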