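"""Complexion histograms: layout arithmetic, normalization, regions, fusion."""

import math

import numpy as np
import pytest

import complexion as cx
from complexion.features import (
    DEFAULT_REGION_WEIGHTS,
    REGION_ORDER,
    LuminanceBinning,
    RegionPartition,
    assign_pixels,
    chromaticity_only_histogram,
    feature_length,
    fuse_features,
    luminance_only_histogram,
    regional_histograms,
    segment_regions,
)

REFINED = LuminanceBinning(25, 95, 14)
COARSE = LuminanceBinning(0, 100, 10)


class TestFeatureLength:
    @pytest.mark.parametrize(
        "binning,base_bins,expected",
        [
            (COARSE, False, 40),  # preliminary layout
            (REFINED, True, 24),  # refined layout
            (LuminanceBinning(25, 95, 1), True, 284),  # sweep endpoint
            (LuminanceBinning(25, 95, 35), True, 12),  # sweep endpoint
        ],
    )
    def test_printed_dimensions(self, binning, base_bins, expected):
        assert feature_length(binning, base_bins) == expected

    @pytest.mark.parametrize("interval", [1, 2, 3, 5, 7, 10, 14, 23, 35])
    def test_agrees_with_bin_edge_enumeration(self, interval):
        # brute-force enumeration of full bins on [25, 95]
        edges = []
        lo = 25.0
        while lo + interval <= 95.0 + 1e-9:
            edges.append(lo)
            lo += interval
        k = len(edges)
        binning = LuminanceBinning(25, 95, interval)
        assert binning.n_bins == k
        assert feature_length(binning, True) == 4 * k + 4
        assert feature_length(binning, False) == 4 * k


class TestAssignPixels:
    def test_forced_assignment_example(self, default_bases):
        # all pixels exactly at the red base with L = 50 -> red sub-bin 1
        red = default_bases.centers[2]
        lab = np.column_stack([np.full(100, 50.0), np.tile(red, (100, 1))])
        hist = assign_pixels(lab, default_bases, REFINED, include_base_bins=True)
        assert hist.aggregate_bins()[2] == pytest.approx(1.0)
        sub = hist.sub_bins()
        assert sub[2, 1] == pytest.approx(1.0)
        assert sub.sum() == pytest.approx(1.0)

    def test_vector_lengths(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(20, 90, 300), rng.normal(10, 8, (300, 2))])
        assert len(assign_pixels(lab, default_bases, COARSE, False).values) == 40
        assert len(assign_pixels(lab, default_bases, REFINED, True).values) == 24

    def test_normalization_identities(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(0, 100, 500), rng.normal(12, 10, (500, 2))])
        hist = assign_pixels(lab, default_bases, REFINED, True)
        assert hist.aggregate_bins().sum() == pytest.approx(1.0, abs=1e-9)
        assert hist.sub_bins().sum() == pytest.approx(1.0, abs=1e-9)

    def test_counts_restore_round_trip(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(0, 100, 321), rng.normal(12, 10, (321, 2))])
        hist = assign_pixels(lab, default_bases, REFINED, True)
        counts = hist.values * hist.n_pixels
        np.testing.assert_allclose(counts / hist.n_pixels, hist.values, atol=1e-9)
        np.testing.assert_allclose(counts.round(), counts, atol=1e-9)

    def test_permutation_invariance(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(20, 90, 400), rng.normal(12, 10, (400, 2))])
        a = assign_pixels(lab, default_bases, REFINED, True)
        b = assign_pixels(lab[rng.permutation(400)], default_bases, REFINED, True)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_out_of_range_luminance_clamps(self, default_bases):
        lab = np.array([[5.0, 14, 16], [99.0, 14, 16]])
        hist = assign_pixels(lab, default_bases, REFINED, True)
        sub = hist.sub_bins()
        assert sub[:, 0].sum() == pytest.approx(0.5)  # clamped to bottom bin
        assert sub[:, -1].sum() == pytest.approx(0.5)  # clamped to top bin

    def test_empty_input_rejected(self, default_bases):
        with pytest.raises(ValueError, match="empty"):
            assign_pixels(np.zeros((0, 3)), default_bases)


class TestSegmentRegions:
    def test_full_rectangle_fractions(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True  # 100 x 100 rectangle
        part = segment_regions(mask)
        areas = {name: int(m.sum()) for name, m in part.regions.items()}
        assert areas["forehead"] == 33 * 100
        assert areas["jaw"] == 25 * 100
        assert areas["left_cheek"] == 42 * 35
        assert areas["nose"] == 42 * 30
        assert areas["right_cheek"] == 42 * 35

    def test_fixture_regions_nonempty_disjoint(self, default_cohort):
        mask = default_cohort["fixtures"][0].skin_mask
        part = segment_regions(mask)
        total = np.zeros_like(mask, dtype=int)
        for name, m in part.regions.items():
            assert m.any(), name
            assert (m & ~mask).sum() == 0  # subset of the skin mask
            total += m
        assert total.max() == 1  # pairwise disjoint

    def test_hole_shrinks_only_the_holed_region(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:, :] = True
        part_full = segment_regions(mask)
        holed = mask.copy()
        holed[45:55, 45:55] = False  # inside the nose block
        part_holed = segment_regions(holed)
        assert part_holed.regions["nose"].sum() < part_full.regions["nose"].sum()
        for name in ("left_cheek", "right_cheek", "forehead", "jaw"):
            assert part_holed.regions[name].sum() == part_full.regions[name].sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_regions(np.zeros((10, 10), dtype=bool))

    def test_weights_must_sum_to_one(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(ValueError, match="sum to 1"):
            RegionPartition(
                regions=segment_regions(mask).regions,
                region_weights={r: 0.5 for r in REGION_ORDER},
            )


def _lab_image_from_mask(mask, rng, center=(14.0, 16.0), lum=60.0):
    h, w = mask.shape
    img = np.zeros((h, w, 3))
    img[..., 0] = rng.normal(lum, 5, (h, w))
    img[..., 1] = rng.normal(center[0], 3, (h, w))
    img[..., 2] = rng.normal(center[1], 3, (h, w))
    return img


class TestRegionalHistograms:
    def test_uniform_face_gives_identical_histograms(self, default_bases):
        mask = np.ones((60, 60), dtype=bool)
        part = segment_regions(mask)
        img = np.zeros((60, 60, 3))
        img[..., 0] = 50.0
        img[..., 1:] = default_bases.centers[0]
        hists = regional_histograms(img, part, default_bases, REFINED)
        ref = hists[REGION_ORDER[0]].values
        for name in REGION_ORDER[1:]:
            np.testing.assert_allclose(hists[name].values, ref, atol=1e-12)

    def test_aggregate_bins_sum_to_one_each(self, default_bases, rng):
        mask = np.ones((60, 60), dtype=bool)
        part = segment_regions(mask)
        img = _lab_image_from_mask(mask, rng)
        for h in regional_histograms(img, part, default_bases, REFINED).values():
            assert h.aggregate_bins().sum() == pytest.approx(1.0, abs=1e-9)

    def test_cheek_tint_shows_in_cheek_histograms(self, default_bases):
        fix = cx.generate_face(
            cx.FaceSpec("red", tint_region="cheeks", artifact_counts=(0, 0), seed=77)
        )
        lab_img = cx.rgb_to_lab(fix.image)
        part = segment_regions(fix.skin_mask)
        hists = regional_histograms(lab_img, part, default_bases, REFINED)
        red_idx = 2
        cheek_red = 0.5 * (
            hists["left_cheek"].aggregate_bins()[red_idx]
            + hists["right_cheek"].aggregate_bins()[red_idx]
        )
        assert cheek_red > hists["forehead"].aggregate_bins()[red_idx] + 0.2

    def test_empty_region_is_named(self, default_bases):
        # carve the whole nose block out of a full rectangle: the hole is
        # far too large for morphological closing to bridge
        mask = np.ones((100, 100), dtype=bool)
        mask[33:75, 35:65] = False
        part = segment_regions(mask)
        img = _lab_image_from_mask(mask, np.random.default_rng(0))
        with pytest.raises(ValueError, match="nose"):
            regional_histograms(img, part, default_bases, REFINED)


class TestFuseFeatures:
    def _identical_hists(self, default_bases, rng):
        mask = np.ones((60, 60), dtype=bool)
        img = np.zeros((60, 60, 3))
        img[..., 0] = 50.0
        img[..., 1:] = default_bases.centers[1]
        part = segment_regions(mask)
        return regional_histograms(img, part, default_bases, REFINED)

    def test_blocks_are_weight_scaled(self, default_bases, rng):
        hists = self._identical_hists(default_bases, rng)
        fused = fuse_features(hists)
        common = hists["left_cheek"].values
        L = len(common)
        for i, name in enumerate(REGION_ORDER):
            np.testing.assert_allclose(
                fused.values[i * L:(i + 1) * L],
                DEFAULT_REGION_WEIGHTS[name] * common,
                atol=1e-12,
            )

    def test_fused_length_is_120(self, default_bases, rng):
        fused = fuse_features(self._identical_hists(default_bases, rng))
        assert len(fused.values) == 120
        # total aggregate mass across regions is 1 by construction
        total = sum(fused.aggregate_bins(r).sum() for r in range(5))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_pixel_weighted_fusion_matches_whole_face(self, default_bases, rng):
        """With weights proportional to region size, summed aggregate bins
        equal the whole-face proportions (regions tile the mask)."""
        mask = np.ones((60, 60), dtype=bool)
        part = segment_regions(mask)
        img = _lab_image_from_mask(mask, rng)
        hists = regional_histograms(img, part, default_bases, REFINED)
        sizes = {n: part.regions[n].sum() for n in REGION_ORDER}
        weights = {n: s / mask.sum() for n, s in sizes.items()}
        fused = fuse_features(hists, weights)
        summed = sum(fused.aggregate_bins(r) for r in range(5))
        whole = assign_pixels(img[mask], default_bases, REFINED, True).aggregate_bins()
        np.testing.assert_allclose(summed, whole, atol=1e-9)

    def test_bad_weight_sum_rejected(self, default_bases, rng):
        hists = self._identical_hists(default_bases, rng)
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_features(hists, {n: 0.3 for n in REGION_ORDER})


class TestChromaticityOnly:
    def test_single_base_mass(self, default_bases):
        lab = np.column_stack(
            [np.full(50, 60.0), np.tile(default_bases.centers[0], (50, 1))]
        )
        np.testing.assert_allclose(
            chromaticity_only_histogram(lab, default_bases), [1, 0, 0, 0], atol=1e-12
        )

    def test_equals_aggregate_bins(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(20, 90, 400), rng.normal(12, 10, (400, 2))])
        hist = assign_pixels(lab, default_bases, REFINED, True)
        np.testing.assert_allclose(
            chromaticity_only_histogram(lab, default_bases),
            hist.aggregate_bins(),
            atol=1e-12,
        )


class TestLuminanceOnly:
    def test_sums_to_one(self, default_bases, rng):
        lab = np.column_stack([rng.uniform(20, 90, 400), rng.normal(12, 10, (400, 2))])
        hist = assign_pixels(lab, default_bases, REFINED, True)
        assert luminance_only_histogram(hist).sum() == pytest.approx(1.0, abs=1e-9)

    def test_top_bin_unit_vector(self, default_bases):
        lab = np.column_stack([np.full(30, 94.0), np.tile([14.0, 16.0], (30, 1))])
        out = luminance_only_histogram(assign_pixels(lab, default_bases, REFINED, True))
        expected = np.zeros(REFINED.n_bins)
        expected[-1] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_bright_face_dominates_dim_face(self, default_bases, rng):
        bright = np.column_stack([rng.normal(80, 5, 2000), rng.normal(14, 4, (2000, 2))])
        dim = np.column_stack([rng.normal(40, 5, 2000), rng.normal(14, 4, (2000, 2))])
        hb = luminance_only_histogram(assign_pixels(bright, default_bases, REFINED, True))
        hd = luminance_only_histogram(assign_pixels(dim, default_bases, REFINED, True))
        # stochastic dominance of the cumulative distributions
        assert (np.cumsum(hb) <= np.cumsum(hd) + 1e-9).all()

    def test_fused_input_sums_regions(self, default_bases, rng):
        mask = np.ones((60, 60), dtype=bool)
        part = segment_regions(mask)
        img = _lab_image_from_mask(mask, rng)
        hists = regional_histograms(img, part, default_bases, REFINED)
        fused = fuse_features(hists)
        out = luminance_only_histogram(fused)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.shape == (REFINED.n_bins,)


def test_binning_validation():
    with pytest.raises(ValueError):
        LuminanceBinning(50, 40, 5)
    with pytest.raises(ValueError):
        LuminanceBinning(0, 100, 0)
    assert LuminanceBinning(25, 95, 14).n_bins == math.floor(70 / 14)
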