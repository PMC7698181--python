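"""The 100-feature catalog: analytic shapes, statistic oracles, and the
published selected-feature subsets."""

import numpy as np
import pytest

from funduslayers.candidates import label_regions
from funduslayers.core import (CandidateRegion, FundusImage, LayerStack,
                               RetinalAnatomy)
from funduslayers.features import (EX_SELECTED, FEATURE_NAMES, RL_SELECTED,
                                   FeatureExtractor, catalog_json,
                                   circle_stats, extract_all, normalize,
                                   region_stats, shape_features)

import oracles


def _region_from_mask(mask):
    return label_regions(mask, min_area=2)[0]


class TestShapeFeatures:
    def test_filled_square_analytic(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        f = shape_features(_region_from_mask(mask))
        area, bw, bh, hull, ecc, holes, extent, major, minor, perim, solid = f
        assert area == 100 and bw == 10 and bh == 10
        assert hull == 100 and holes == 0
        assert extent == 1.0 and solid == 1.0
        assert perim == 40.0
        assert ecc == pytest.approx(0.0, abs=1e-12)
        assert major == pytest.approx(minor)

    def test_square_with_hole(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[9:11, 9:11] = False
        f = shape_features(_region_from_mask(mask))
        assert f[0] == 96 and f[5] == 1
        assert f[3] == 100            # hull ignores the hole

    def test_degenerate_line_region(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 2:8] = True
        f = shape_features(_region_from_mask(mask))
        assert f[4] == 1.0 and f[10] == 1.0     # eccentricity, solidity

    def test_random_blobs_match_oracle(self, rng):
        for _ in range(10):
            mask = np.zeros((24, 24), bool)
            seed_pts = rng.integers(4, 20, size=(3, 2))
            rows, cols = np.indices((24, 24))
            for r, c in seed_pts:
                mask |= (np.hypot(rows - r, cols - c) <= rng.uniform(2, 5))
            regions = label_regions(mask, min_area=2)
            for region in regions:
                got = shape_features(region)
                want = oracles.shape_oracle(region.pixels)
                np.testing.assert_allclose(got, want, atol=1e-9)


class TestRegionStats:
    def test_constant_region(self):
        raster = np.full((10, 10, 3), 0.4)
        mask = np.zeros((10, 10), bool)
        mask[2:6, 2:6] = True
        s = region_stats(raster, _region_from_mask(mask))
        assert np.allclose(s[0:6], 0.4)          # means, medians
        assert np.allclose(s[6:12], 0.0)         # stds, entropies

    def test_two_valued_region_entropy_one_bit(self):
        raster = np.zeros((4, 4, 3))
        raster[0:2] = 0.2
        raster[2:4] = 0.8
        mask = np.ones((4, 4), bool)
        s = region_stats(raster, _region_from_mask(mask))
        assert np.allclose(s[9:12], 1.0)

    def test_random_region_matches_loops(self, rng):
        raster = rng.uniform(size=(16, 16, 3))
        mask = rng.uniform(size=(16, 16)) < 0.4
        mask[0, :2] = True
        region = label_regions(mask, min_area=2)[0]
        got = region_stats(raster, region)
        vals = raster[region.pixels[:, 0], region.pixels[:, 1], :]
        want = oracles.stats12_oracle(vals)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestCircleStats:
    def test_all_black_layer(self):
        s = circle_stats(np.zeros((32, 32, 3)), (16.0, 16.0), 6.0)
        assert np.allclose(s, 0.0)

    def test_half_black_circle_mean(self):
        raster = np.zeros((64, 64, 3))
        raster[:, 32:] = 0.6
        s = circle_stats(raster, (32.0, 32.0), 10.0)
        assert s[0] == pytest.approx(0.3, abs=0.02)

    def test_random_matches_enumeration(self, rng):
        raster = rng.uniform(size=(32, 32, 3))
        center = (14.3, 17.8)
        got = circle_stats(raster, center, 7.5)
        pix = oracles.circle_pixels_oracle((32, 32), center, 7.5)
        vals = np.array([raster[r, c, :] for r, c in pix])
        want = oracles.stats12_oracle(vals)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_clipping_at_raster_bounds(self, rng):
        raster = rng.uniform(size=(20, 20, 3))
        s = circle_stats(raster, (1.0, 1.0), 5.0)
        assert np.all(np.isfinite(s))


def _tiny_stack(rng, side=64):
    """Random layer stack + anatomy for extractor-level tests."""
    def sparse():
        r = rng.uniform(size=(side, side, 3))
        r[rng.uniform(size=(side, side)) < 0.6] = 0.0
        return r

    iprep = FundusImage(rng.uniform(size=(side, side, 3)),
                        np.ones((side, side), bool), float(side) * 0.9)
    stack = LayerStack(
        idark=sparse(), idark2=sparse(), lchor_dark=sparse(),
        lrl_cand=sparse(), mrl_cand=rng.uniform(size=(side, side)) < 0.1,
        ibri=sparse(), lchor_bri=sparse(), lbm=sparse(),
        lex_cand=sparse(), mex_cand=rng.uniform(size=(side, side)) < 0.1,
    )
    anat = RetinalAnatomy(
        vessel_mask=rng.uniform(size=(side, side)) < 0.1,
        od_center=(side * 0.3, side * 0.6), od_radius=iprep.fov_diameter / 12.0,
        fovea_center=(side * 0.55, side * 0.35),
    )
    return iprep, stack, anat


class TestExtractor:
    def test_feature_vector_contract(self, rng):
        iprep, stack, anat = _tiny_stack(rng)
        regions = label_regions(stack.mrl_cand, min_area=2)[:5]
        X = extract_all(regions, stack, iprep, anat, "rl")
        assert X.shape == (len(regions), 100)
        assert np.all(np.isfinite(X))
        assert regions[0].features is not None

    def test_row_region_correspondence_under_shuffle(self, rng):
        iprep, stack, anat = _tiny_stack(rng)
        regions = label_regions(stack.mrl_cand, min_area=2)[:6]
        X = extract_all(regions, stack, iprep, anat, "rl")
        perm = rng.permutation(len(regions))
        X2 = extract_all([regions[i] for i in perm], stack, iprep, anat, "rl")
        np.testing.assert_allclose(X2, X[perm], atol=1e-12)

    def test_distance_features_zero_at_landmarks(self, rng):
        iprep, stack, anat = _tiny_stack(rng)
        mask = np.zeros((64, 64), bool)
        r, c = int(anat.od_center[0]), int(anat.od_center[1])
        mask[r - 1:r + 1, c - 1:c + 1] = True    # centroid exactly at od_center
        region = label_regions(mask)[0]
        ext = FeatureExtractor(iprep, stack, anat, "rl")
        f = ext.extract(region)
        assert f[98] == pytest.approx(
            np.hypot(region.centroid[0] - anat.od_center[0],
                     region.centroid[1] - anat.od_center[1]) / iprep.fov_diameter)

    def test_sharp_edge_scores_higher_prewitt(self, rng):
        from scipy.ndimage import gaussian_filter
        side = 64
        base = np.full((side, side, 3), 0.5)
        rows, cols = np.indices((side, side))
        disk_sharp = np.hypot(rows - 20, cols - 20) <= 6
        disk_soft = (gaussian_filter((np.hypot(rows - 44, cols - 44) <= 6).astype(float), 2.0))
        img = base + 0.3 * disk_sharp[..., None] + 0.3 * disk_soft[..., None]
        iprep = FundusImage(np.clip(img, 0, 1), np.ones((side, side), bool), side * 0.9)
        _, stack, anat = _tiny_stack(rng, side)
        ext = FeatureExtractor(iprep, stack, anat, "rl")
        f_sharp = ext.extract(label_regions(disk_sharp)[0])
        f_soft = ext.extract(label_regions(np.hypot(rows - 44, cols - 44) <= 6)[0])
        assert f_sharp[96] > f_soft[96]

    def test_line_operator_separates_lines_from_blobs(self, rng):
        side = 64
        img = np.full((side, side, 3), 0.6)
        rows, cols = np.indices((side, side))
        line = (np.abs(rows - 20) <= 1) & (np.abs(cols - 32) <= 8)
        blob = np.hypot(rows - 44, cols - 32) <= np.sqrt(line.sum() / np.pi)
        img[line] -= 0.3
        img[blob] -= 0.3
        iprep = FundusImage(np.clip(img, 0, 1), np.ones((side, side), bool), side * 0.9)
        _, stack, anat = _tiny_stack(rng, side)
        ext = FeatureExtractor(iprep, stack, anat, "rl")
        f_line = ext.extract(label_regions(line)[0])
        f_blob = ext.extract(label_regions(blob)[0])
        assert f_line[97] > f_blob[97]

    def test_translation_invariance(self, rng):
        """Shifting scene + anatomy together leaves all 100 features equal."""
        iprep, stack, anat = _tiny_stack(rng)
        dr, dc = 3, 5

        def shift2(a):
            return np.roll(np.roll(a, dr, axis=0), dc, axis=1)

        iprep2 = FundusImage(shift2(iprep.rgb), shift2(iprep.fov_mask),
                             iprep.fov_diameter)
        stack2 = LayerStack(**{
            n: (shift2(getattr(stack, n)) if getattr(stack, n) is not None else None)
            for n in LayerStack.LAYER_NAMES
        })
        anat2 = RetinalAnatomy(
            vessel_mask=shift2(anat.vessel_mask),
            od_center=(anat.od_center[0] + dr, anat.od_center[1] + dc),
            od_radius=anat.od_radius,
            fovea_center=(anat.fovea_center[0] + dr, anat.fovea_center[1] + dc),
        )
        mask = np.zeros((64, 64), bool)
        mask[20:26, 30:37] = True
        mask[22, 36] = True
        region = label_regions(mask)[0]
        region2 = label_regions(shift2(mask))[0]
        f1 = FeatureExtractor(iprep, stack, anat, "rl").extract(region)
        f2 = FeatureExtractor(iprep2, stack2, anat2, "rl").extract(region2)
        # interior shift with wraparound avoided by margins → identical maps
        np.testing.assert_allclose(f2, f1, atol=1e-9)


class TestFullOracle:
    def test_every_feature_matches_independent_recomputation(self, rng):
        """All 100 features against loop-based recomputation (tol 1e-9)."""
        from skimage import color as skcolor
        iprep, stack, anat = _tiny_stack(rng)
        regions = []
        rows, cols = np.indices((64, 64))
        while len(regions) < 20:
            r, c = rng.integers(6, 58, size=2)
            rad = rng.uniform(1.5, 4)
            mask = np.hypot(rows - r, cols - c) <= rad
            found = label_regions(mask, min_area=2)
            if found:
                regions.append(found[0])
        X = extract_all(regions, stack, iprep, anat, "rl")

        cand_hsv = skcolor.rgb2hsv(stack.lrl_cand)
        layer_hsvs = [skcolor.rgb2hsv(getattr(stack, n)) for n in
                      ("lrl_cand", "lchor_dark", "lchor_bri", "lex_cand", "lbm")]
        value = iprep.rgb.max(axis=2)
        inv_green = 1.0 - iprep.rgb[..., 1]
        lbm_v = stack.lbm.max(axis=2)
        f96 = lbm_v[iprep.fov_mask].mean()

        for row, region in zip(X, regions):
            want = np.empty(100)
            want[0:11] = oracles.shape_oracle(region.pixels)
            vals = iprep.rgb[region.pixels[:, 0], region.pixels[:, 1], :]
            want[11:23] = oracles.stats12_oracle(vals)
            vals = cand_hsv[region.pixels[:, 0], region.pixels[:, 1], :]
            want[23:35] = oracles.stats12_oracle(vals)
            for i, hsv in enumerate(layer_hsvs):
                pix = oracles.circle_pixels_oracle((64, 64), region.centroid,
                                                   anat.od_radius)
                cvals = np.array([hsv[a, b, :] for a, b in pix])
                want[35 + 12 * i: 47 + 12 * i] = oracles.stats12_oracle(cvals)
            want[95] = f96
            from funduslayers.features import boundary_pixels
            bp = boundary_pixels(region)
            want[96] = np.mean([oracles.prewitt_magnitude_oracle(value, r, c)
                                for r, c in bp])
            want[97] = np.mean([oracles.line_response_oracle(inv_green, r, c,
                                                             anat.od_radius)
                                for r, c in region.pixels])
            want[98] = np.hypot(region.centroid[0] - anat.od_center[0],
                                region.centroid[1] - anat.od_center[1]) / iprep.fov_diameter
            want[99] = np.hypot(region.centroid[0] - anat.fovea_center[0],
                                region.centroid[1] - anat.fovea_center[1]) / iprep.fov_diameter
            np.testing.assert_allclose(row, want, atol=1e-9)


class TestNormalize:
    def test_training_call_standardizes(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 7))
        Xz, mean, std = normalize(X)
        np.testing.assert_allclose(Xz.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xz.std(axis=0), 1.0, atol=1e-9)

    def test_inference_reuses_constants(self, rng):
        X = rng.normal(size=(30, 4))
        _, mean, std = normalize(X)
        X2 = rng.normal(size=(10, 4))
        Xz2, m2, s2 = normalize(X2, mean, std)
        np.testing.assert_array_equal(m2, mean)
        np.testing.assert_allclose(Xz2, (X2 - mean) / std, atol=1e-12)

    def test_roundtrip_inverse(self, rng):
        X = rng.normal(size=(40, 5))
        Xz, mean, std = normalize(X)
        np.testing.assert_allclose(Xz * std + mean, X, atol=1e-9)

    def test_zero_variance_column_warns_and_passes_through(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning):
            Xz, mean, std = normalize(X)
        assert std[1] == 1.0
        np.testing.assert_allclose(Xz[:, 1], 0.0, atol=1e-12)


class TestCatalogConstants:
    def test_selected_subsets_exact(self):
        assert len(RL_SELECTED) == 24
        assert len(EX_SELECTED) == 34
        assert RL_SELECTED == (5, 11, 13, 18, 19, 22, 23, 24, 26, 28, 29, 32,
                               35, 44, 59, 63, 64, 65, 66, 90, 96, 97, 98, 100)
        assert EX_SELECTED == (5, 7, 17, 18, 19, 20, 21, 22, 23, 26, 27, 29,
                               30, 32, 34, 35, 42, 57, 62, 64, 65, 73, 74, 78,
                               79, 80, 83, 91, 93, 96, 97, 98, 99, 100)

    def test_catalog_has_100_named_entries(self):
        import json
        cat = json.loads(catalog_json())
        assert len(cat) == 100
        assert cat[0]["name"] == "area"
        assert cat[99]["name"] == "dist_to_fovea"
        assert len(FEATURE_NAMES) == len(set(FEATURE_NAMES))
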