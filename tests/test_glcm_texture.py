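"""Quantization, co-occurrence accumulation and texture features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrotex.glcm_texture import (
    DIRECTION_OFFSETS,
    FEATURE_NAMES,
    GLCMError,
    cooccurrence,
    features,
    quantize,
    texture_profile,
)
from fibrotex.imaging_core import BinaryMask, MaskedImage, apply_mask
from conftest import fully_valid, grid8


def brute_force_glcm(levels, valid, d, direction, n_levels):
    """Independent oracle: enumerate every pixel pair with a double loop."""
    dr, dc = (d * o for o in DIRECTION_OFFSETS[direction])
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels))
    n = 0
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and valid[r, c] and valid[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
                counts[levels[r2, c2], levels[r, c]] += 1
                n += 1
    return counts / counts.sum() if n else counts, n


def checkerboard_quantized(n=8):
    arr = np.indices((n, n)).sum(axis=0) % 2 * 255
    return quantize(fully_valid(grid8(arr)), n_levels=2)


class TestQuantize:
    def test_two_point_range(self):
        q = quantize(fully_valid(grid8([[0, 255]])), n_levels=2)
        assert q.levels.tolist() == [[0, 1]]

    def test_matches_per_pixel_formula(self, rng):
        img = grid8(rng.integers(13, 201, (20, 20)))
        q = quantize(fully_valid(img), n_levels=64)
        v = img.pixels.astype(float)
        expected = np.floor(63 * (v - v.min()) / (v.max() - v.min())).astype(int)
        np.testing.assert_array_equal(q.levels, expected)
        assert q.levels.max() == 63 and q.levels.min() == 0

    def test_constant_region_maps_to_zero(self):
        q = quantize(fully_valid(grid8(np.full((4, 4), 90))), n_levels=16)
        assert (q.levels == 0).all()

    def test_range_taken_from_valid_pixels_only(self, rng):
        arr = np.full((6, 6), 100, dtype=np.uint8)
        arr[0, 0] = 255  # invalid outlier must not stretch the range
        arr[5, 5] = 120
        valid = np.ones((6, 6), bool)
        valid[0, 0] = False
        q = quantize(MaskedImage(grid8(arr), valid), n_levels=4)
        assert q.levels[5, 5] == 3 and q.levels[1, 1] == 0

    def test_no_valid_pixels_errors(self, rng):
        masked = MaskedImage(grid8(rng.integers(0, 256, (4, 4))), np.zeros((4, 4), bool))
        with pytest.raises(GLCMError):
            quantize(masked)


class TestCooccurrence:
    def test_single_horizontal_pair(self):
        q = quantize(fully_valid(grid8([[0, 255]])), n_levels=2)
        g = cooccurrence(q, 1, 0)
        assert g.pair_count == 1
        assert g.p[0, 1] == g.p[1, 0] == 0.5 and g.p.sum() == 1.0

    def test_checkerboard_alternates(self):
        g = cooccurrence(checkerboard_quantized(), 1, 0)
        assert g.p[0, 1] == g.p[1, 0] == 0.5
        assert g.p[0, 0] == g.p[1, 1] == 0.0

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_matches_brute_force_with_mask(self, direction, rng):
        img = grid8(rng.integers(0, 256, (8, 8)))
        valid = rng.random((8, 8)) > 0.3
        q = quantize(MaskedImage(img, valid), n_levels=8)
        for d in range(1, 8):
            g = cooccurrence(q, d, direction)
            expected, n = brute_force_glcm(q.levels, valid, d, direction, 8)
            assert g.pair_count == n
            np.testing.assert_array_equal(g.p, expected)

    def test_offset_too_large_flags_empty(self):
        q = quantize(fully_valid(grid8(np.arange(16).reshape(4, 4))), n_levels=4)
        assert cooccurrence(q, 4, 0).is_empty

    def test_agrees_with_skimage_on_fully_valid_image(self, rng):
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        arr = rng.integers(0, 8, (16, 16)).astype(np.uint8)
        q = quantize(fully_valid(grid8(arr * 36)), n_levels=8)
        def close(set_a, set_b):
            return all(any(np.allclose(a, b) for b in set_b) for a in set_a)

        for d in (1, 3):
            ours_axial = {tuple(cooccurrence(q, d, a).p.ravel()) for a in (0, 90)}
            ref = graycomatrix(q.levels.astype(np.uint8), [d], [0, np.pi / 2],
                               levels=8, symmetric=True, normed=True)
            ref_axial = {tuple(ref[:, :, 0, i].ravel()) for i in (0, 1)}
            assert close(ours_axial, ref_axial)

        # diagonal comparison only at d = 1: skimage rounds d·(sin, cos) per
        # angle, so its longer "diagonal distances" are not multiples of (1, 1)
        ours_diag = {tuple(cooccurrence(q, 1, a).p.ravel()) for a in (45, 135)}
        ref = graycomatrix(q.levels.astype(np.uint8), [1], [np.pi / 4, 3 * np.pi / 4],
                           levels=8, symmetric=True, normed=True)
        ref_diag = {tuple(ref[:, :, 0, i].ravel()) for i in (0, 1)}
        assert close(ours_diag, ref_diag)


class TestFeatures:
    def test_degenerate_single_level(self):
        q = quantize(fully_valid(grid8(np.full((4, 4), 10))), n_levels=4)
        fs = features(cooccurrence(q, 1, 0))
        assert fs.asm == 1.0 and fs.contrast == 0.0 and fs.idm == 1.0
        assert fs.entropy == 0.0 and not fs.correlation_defined

    def test_checkerboard_closed_form(self):
        fs = features(cooccurrence(checkerboard_quantized(), 1, 0))
        assert fs.contrast == pytest.approx(1.0, abs=1e-15)
        assert fs.correlation == pytest.approx(-1.0, abs=1e-15)
        assert fs.asm == pytest.approx(0.5, abs=1e-15)
        assert fs.idm == pytest.approx(0.5, abs=1e-15)
        assert fs.entropy == pytest.approx(math.log(2), abs=1e-15)

    def test_matches_direct_summation(self, rng):
        img = grid8(rng.integers(0, 256, (8, 8)))
        g = cooccurrence(quantize(fully_valid(img), n_levels=8), 1, 45)
        fs = features(g)
        cells = [(i, j, g.p[i, j]) for i in range(8) for j in range(8)]
        asm = math.fsum(p * p for _, _, p in cells)
        contrast = math.fsum((i - j) ** 2 * p for i, j, p in cells)
        idm = math.fsum(p / (1 + (i - j) ** 2) for i, j, p in cells)
        entropy = -math.fsum(p * math.log(p) for _, _, p in cells if p > 0)
        mu = math.fsum(i * p for i, _, p in cells)
        var = math.fsum((i - mu) ** 2 * p for i, _, p in cells)
        corr = math.fsum((i - mu) * (j - mu) * p for i, j, p in cells) / var
        assert fs.asm == pytest.approx(asm, rel=1e-12)
        assert fs.contrast == pytest.approx(contrast, rel=1e-12)
        assert fs.idm == pytest.approx(idm, rel=1e-12)
        assert fs.entropy == pytest.approx(entropy, rel=1e-12)
        assert fs.correlation == pytest.approx(corr, rel=1e-10)

    def test_empty_glcm_rejected(self):
        q = quantize(fully_valid(grid8([[0, 255]])), n_levels=2)
        with pytest.raises(GLCMError):
            features(cooccurrence(q, 5, 0))


class TestProfile:
    def test_unit_configuration_has_five_values(self, rng):
        masked = fully_valid(grid8(rng.integers(0, 256, (8, 8))))
        profile = texture_profile(masked, n_levels=8, max_distance=1, directions=(0,))
        assert profile.n_values == 5
        assert set(profile.df["feature"]) == set(FEATURE_NAMES)

    def test_composes_cooccurrence_and_features(self, rng):
        img = grid8(rng.integers(0, 256, (12, 12)))
        valid = rng.random((12, 12)) > 0.2
        masked = MaskedImage(img, valid)
        profile = texture_profile(masked, n_levels=8, max_distance=4)
        q = quantize(masked, n_levels=8)
        for (d, ang), sub in profile.df.groupby(["distance_px", "direction_deg"]):
            fs = features(cooccurrence(q, int(d), int(ang)))
            got = dict(zip(sub["feature"], sub["value"]))
            for name, expected in fs.as_dict().items():
                if math.isnan(expected):
                    assert math.isnan(got[name])
                else:
                    assert got[name] == expected

    def test_unreachable_offsets_are_missing_not_zero(self, rng):
        masked = fully_valid(grid8(rng.integers(0, 256, (4, 4))))
        profile = texture_profile(masked, n_levels=4, max_distance=6)
        assert profile.df["distance_px"].max() == 3  # d >= 4 has no in-bounds pair

    def test_marginal_mass_sums_to_one(self, rng):
        q = quantize(fully_valid(grid8(rng.integers(0, 256, (10, 10)))), n_levels=8)
        g = cooccurrence(q, 2, 90)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.p.sum(axis=0), g.p.sum(axis=1), atol=1e-15)

    def test_rotation_swaps_axial_and_diagonal_profiles(self, rng):
        arr = rng.integers(0, 256, (10, 10))
        prof = texture_profile(fully_valid(grid8(arr)), n_levels=8, max_distance=3)
        prof_rot = texture_profile(fully_valid(grid8(np.rot90(arr))), n_levels=8, max_distance=3)

        def curves(p):
            return {
                (int(d), int(a), f): v
                for d, a, f, v in zip(p.df["distance_px"], p.df["direction_deg"],
                                      p.df["feature"], p.df["value"])
            }

        a, b = curves(prof), curves(prof_rot)
        swap = {0: 90, 90: 0, 45: 135, 135: 45}
        for (d, ang, f), v in a.items():
            w = b[(d, swap[ang], f)]
            assert (math.isnan(v) and math.isnan(w)) or v == w

    def test_smoothing_lowers_contrast_raises_correlation(self):
        from scipy.ndimage import gaussian_filter

        wins_contrast = wins_corr = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = rng.integers(0, 256, (64, 64)).astype(float)
            smooth = gaussian_filter(noise, 2.0)
            smooth = np.clip(np.rint(smooth), 0, 255)
            p_n = texture_profile(fully_valid(grid8(noise)), n_levels=32, max_distance=5)
            p_s = texture_profile(fully_valid(grid8(smooth)), n_levels=32, max_distance=5)
            from fibrotex.decay_stats import aggregate

            cn = aggregate(p_n).curve("contrast")[1]
            cs = aggregate(p_s).curve("contrast")[1]
            if (cn > cs).all():
                wins_contrast += 1
            rn = aggregate(p_n).curve("correlation")[1]
            rs = aggregate(p_s).curve("correlation")[1]
            if (rs[:2] > rn[:2]).all():
                wins_corr += 1
        assert wins_contrast >= 9 and wins_corr >= 9
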