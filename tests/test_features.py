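import numpy as np
import pytest

from woundbed.color import convert_all_spaces
from woundbed.features import (FEATURE_NAMES_PER_CHANNEL, N_FEATURES,
                               TissueRegion, build_feature_table, color_moments,
                               extract_features, feature_names, lbp_ri_code,
                               lbp_var_from_samples, lbp_var_maps,
                               local_contrast, quantize256, read_features,
                               shannon_entropy, write_features)
from woundbed.io import BinaryMask, RgbImage


def ri_oracle(bits):
    """Brute-force rotation minimum over explicit bit-list rotations."""
    p = len(bits)
    best = None
    for i in range(p):
        rot = bits[i:] + bits[:i]
        code = sum(b << k for k, b in enumerate(rot))
        best = code if best is None else min(best, code)
    return best


class TestColorMoments:
    def test_hand_example(self):
        mean, std, var, skew, kurt = color_moments([1, 2, 3, 4])
        assert mean == pytest.approx(2.5)
        assert var == pytest.approx(1.25)
        assert std == pytest.approx(np.sqrt(1.25), abs=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.64)

    def test_constant_degenerate(self):
        assert color_moments([7, 7, 7]) == (7.0, 0.0, 0.0, 0.0, 0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            color_moments([])


class TestEntropy:
    @pytest.mark.parametrize(
        "values,bits",
        [
            (np.full(50, 13.0), 0.0),
            (np.repeat([0.0, 128.0], 25), 1.0),
            (np.repeat([0.0, 64.0, 128.0, 192.0], 10), 2.0),
        ],
    )
    def test_closed_forms(self, values, bits):
        assert shannon_entropy(values) == pytest.approx(bits)


class TestLocalContrast:
    def test_mean_center_examples(self):
        assert local_contrast(np.array([2.0, 2, 8, 8]), "mean") == pytest.approx(0.6)
        assert local_contrast(np.array([1.0, 3, 5, 7]), "mean") == pytest.approx(0.5)

    def test_constant_is_zero(self):
        assert local_contrast(np.full(10, 5.0), "mean") == 0.0
        assert local_contrast(np.full(10, 5.0), "mode") == 0.0

    def test_median_and_mode_bounded(self, rng):
        v = rng.uniform(0, 255, size=200)
        for c in ("mean", "median", "mode"):
            assert -1.0 <= local_contrast(v, c) <= 1.0


class TestLbpCode:
    def test_flat_patch_all_ones(self):
        assert lbp_ri_code(np.full(8, 5.0), 5.0) == 255

    def test_hand_neighborhood(self):
        neigh = [6, 2, 7, 9, 1, 3, 8, 4]
        bits = [1 if g >= 5 else 0 for g in neigh]
        raw = sum(b << k for k, b in enumerate(bits))
        assert raw == 77
        assert lbp_ri_code(np.array(neigh, float), 5.0) == ri_oracle(bits) == 53

    def test_rotation_invariance_random(self, rng):
        for p in (8, 16, 24):
            g = rng.integers(0, 256, size=p).astype(float)
            c = float(rng.integers(0, 256))
            base = lbp_ri_code(g, c)
            for shift in (1, 3, p - 1):
                assert lbp_ri_code(np.roll(g, shift), c) == base

    def test_var_formula_alternating_ring(self):
        samples = np.tile([0.0, 255.0], 4)[None, :]
        ri, var = lbp_var_from_samples(samples, np.array([100.0]))
        assert var[0] == pytest.approx(16256.25)
        assert ri[0] == ri_oracle([0, 1, 0, 1, 0, 1, 0, 1])


class TestLbpVarMaps:
    def test_flat_region(self):
        plane = np.full((20, 20), 90.0)
        mask = BinaryMask(np.ones((20, 20), dtype=bool))
        for r, p in ((1, 8), (2, 16), (3, 24)):
            lbp, var = lbp_var_maps(plane, mask, r)
            assert var == pytest.approx(0.0, abs=1e-12)
            assert lbp == 2**p - 1

    def test_checkerboard_rougher_than_flat(self):
        yy, xx = np.mgrid[0:20, 0:20]
        checker = ((yy + xx) % 2) * 255.0
        mask = BinaryMask(np.ones((20, 20), dtype=bool))
        _, var_checker = lbp_var_maps(checker, mask, 1)
        _, var_flat = lbp_var_maps(np.zeros((20, 20)), mask, 1)
        assert var_checker > var_flat

    def test_tiny_mask_warns_and_zeroes(self, caplog):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = mask[5, 6] = True
        import logging
        with caplog.at_level(logging.WARNING, logger="woundbed.features"):
            lbp, var = lbp_var_maps(np.ones((20, 20)), BinaryMask(mask), 3)
        assert (lbp, var) == (0.0, 0.0)
        assert "neighborhood" in caplog.text


class TestExtractFeatures:
    def test_length_and_finiteness(self, small_wound):
        vec = extract_features(small_wound.image, small_wound.regions[0])
        assert vec.shape == (675,)
        assert np.all(np.isfinite(vec))
        assert N_FEATURES == 675 and len(feature_names()) == 675

    def test_constant_region_zero_spread(self):
        px = np.full((32, 32, 3), 120, dtype=np.uint8)
        img = RgbImage(px, id="flat")
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        vec = extract_features(img, TissueRegion("flat", BinaryMask(mask)))
        names = feature_names()
        for feat in ("std", "variance", "entropy", "var_r1", "var_r2", "var_r3"):
            idx = [i for i, n in enumerate(names) if n.endswith("_" + feat)]
            assert np.allclose(vec[idx], 0.0), feat

    def test_rotation_invariance_of_texture(self, small_wound):
        region = small_wound.regions[1]
        img90 = RgbImage(np.rot90(small_wound.image.pixels).copy(), id="rot")
        mask90 = BinaryMask(np.rot90(region.mask.pixels).copy())
        reg90 = TissueRegion("rot", mask90, region.label)
        v0 = extract_features(small_wound.image, region)
        v90 = extract_features(img90, reg90)
        names = feature_names()
        tex = [i for i, n in enumerate(names) if ("lbp_r" in n or "var_r" in n)]
        denom = np.maximum(np.abs(v0[tex]), 1.0)
        assert np.all(np.abs(v0[tex] - v90[tex]) / denom <= 0.02)

    def test_region_below_minimum_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[0, :8] = True
        with pytest.raises(ValueError, match="minimum"):
            TissueRegion("x", BinaryMask(mask))


class TestFeatureTableIO:
    def test_csv_roundtrip_bit_identical(self, small_wound, tmp_path):
        images = {small_wound.image.id: small_wound.image}
        table = build_feature_table(images, small_wound.regions[:2])
        assert table.shape[1] == 678  # 675 features + 3 bookkeeping columns
        path = tmp_path / "features.csv"
        write_features(table, path)
        back = read_features(path)
        assert list(back.columns) == list(table.columns)
        np.testing.assert_array_equal(
            back.iloc[:, 3:].to_numpy(), table.iloc[:, 3:].to_numpy()
        )


def test_quantize_range_edges():
    q = quantize256(np.array([0.0, 255.0, -5.0, 300.0]), 0.0, 255.0)
    assert q.tolist() == [0, 255, 0, 255]
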