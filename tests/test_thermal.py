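"""Canopy-temperature extraction: ROI, trimming, segmentation, Tc/SDD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermotype as tt
from thermotype.thermal import TEMP_MAX_C, TEMP_MIN_C


def brute_force_trim(values, low, high):
    """Independent oracle: explicit sort + order-statistic interpolation + filter."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size

    def pct(q):
        pos = q / 100.0 * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    p_low, p_high = pct(low), pct(high)
    kept = [x for x in np.asarray(values, dtype=float).ravel()
            if p_low <= x <= p_high]
    if not kept:  # degenerate contract: never return an empty sample
        kept, p_low, p_high = list(v), v[0], v[-1]
    return np.array(kept), p_low, p_high


class TestThermalImage:
    def test_rejects_out_of_window_pixels(self):
        with pytest.raises(ValueError, match="plausibility"):
            tt.ThermalImage(np.full((4, 4), TEMP_MAX_C + 1))
        with pytest.raises(ValueError, match="plausibility"):
            tt.ThermalImage(np.full((4, 4), TEMP_MIN_C - 1))

    def test_rejects_nonfinite_and_empty(self):
        bad = np.full((3, 3), 20.0)
        bad[1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tt.ThermalImage(bad)
        with pytest.raises(ValueError):
            tt.ThermalImage(np.empty((0, 5)))


class TestCentralRoi:
    def test_120_to_30_selects_rows_45_to_74(self):
        px = np.arange(120 * 120, dtype=float).reshape(120, 120) % 50
        img = tt.ThermalImage(px)
        roi = tt.central_roi(img, 30)
        np.testing.assert_array_equal(roi.pixels, px[45:75, 45:75])

    def test_identity_when_roi_equals_image(self):
        img = tt.ThermalImage(np.random.default_rng(0).uniform(15, 30, (30, 30)))
        roi = tt.central_roi(img, 30)
        np.testing.assert_array_equal(roi.pixels, img.pixels)

    def test_odd_remainder_drops_high_side(self):
        # 5x5 with distinct values, roi 2: remainder 3 -> rows/cols 1..2
        px = np.arange(25, dtype=float).reshape(5, 5)
        roi = tt.central_roi(tt.ThermalImage(px), 2)
        np.testing.assert_array_equal(roi.pixels, px[1:3, 1:3])

    def test_roi_shares_memory_with_source(self):
        img = tt.ThermalImage(np.full((10, 10), 20.0))
        roi = tt.central_roi(img, 4)
        assert np.shares_memory(roi.pixels, img.pixels)

    def test_oversized_roi_names_both_sizes(self):
        img = tt.ThermalImage(np.full((10, 12), 20.0))
        with pytest.raises(tt.DimensionError, match="30.*10x12"):
            tt.central_roi(img, 30)


class TestTrimByPercentiles:
    def test_constant_sample_fully_retained(self):
        retained, p_low, p_high = tt.trim_by_percentiles(np.full(900, 22.0))
        assert retained.size == 900
        assert p_low == p_high == 22.0

    def test_matches_brute_force_on_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        retained, p_low, p_high = tt.trim_by_percentiles(vals, 1, 97.5)
        exp_ret, exp_lo, exp_hi = brute_force_trim(vals, 1, 97.5)
        assert p_low == pytest.approx(exp_lo)
        assert p_high == pytest.approx(exp_hi)
        np.testing.assert_array_equal(np.sort(retained), np.sort(exp_ret))

    def test_gaussian_removal_fraction_near_3_5_percent(self):
        rng = np.random.default_rng(42)
        removed = []
        for _ in range(50):
            vals = rng.normal(25, 1.0, 900)
            retained, _, _ = tt.trim_by_percentiles(vals, 1, 97.5)
            removed.append(1 - retained.size / 900)
        # 1% low + 2.5% high, within binomial sampling error
        assert np.mean(removed) == pytest.approx(0.035, abs=0.01)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            tt.trim_by_percentiles([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-19, max_value=69), min_size=1, max_size=300),
           st.floats(min_value=0, max_value=20),
           st.floats(min_value=80, max_value=100))
    def test_property_matches_brute_force(self, values, low, high):
        retained, p_low, p_high = tt.trim_by_percentiles(values, low, high)
        exp_ret, exp_lo, exp_hi = brute_force_trim(values, low, high)
        assert p_low == pytest.approx(exp_lo, abs=1e-9)
        assert p_high == pytest.approx(exp_hi, abs=1e-9)
        np.testing.assert_allclose(np.sort(retained), np.sort(exp_ret))

    def test_repeated_trims_nest(self):
        # a second pass recomputes percentiles inside the trimmed range,
        # so results shrink monotonically with nested thresholds
        rng = np.random.default_rng(7)
        vals = rng.normal(25, 2, 500)
        first, lo1, hi1 = tt.trim_by_percentiles(vals, 1, 97.5)
        second, lo2, hi2 = tt.trim_by_percentiles(first, 1, 97.5)
        assert lo1 <= lo2 <= hi2 <= hi1
        assert set(second).issubset(set(first))
        assert second.size >= 0.95 * first.size

    def test_degenerate_two_value_sample_retained_in_full(self):
        retained, p_low, p_high = tt.trim_by_percentiles([20.0, 30.0], 1, 97.5)
        np.testing.assert_array_equal(np.sort(retained), [20.0, 30.0])
        assert (p_low, p_high) == (20.0, 30.0)


class TestSegmentCanopy:
    def test_band_keeps_separated_canopy_class(self):
        px = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 20.0, 35.0)
        img = tt.ThermalImage(px)
        mask = tt.segment_canopy(img, mode="band_threshold", t_min=15, t_max=27)
        np.testing.assert_array_equal(mask.keep, px == 20.0)

    def test_external_mask_passthrough(self):
        img = tt.ThermalImage(np.full((6, 6), 21.0))
        mask = tt.CanopyMask(np.ones((6, 6), dtype=bool))
        assert tt.segment_canopy(img, mode="external_mask", mask=mask) is mask

    def test_shape_mismatch_raises(self):
        img = tt.ThermalImage(np.full((6, 6), 21.0))
        with pytest.raises(tt.ShapeMismatchError):
            tt.segment_canopy(img, mode="external_mask",
                              mask=tt.CanopyMask(np.ones((5, 6), dtype=bool)))

    def test_empty_band_advises_threshold_review(self):
        img = tt.ThermalImage(np.full((6, 6), 21.0))
        with pytest.raises(tt.EmptyCanopyError, match="review"):
            tt.segment_canopy(img, mode="band_threshold", t_min=40, t_max=50)

    def test_band_at_antimode_recovers_simulated_mask(self):
        # class separation 12 °C >> 8 °C at noise 0.5: >= 99% agreement
        spec = tt.SceneSpec(ta=25.0, sdd_true=0.0, soil_offset=12.0,
                            noise_sd=0.5, seed=11)
        sample = tt.simulate_scene(spec)
        cut = 25.0 + 6.0  # antimode between canopy (25) and soil (37)
        mask = tt.segment_canopy(sample.image, mode="band_threshold",
                                 t_min=TEMP_MIN_C, t_max=cut)
        agreement = np.mean(mask.keep == sample.mask.keep)
        assert agreement >= 0.99


class TestExtractTc:
    def test_uniform_canopy(self, flat_image):
        s = tt.extract_tc(flat_image, ta=20.2)
        assert s.tc == pytest.approx(22.0)
        assert s.sdd == pytest.approx(1.8)
        assert s.n_roi == 900 and s.n_masked == 900 and s.n_retained == 900

    def test_negative_sdd_is_legitimate(self, flat_image):
        s = tt.extract_tc(flat_image, ta=23.7)
        assert s.sdd == pytest.approx(-1.7)

    def test_counts_and_threshold_invariants(self, rng):
        px = rng.normal(26, 1.5, (120, 120)).clip(-19, 69)
        img = tt.ThermalImage(px)
        mask = tt.CanopyMask(rng.random((120, 120)) < 0.7)
        s = tt.extract_tc(img, ta=24.0, mask=mask)
        assert s.n_retained <= s.n_masked <= s.n_roi
        assert s.p_low <= s.tc <= s.p_high
        assert s.sdd == s.tc - s.ta

    def test_permutation_invariance(self, rng):
        px = rng.normal(26, 1.0, (30, 30))
        img = tt.ThermalImage(px)
        shuffled = px.ravel().copy()
        rng.shuffle(shuffled)
        img2 = tt.ThermalImage(shuffled.reshape(30, 30))
        s1 = tt.extract_tc(img, ta=24.0)
        s2 = tt.extract_tc(img2, ta=24.0)
        assert s1.tc == pytest.approx(s2.tc, abs=1e-12)

    def test_sdd_shifts_with_air_temperature(self, rng):
        px = rng.normal(26, 1.0, (40, 40))
        img = tt.ThermalImage(px)
        s1 = tt.extract_tc(img, ta=24.0)
        s2 = tt.extract_tc(img, ta=21.5)  # ta decreases by 2.5
        assert s2.sdd - s1.sdd == pytest.approx(2.5, abs=1e-12)

    def test_all_masked_out_raises(self, flat_image):
        mask = tt.CanopyMask(np.zeros((120, 120), dtype=bool))
        with pytest.raises(tt.EmptyCanopyError):
            tt.extract_tc(flat_image, ta=20.0, mask=mask)

    def test_recovers_true_canopy_mean_on_scenes(self):
        errs = []
        for seed in range(40):
            spec = tt.SceneSpec(ta=25.0, sdd_true=5.0, noise_sd=0.5, seed=seed)
            sample = tt.simulate_scene(spec)
            s = tt.extract_tc(sample.image, ta=spec.ta, mask=sample.mask)
            assert s.n_retained >= 400
            errs.append(abs(s.tc - sample.canopy_mean_true))
        assert np.median(errs) <= 0.1

    def test_matches_explicit_pipeline_oracle(self, rng):
        """ROI -> mask -> sort/interp/filter -> mean, written out longhand."""
        from tests.test_thermal import brute_force_trim
        for _ in range(25):
            h, w = rng.integers(6, 16, 2)
            roi = int(rng.integers(2, min(h, w) + 1))
            px = rng.uniform(10, 40, (h, w))
            keep = rng.random((h, w)) < 0.8
            if not keep[(h - roi) // 2:(h - roi) // 2 + roi,
                        (w - roi) // 2:(w - roi) // 2 + roi].any():
                continue
            img = tt.ThermalImage(px)
            cfg = tt.TrimConfig(roi_size=roi)
            s = tt.extract_tc(img, ta=20.0, mask=tt.CanopyMask(keep), config=cfg)
            r0, c0 = (h - roi) // 2, (w - roi) // 2
            vals = px[r0:r0 + roi, c0:c0 + roi][keep[r0:r0 + roi, c0:c0 + roi]]
            exp_ret, _, _ = brute_force_trim(vals, 1, 97.5)
            assert s.tc == pytest.approx(exp_ret.mean(), abs=1e-12)


class TestIO:
    def test_tiff_and_csv_roundtrip(self, tmp_path, rng):
        import tifffile

        px = rng.uniform(15, 35, (20, 20)).astype(np.float32)
        tifffile.imwrite(tmp_path / "img.tif", px)
        np.savetxt(tmp_path / "img.csv", px, delimiter=",")
        a = tt.read_thermal_image(tmp_path / "img.tif")
        b = tt.read_thermal_image(tmp_path / "img.csv")
        np.testing.assert_allclose(a.pixels, px)
        np.testing.assert_allclose(b.pixels, px, rtol=1e-5)

    def test_mask_csv(self, tmp_path):
        m = np.eye(5, dtype=int)
        np.savetxt(tmp_path / "m.csv", m, delimiter=",", fmt="%d")
        mask = tt.read_mask(tmp_path / "m.csv")
        np.testing.assert_array_equal(mask.keep, m.astype(bool))
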