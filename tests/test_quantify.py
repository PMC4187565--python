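"""Percentage-area arithmetic, ordinal scores, summaries, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibroquant as fq


def make_threshold(value=160.0, mode=100.0, fwhm=40.0):
    return fq.BackgroundThreshold(
        value=value, multiplier=1.5, provenance=fq.BackgroundPeak(mode, fwhm, 1000)
    )


def image_with_above(n_above, shape=(100, 100), hot=3000, cold=100):
    pixels = np.full(shape, cold, dtype=np.int64)
    pixels.ravel()[:n_above] = hot
    return fq.GrayscaleImage(pixels)


class TestMeasureFibrosis:
    def test_no_vessel_mask(self):
        m = fq.measure_fibrosis(image_with_above(500), None, make_threshold())
        assert m.total_pct == 5.0
        assert m.interstitial_pct == 5.0 and m.perivascular_pct == 0.0
        assert m.n_roi == 10000 and m.n_above == 500

    def test_partition_with_vessel_mask(self):
        img = image_with_above(500)
        vmask_arr = np.zeros((100, 100), dtype=bool)
        vmask_arr.ravel()[:200] = True
        vm = fq.VesselMask(vmask_arr, fq.VesselMaskParams(2000, 3, 0.35))
        m = fq.measure_fibrosis(img, None, make_threshold(), vm)
        assert m.interstitial_pct == 3.0 and m.perivascular_pct == 2.0
        assert m.total_pct == 5.0

    def test_all_background(self):
        m = fq.measure_fibrosis(image_with_above(0), None, make_threshold())
        assert m.total_pct == m.interstitial_pct == m.perivascular_pct == 0.0

    def test_pixels_outside_roi_do_not_matter(self):
        thr = make_threshold()
        poly = [(-0.5, -0.5), (49.5, -0.5), (49.5, 99.5), (-0.5, 99.5)]
        roi = fq.rasterize_roi(poly, (100, 100))
        img_a = image_with_above(500)
        pixels_b = img_a.pixels.copy()
        pixels_b[:, 60:] = 4000  # garbage outside the ROI
        m_a = fq.measure_fibrosis(img_a, roi, thr)
        m_b = fq.measure_fibrosis(fq.GrayscaleImage(pixels_b), roi, thr)
        assert m_a.total_pct == m_b.total_pct
        assert m_a.n_roi == m_b.n_roi == 5000

    def test_shape_mismatch_rejected(self):
        roi = fq.rasterize_roi(None, (10, 10))
        with pytest.raises(ValueError):
            fq.measure_fibrosis(image_with_above(0, shape=(20, 20)), roi, make_threshold())

    def test_saturated_pixels_counted_and_flagged(self):
        img = image_with_above(10, hot=4095)
        m = fq.measure_fibrosis(img, None, make_threshold())
        assert m.n_above == 10 and m.n_saturated == 10

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 9999), st.integers(0, 9999))
    def test_partition_identity_exact(self, n_above, n_mask):
        img = image_with_above(n_above)
        vmask_arr = np.zeros((100, 100), dtype=bool)
        vmask_arr.ravel()[:n_mask] = True
        vm = fq.VesselMask(vmask_arr, fq.VesselMaskParams(2000, 3, 0.35))
        m = fq.measure_fibrosis(img, None, make_threshold(), vm)
        assert m.interstitial_pct + m.perivascular_pct == m.total_pct
        assert m.n_above_interstitial + m.n_above_vessel == m.n_above


class TestOrdinalScore:
    @pytest.mark.parametrize(
        "pct,category",
        [(3, 0), (7, 1), (4.999, 0), (5, 1), (10, 2), (25, 3), (49.9, 3),
         (50, 4), (75, 5), (99, 5), (100, 5), (0, 0)],
    )
    def test_band_mapping(self, pct, category):
        score = fq.ordinal_score(pct)
        assert score.category == category
        lo, hi = score.band
        assert lo <= pct <= hi

    def test_out_of_range_rejected(self):
        for pct in (-1, 101):
            with pytest.raises(ValueError):
                fq.ordinal_score(pct)

    def test_bands_partition_zero_to_hundred(self):
        grid = np.linspace(0, 100, 2001)
        cats = [fq.ordinal_score(p).category for p in grid]
        assert set(cats) == {0, 1, 2, 3, 4, 5}
        assert cats == sorted(cats)  # monotone in severity


class TestFieldSummary:
    def test_constant_fields(self):
        s = fq.field_summary([2, 2, 2, 2])
        assert s.mean == 2.0 and s.sem == 0.0 and s.n_fields == 4

    def test_closed_form_sem(self):
        s = fq.field_summary([1, 2, 3])
        assert s.mean == 2.0
        assert s.sem == pytest.approx(1 / np.sqrt(3))

    def test_single_field_sem_zero(self):
        assert fq.field_summary([7.5]).sem == 0.0

    def test_twenty_fields_match_independent_arithmetic(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(1, 20, size=20)
        s = fq.field_summary(values)
        # independent spreadsheet-style arithmetic
        mean = sum(values) / 20
        var = sum((v - mean) ** 2 for v in values) / 19
        assert s.mean == pytest.approx(mean)
        assert s.sem == pytest.approx((var**0.5) / (20**0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fq.field_summary([])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(1.0, 11.0)
        assert fq.pearson_r(x, x).r == pytest.approx(1.0)
        assert fq.pearson_r(x, -2 * x + 7).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = fq.pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.n == 4

    def test_p_value_uses_t_reference(self):
        # r = 0.8, n = 4 -> t = 0.8 * sqrt(2 / 0.36), df = 2
        from scipy import stats

        res = fq.pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert res.p_value == pytest.approx(2 * stats.t.sf(t, df=2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fq.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fq.pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fq.pearson_r([1, 2, 3], [1, 2])


class TestRunPipeline:
    def test_bit_identical_repeat_runs(self):
        img, _ = fq.generate_field(fq.SceneSpec(shape=(128, 128), fibril_count=20, seed=4))
        cfg = fq.PipelineConfig()
        m1 = fq.run_pipeline(img, config=cfg)
        m2 = fq.run_pipeline(img, config=cfg)
        assert m1 == m2

    def test_ground_truth_recovery_at_ten_percent(self):
        target_count = 120  # ~10% of a 256x256 field at default fibril size
        img, truth = fq.generate_field(fq.SceneSpec(fibril_count=target_count, seed=5))
        m = fq.run_pipeline(img)
        assert truth.true_interstitial_fraction * 100 == pytest.approx(10, abs=2)
        assert m.interstitial_pct == pytest.approx(
            truth.true_interstitial_fraction * 100, abs=0.5
        )

    def test_pure_background_measures_nearly_zero(self):
        img, _ = fq.generate_field(fq.SceneSpec(fibril_count=0, seed=6))
        assert fq.run_pipeline(img).total_pct < 0.1

    def test_high_threshold_must_exceed_background_threshold(self):
        img, _ = fq.generate_field(fq.SceneSpec(shape=(64, 64), fibril_count=0, seed=1))
        cfg = fq.PipelineConfig(high_threshold=10.0)
        with pytest.raises(ValueError, match="high_threshold"):
            fq.run_pipeline(img, config=cfg)

    def test_measurement_carries_fingerprint_and_id(self):
        img, _ = fq.generate_field(fq.SceneSpec(shape=(64, 64), fibril_count=3, seed=2))
        cfg = fq.PipelineConfig()
        m = fq.run_pipeline(img, config=cfg, image_id="x")
        assert m.image_id == "x"
        assert m.config_fingerprint == cfg.fingerprint()
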