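import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adctrack import (
    ADCMap,
    ROIMask,
    compute_volume,
    extract_values,
    split_components,
    subtract_rois,
    summarize_histogram,
)
from helpers_oracle import (
    oracle_kurtosis,
    oracle_mean,
    oracle_median,
    oracle_percentile,
    oracle_sd,
    oracle_skewness,
)

SPACING = (2.0, 2.0, 5.0)
SHAPE = (10, 10, 4)


def mask_with_n(n, label="gtv", shape=SHAPE, spacing=SPACING, offset=0):
    m = np.zeros(shape, dtype=bool)
    m.flat[offset : offset + n] = True
    return ROIMask(m, label, spacing)


class TestSubtractRois:
    def test_full_containment(self):
        gtv = mask_with_n(100)
        cystic = mask_with_n(30, "cystic_necrotic")
        viable = subtract_rois(gtv, cystic)
        assert viable.label == "viable"
        assert viable.n_voxels == 70

    def test_empty_cystic_is_identity(self):
        gtv = mask_with_n(100)
        cystic = mask_with_n(0, "cystic_necrotic")
        viable = subtract_rois(gtv, cystic)
        np.testing.assert_array_equal(viable.mask, gtv.mask)

    def test_cystic_partially_outside_warns(self, caplog):
        gtv = mask_with_n(100)
        cystic = mask_with_n(30, "cystic_necrotic", offset=80)  # 10 voxels outside
        with caplog.at_level(logging.WARNING, logger="adctrack.roi"):
            viable = subtract_rois(gtv, cystic)
        assert viable.n_voxels == 80
        assert "10" in caplog.text

    def test_grid_mismatch_raises(self):
        gtv = mask_with_n(10)
        cystic = ROIMask(np.zeros((5, 5, 5), bool), "cystic_necrotic", SPACING)
        with pytest.raises(ValueError, match="grid"):
            subtract_rois(gtv, cystic)

    def test_empty_viable_raises_naming_gtv(self):
        gtv = mask_with_n(30)
        gtv.name = "node-3"
        cystic = mask_with_n(30, "cystic_necrotic")
        with pytest.raises(ValueError, match="node-3"):
            subtract_rois(gtv, cystic)

    def test_volume_additivity_and_disjointness_random_masks(self, rng):
        for _ in range(25):
            g = rng.random(SHAPE) < 0.4
            c = rng.random(SHAPE) < 0.2
            g.flat[0] = True
            c.flat[0] = False  # keep viable non-empty
            gtv = ROIMask(g, "gtv", SPACING)
            cystic = ROIMask(c, "cystic_necrotic", SPACING)
            viable = subtract_rois(gtv, cystic)
            inter = ROIMask(g & c, "cystic_necrotic", SPACING)
            assert not (viable.mask & cystic.mask).any()
            assert (viable.mask & ~gtv.mask).sum() == 0
            # additivity is exact in voxel counts, hence in volume
            assert gtv.n_voxels == viable.n_voxels + inter.n_voxels
            assert compute_volume(gtv) == pytest.approx(
                compute_volume(viable) + compute_volume(inter), rel=1e-12
            )


class TestComputeVolume:
    def test_thousand_voxels(self):
        assert compute_volume(mask_with_n(100)) == pytest.approx(100 * 20.0 / 1000.0)

    def test_single_unit_voxel(self):
        m = ROIMask(np.ones((1, 1, 1), bool), "gtv", (1.0, 1.0, 1.0))
        assert compute_volume(m) == pytest.approx(0.001)

    def test_empty_mask_is_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="adctrack.roi"):
            v = compute_volume(mask_with_n(0))
        assert v == 0.0
        assert "empty" in caplog.text


class TestExtractValues:
    def adc_map(self, values, valid=None):
        valid = np.ones(values.shape, bool) if valid is None else valid
        return ADCMap(values, valid, SPACING)

    def test_count_conservation(self, rng):
        amap = self.adc_map(rng.random(SHAPE))
        roi = mask_with_n(70)
        assert extract_values(amap, roi).size == 70

    def test_invalid_voxels_excluded(self, rng):
        values = rng.random(SHAPE)
        valid = np.ones(SHAPE, bool)
        valid.flat[:5] = False
        values[~valid] = np.nan
        roi = mask_with_n(70)
        assert extract_values(self.adc_map(values, valid), roi).size == 65

    def test_constant_map(self):
        amap = self.adc_map(np.full(SHAPE, 1.3e-3))
        out = extract_values(amap, mask_with_n(40))
        np.testing.assert_array_equal(out, 1.3e-3)

    def test_lexicographic_order(self):
        values = np.arange(np.prod(SHAPE), dtype=float).reshape(SHAPE)
        roi = mask_with_n(10, offset=17)
        np.testing.assert_array_equal(
            extract_values(self.adc_map(values), roi), np.arange(17.0, 27.0)
        )

    def test_all_invalid_raises(self):
        values = np.full(SHAPE, np.nan)
        amap = self.adc_map(values, np.zeros(SHAPE, bool))
        with pytest.raises(ValueError, match="valid"):
            extract_values(amap, mask_with_n(10))

    def test_empty_roi_raises(self):
        amap = self.adc_map(np.zeros(SHAPE))
        with pytest.raises(ValueError, match="empty"):
            extract_values(amap, mask_with_n(0))


class TestSummarizeHistogram:
    def test_five_element_example(self):
        s = summarize_histogram([1.0, 2.0, 3.0, 4.0, 5.0])
        assert s.mean == 3.0
        assert s.median == 3.0
        assert s.p25 == 2.0
        assert s.p75 == 4.0

    def test_constant_list_flags_shape_undefined(self):
        s = summarize_histogram([2.0] * 10)
        assert s.sd == 0.0
        assert math.isnan(s.skewness) and math.isnan(s.kurtosis)
        assert not s.shape_defined

    def test_single_value(self):
        s = summarize_histogram([1.5])
        assert s.n_voxels == 1
        assert s.sd == 0.0
        assert not s.shape_defined

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_histogram([])

    def test_normal_sample_near_zero_shape(self):
        # excess-kurtosis convention: Gaussian -> skewness 0, kurtosis 0
        rng = np.random.default_rng(0)
        n = 100_000
        s = summarize_histogram(rng.normal(0.0, 1.0, n))
        se_skew = math.sqrt(6.0 / n)
        se_kurt = math.sqrt(24.0 / n)
        assert abs(s.skewness) < 3 * se_skew
        assert abs(s.kurtosis) < 3 * se_kurt

    def test_percentile_ordering_invariant(self, rng):
        for _ in range(20):
            s = summarize_histogram(rng.lognormal(0, 0.5, rng.integers(3, 500)))
            assert s.p10 <= s.p25 <= s.median <= s.p75 <= s.p90
            assert s.sd >= 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            xs = rng.uniform(0.5e-3, 3e-3, size=int(rng.integers(3, 2000))).tolist()
            s = summarize_histogram(xs)
            assert s.mean == pytest.approx(oracle_mean(xs), rel=1e-10)
            assert s.median == pytest.approx(oracle_median(xs), rel=1e-10)
            assert s.sd == pytest.approx(oracle_sd(xs), rel=1e-10)
            for attr, q in (("p10", 10), ("p25", 25), ("p75", 75), ("p90", 90)):
                assert getattr(s, attr) == pytest.approx(
                    oracle_percentile(xs, q), rel=1e-10
                )
            assert s.skewness == pytest.approx(oracle_skewness(xs), rel=1e-8, abs=1e-10)
            assert s.kurtosis == pytest.approx(oracle_kurtosis(xs), rel=1e-8, abs=1e-10)

    @given(
        st.lists(
            st.floats(min_value=1e-4, max_value=5e-3, allow_nan=False),
            min_size=3,
            max_size=200,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_property_oracle_equivalence(self, xs):
        s = summarize_histogram(xs)
        assert s.mean == pytest.approx(oracle_mean(xs), rel=1e-9)
        assert s.median == pytest.approx(oracle_median(xs), rel=1e-9)
        assert s.p10 <= s.p25 <= s.median <= s.p75 <= s.p90


class TestSplitComponents:
    @staticmethod
    def mixture_sample(rng, n=5000, w=0.7, m1=1.1e-3, m2=2.4e-3, s1=0.15e-3, s2=0.3e-3):
        n1 = int(round(w * n))
        return np.concatenate(
            [rng.normal(m1, s1, n1), rng.normal(m2, s2, n - n1)]
        )

    def test_bimodal_mixture_detected_and_means_recovered(self):
        rng = np.random.default_rng(2)
        x = self.mixture_sample(rng)
        split = split_components(x, seed=0)
        assert split.bimodal
        assert abs(split.means[0] - 1.1e-3) < 0.05e-3
        assert abs(split.means[1] - 2.4e-3) < 0.05e-3
        assert split.weights[0] + split.weights[1] == pytest.approx(1.0)
        assert split.means[0] < split.means[1]

    def test_unimodal_sample_not_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.2e-3, 0.2e-3, 5000)
        split = split_components(x, seed=0)
        assert not split.bimodal

    def test_identical_components_unimodal(self):
        rng = np.random.default_rng(4)
        x = self.mixture_sample(rng, m1=1.2e-3, m2=1.2e-3, s1=0.2e-3, s2=0.2e-3)
        assert not split_components(x, seed=0).bimodal

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = self.mixture_sample(rng)
        a = split_components(x, seed=1)
        b = split_components(x, seed=1)
        assert a.means == b.means and a.bimodal == b.bimodal
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="manual"):
            split_components(np.ones(49), seed=0)

    def test_assignments_track_components(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(1.0e-3, 0.1e-3, 500), rng.normal(2.5e-3, 0.1e-3, 500)])
        split = split_components(x, seed=0)
        # low-mean component is index 0 after ordering
        assert split.assignments[:500].mean() < 0.1
        assert split.assignments[500:].mean() > 0.9
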