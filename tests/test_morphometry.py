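"""Per-nucleus shape descriptors and the ROI/case parameter suite."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleomorph.core_io import Calibration
from nucleomorph.morphometry import (
    MorphometryConfig,
    NucleusFeatures,
    case_morphometry,
    invert_mean_solidity,
    nucleus_features,
    roi_morphometry,
)
from tests.conftest import disk_mask, ellipse_mask


def feats_from_areas(areas, ecc=0.5, sol=0.97):
    return [
        NucleusFeatures(area=float(a), eccentricity=ecc, solidity=sol, centroid=(0, 0), id=i)
        for i, a in enumerate(areas)
    ]


def brute_force_stats(areas, config=MorphometryConfig()):
    """Aggregate statistics recomputed from first principles."""
    xs = sorted(float(a) for a in areas)
    n = len(xs)
    mean = sum(xs) / n
    median = (xs[(n - 1) // 2] + xs[n // 2]) / 2
    sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1)) if n >= 2 else None
    # linear-interpolation p90 between order statistics
    pos = 0.9 * (n - 1)
    lo, frac = int(math.floor(pos)), pos - math.floor(pos)
    p90 = xs[lo] if lo == n - 1 else xs[lo] * (1 - frac) + xs[lo + 1] * frac
    k = math.ceil(config.top_fraction * n)
    top = sum(xs[-k:]) / k
    pct_large = {
        t: 100.0 * sum(x > t for x in xs) / n for t in config.large_nucleus_thresholds_um2
    }
    skew = None
    if n >= 3 and sd and sd > 0:
        m3 = sum((x - mean) ** 3 for x in xs) / n
        m2 = sum((x - mean) ** 2 for x in xs) / n
        g1 = m3 / m2**1.5
        skew = g1 * math.sqrt(n * (n - 1)) / (n - 2)
    return dict(mean=mean, median=median, sd=sd, p90=p90, top=top,
                pct_large=pct_large, skew=skew)


class TestNucleusFeatures:
    def test_digital_disk_is_round_and_solid(self, calibration):
        f = nucleus_features(disk_mask(40), calibration)
        assert abs(f.eccentricity) < 0.05
        assert f.solidity >= 0.98

    def test_ellipse_area_and_eccentricity_match_analytic_values(self):
        # semi-axes 5 µm and 3 µm at 0.05 µm/px: area πab = 47.12 µm²,
        # eccentricity sqrt(1 - 9/25) = 0.8
        cal = Calibration(0.05)
        f = nucleus_features(ellipse_mask(5 / 0.05, 3 / 0.05), cal)
        assert f.area == pytest.approx(math.pi * 15.0, rel=0.01)
        assert f.eccentricity == pytest.approx(0.8, abs=0.02)

    def test_convex_instance_has_solidity_one(self, calibration):
        square = np.ones((12, 12), dtype=np.uint8)
        assert nucleus_features(square, calibration).solidity == 1.0

    def test_single_pixel_degenerates_cleanly(self, calibration):
        one = np.zeros((3, 3), dtype=np.uint8)
        one[1, 1] = 1
        f = nucleus_features(one, calibration)
        assert f.eccentricity == 0.0 and f.solidity == 1.0

    def test_empty_pixel_set_rejected(self, calibration):
        with pytest.raises(ValueError):
            nucleus_features(np.zeros((3, 3), dtype=np.uint8), calibration)

    def test_scale_equivariance(self):
        patch = ellipse_mask(20, 12)
        f1 = nucleus_features(patch, Calibration(0.25))
        f2 = nucleus_features(patch, Calibration(0.5))
        assert f2.area == pytest.approx(4 * f1.area)
        assert f2.eccentricity == f1.eccentricity
        assert f2.solidity == f1.solidity


class TestROIMorphometry:
    def test_pct_large_strict_above(self):
        roi = roi_morphometry(feats_from_areas([30, 40, 60]))
        assert roi.pct_large[50.3] == pytest.approx(100 / 3)
        assert roi.pct_large[37.8] == pytest.approx(200 / 3)

    def test_degenerate_equal_areas(self):
        roi = roi_morphometry(feats_from_areas([20.0] * 5))
        assert roi.area_sd == 0.0
        assert roi.area_p90_over_median == pytest.approx(1.0)
        assert roi.area_skewness is None  # zero SD -> undefined, not 0

    def test_top10_of_ten_values_is_single_largest(self):
        roi = roi_morphometry(feats_from_areas(range(10, 30, 2)))
        assert roi.area_mean_top10 == 28.0
        oracle = brute_force_stats(range(10, 30, 2))
        assert roi.area_p90 == pytest.approx(oracle["p90"])

    def test_single_nucleus_statistics_flagged_missing(self):
        roi = roi_morphometry(feats_from_areas([25.0]))
        assert roi.n_nuclei == 1
        assert roi.area_sd is None and roi.area_skewness is None

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_morphometry([])

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregates_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        areas = rng.lognormal(3.2, 0.4, size=rng.integers(3, 200))
        roi = roi_morphometry(feats_from_areas(areas))
        oracle = brute_force_stats(areas)
        assert roi.area_mean == pytest.approx(oracle["mean"], rel=1e-9)
        assert roi.area_median == pytest.approx(oracle["median"], rel=1e-9)
        assert roi.area_sd == pytest.approx(oracle["sd"], rel=1e-9)
        assert roi.area_p90 == pytest.approx(oracle["p90"], rel=1e-9)
        assert roi.area_mean_top10 == pytest.approx(oracle["top"], rel=1e-9)
        assert roi.area_skewness == pytest.approx(oracle["skew"], rel=1e-9)
        for t, v in oracle["pct_large"].items():
            assert roi.pct_large[t] == pytest.approx(v, rel=1e-9)

    def test_pct_large_monotone_in_threshold(self, rng):
        areas = rng.lognormal(3.2, 0.5, size=100)
        cfg = MorphometryConfig(large_nucleus_thresholds_um2=(20.0, 30.0, 40.0, 50.0))
        roi = roi_morphometry(feats_from_areas(areas), cfg)
        vals = [roi.pct_large[t] for t in (20.0, 30.0, 40.0, 50.0)]
        assert vals == sorted(vals, reverse=True)

    def test_p90_over_median_at_least_one_for_right_skewed(self, rng):
        areas = rng.lognormal(3.0, 0.6, size=500)
        roi = roi_morphometry(feats_from_areas(areas))
        assert roi.area_p90_over_median >= 1.0

    def test_pct_indented_strict_below(self):
        feats = [
            NucleusFeatures(area=20, eccentricity=0.5, solidity=s, centroid=(0, 0))
            for s in [0.90, 0.913, 0.95]
        ]
        roi = roi_morphometry(feats)
        # 0.913 itself is not "< 0.913"
        assert roi.pct_indented[0.913] == pytest.approx(100 / 3)
        assert roi.pct_indented[0.943] == pytest.approx(200 / 3)


class TestCaseLevel:
    def test_invert_mean_solidity(self):
        rois = [{"sol_mean": 0.95}, {"sol_mean": 0.97}, {"sol_mean": 0.96}]
        assert invert_mean_solidity(rois) == pytest.approx(0.04)
        assert invert_mean_solidity([{"sol_mean": 1.0}]) == 0.0
        assert invert_mean_solidity([{"sol_mean": 0.9}]) == pytest.approx(0.1)

    def test_case_average_is_unweighted(self):
        rois = [{"area_sd": 8.0}, {"area_sd": 10.0}]
        assert case_morphometry(rois)["area_sd"] == 9.0

    def test_single_roi_identity(self):
        roi = {"area_sd": 7.5, "area_mean": 25.0}
        assert case_morphometry([roi]) == roi

    def test_five_rois_percentage_average(self):
        rois = [{"pct": 0.0}] * 4 + [{"pct": 100.0}]
        assert case_morphometry(rois)["pct"] == 20.0

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            case_morphometry([{"a": 1.0}, {"b": 2.0}])

    def test_missing_parameter_propagates(self):
        assert case_morphometry([{"a": 1.0}, {"a": None}])["a"] is None


class TestParameterCorrelations:
    def test_self_and_inverse_correlation(self, rng):
        from nucleomorph.morphometry import parameter_correlations

        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "also_x": x, "neg_x": -x})
        corr = parameter_correlations(df)
        assert corr.loc["x", "also_x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg_x"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_recovers_generating_correlation(self, rng):
        from nucleomorph.morphometry import parameter_correlations

        cov = [[1.0, 0.9], [0.9, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        corr = parameter_correlations(pd.DataFrame(xy, columns=["a", "b"]))
        assert corr.loc["a", "b"] == pytest.approx(0.9, abs=0.02)

    def test_zero_variance_column_missing(self, rng):
        from nucleomorph.morphometry import parameter_correlations

        df = pd.DataFrame({"x": rng.normal(size=10), "const": np.ones(10)})
        assert np.isnan(parameter_correlations(df).loc["x", "const"])

    def test_too_few_cases_rejected(self):
        from nucleomorph.morphometry import parameter_correlations

        with pytest.raises(ValueError):
            parameter_correlations(pd.DataFrame({"x": [1, 2]}))
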