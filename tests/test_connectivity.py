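"""Connectivity estimation: preprocessing, Pearson screening, COI selection,
Scott binning, and the XMI estimator against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xmiconnect as xc
from xmiconnect import DegenerateInputError, SpecValidationError
from xmiconnect.connectivity import CorrelationMatrix
from xmiconnect.synthetic import RegionalTimeSeries


def plugin_histogram_mi(x, y, nc, nr):
    """Independent plug-in mutual-information oracle: raw 2-D histogram,
    explicit double loop, natural log, zero cells skipped."""
    hist, _, _ = np.histogram2d(x, y, bins=[nc, nr])
    p = hist / hist.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    m = 0.0
    for k in range(nc):
        for l in range(nr):
            if p[k, l] > 0:
                m += p[k, l] * math.log(p[k, l] / (px[k] * py[l]))
    return m


def _ts(signal, pid="P1", run=0):
    return RegionalTimeSeries(pid, run, np.asarray(signal, dtype=float))


class TestPreprocess:
    def test_linear_ramp_flagged_degenerate(self):
        ts = _ts(np.vstack([np.linspace(0, 5, 50), np.random.default_rng(0).normal(size=50)]))
        with pytest.raises(DegenerateInputError, match=r"\[0\]"):
            xc.preprocess_series(ts)

    def test_outlier_clipped_to_threshold(self):
        rng = np.random.default_rng(1)
        row = rng.normal(0, 1, 200)
        row[13] = 10 * row.std() * 10  # gross outlier
        clean = xc.preprocess_series(_ts(row[None, :]), clip_z=3.0)
        assert clean.signal.max() == pytest.approx(3.0)
        assert np.all(np.abs(clean.signal) <= 3.0)

    def test_zero_mean_unit_sd_before_clipping(self):
        rng = np.random.default_rng(2)
        row = rng.uniform(-1, 1, 300)  # bounded, so no values clip at z=3
        clean = xc.preprocess_series(_ts(row[None, :]))
        assert abs(clean.signal.mean()) < 1e-9
        assert clean.signal.std() == pytest.approx(1.0, abs=1e-9)

    def test_trend_removed(self):
        rng = np.random.default_rng(3)
        row = rng.normal(0, 1, 200) + np.linspace(0, 8, 200)
        clean = xc.preprocess_series(_ts(row[None, :]), clip_z=100.0)
        t = np.arange(200)
        slope = np.polyfit(t, clean.signal[0], 1)[0]
        assert abs(slope) < 1e-9


class TestCorrelationMatrix:
    def test_identical_and_negated_rows(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 100)
        mat = xc.correlation_matrix(_ts(np.vstack([base, base, -base])))
        assert mat.values[0, 1] == pytest.approx(1.0)
        assert mat.values[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)

    def test_independent_rows_near_zero(self):
        rng = np.random.default_rng(5)
        mat = xc.correlation_matrix(_ts(rng.normal(size=(2, 1000))))
        assert abs(mat.values[0, 1]) < 0.1

    def test_too_few_timepoints(self):
        with pytest.raises(DegenerateInputError):
            xc.correlation_matrix(_ts([[1.0, 2.0], [2.0, 1.0]]))


def _matrices_with_dominant_pair(hot_matrices, n=5, n_total=4):
    """n x n correlation matrices where pair (0,1) is the single largest
    off-diagonal value in ``hot_matrices`` of the 4, and a decoy pair (2,3)
    dominates the rest."""
    rng = np.random.default_rng(6)
    out = []
    for m in range(n_total):
        base = rng.uniform(-0.2, 0.2, size=(n, n))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 1.0)
        hot = (0, 1) if m < hot_matrices else (2, 3)
        vals[hot] = vals[hot[::-1]] = 0.95
        out.append(CorrelationMatrix("P1", m, vals))
    return out


class TestSelectCois:
    def test_pair_in_enough_matrices_included(self):
        # top_frac 0.1 of 10 pairs -> 1 marked per matrix; 2/4 = 0.5 >= 0.3
        cois = xc.select_cois(_matrices_with_dominant_pair(2), top_frac=0.1)
        assert (0, 1) in cois

    def test_pair_in_too_few_matrices_excluded(self):
        # 1/4 = 0.25 < 0.3
        cois = xc.select_cois(_matrices_with_dominant_pair(1), top_frac=0.1)
        assert (0, 1) not in cois
        assert (2, 3) in cois

    def test_min_prop_zero_gives_union_and_top_frac_one_all_pairs(self):
        mats = _matrices_with_dominant_pair(2)
        union = xc.select_cois(mats, top_frac=0.1, min_prop=0.0)
        assert {(0, 1), (2, 3)} <= set(union)
        everything = xc.select_cois(mats, top_frac=1.0, min_prop=1.0)
        assert len(everything) == 5 * 4 // 2

    def test_min_prop_monotone(self):
        rng = np.random.default_rng(7)
        mats = []
        for m in range(6):
            a = rng.normal(size=(8, 8))
            vals = np.corrcoef(a)
            mats.append(CorrelationMatrix("P1", m, vals))
        previous = None
        for prop in (0.9, 0.6, 0.3, 0.0):
            cois = set(xc.select_cois(mats, top_frac=0.2, min_prop=prop))
            if previous is not None:
                assert previous <= cois
            previous = cois

    def test_lexicographic_order_and_uniqueness(self):
        cois = xc.select_cois(_matrices_with_dominant_pair(4), top_frac=0.3)
        assert cois == sorted(set(cois))

    def test_inconsistent_dimensions(self):
        mats = _matrices_with_dominant_pair(2)
        small = CorrelationMatrix("P1", 9, np.eye(3))
        with pytest.raises(SpecValidationError, match="dimension"):
            xc.select_cois(mats + [small])


class TestScottBins:
    def test_formula_on_random_samples(self):
        rng = np.random.default_rng(8)
        for n in (8, 50, 154, 1000):
            x = rng.normal(0, 1, n)
            expected = max(
                2,
                int(np.floor(np.ptp(x) / (3.5 * x.std(ddof=1) * n ** (-1 / 3)) + 0.5)),
            )
            assert xc.scott_bins(x) == expected

    @staticmethod
    def _vector_with_unit_sd_range_35(n):
        """min 0, max 3.5, remaining values in symmetric pairs 1.75 +- d with
        d solved so the sample SD is exactly 1."""
        n_pairs = (n - 2) // 2
        d = math.sqrt((n - 1 - 2 * 1.75**2) / (2 * n_pairs))
        assert d <= 1.75  # stays inside [0, 3.5], so the range holds
        vals = [0.0, 3.5] + [1.75 - d, 1.75 + d] * n_pairs
        x = np.asarray(vals)
        assert x.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert np.ptp(x) == 3.5
        return x

    def test_ratio_examples(self):
        # range 3.5, s = 1, n = 1000 -> 3.5/(3.5 * 1000^(-1/3)) = 10 bins
        assert xc.scott_bins(self._vector_with_unit_sd_range_35(1000)) == 10
        # range 3.5, s = 1, n = 8 -> 8^(1/3) = 2 bins
        assert xc.scott_bins(self._vector_with_unit_sd_range_35(8)) == 2

    def test_floor_at_two(self):
        x = np.array([0.0, 1.0] * 4)
        assert xc.scott_bins(x) == 2

    def test_constant_vector_errors(self):
        with pytest.raises(DegenerateInputError):
            xc.scott_bins(np.ones(10))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=200))
    def test_always_at_least_two_bins(self, values):
        x = np.asarray(values)
        if np.ptp(x) == 0 or x.std(ddof=1) <= 0:  # constant or SD underflow
            with pytest.raises(DegenerateInputError):
                xc.scott_bins(x)
        else:
            assert xc.scott_bins(x) >= 2


class TestXmi:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(10)
        vals = [
            xc.xmi(rng.normal(size=1000), rng.normal(size=1000)) for _ in range(20)
        ]
        assert np.mean(vals) < 0.05

    def test_self_dependency_maximal(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        assert xc.xmi(x, x) > xc.xmi(x, y)

    def test_plugin_oracle_equivalence_unsmoothed(self):
        """With smoothing disabled the estimator equals the brute-force
        plug-in histogram MI on identical bins, exactly."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(50, 500))
            rho = rng.uniform(-0.9, 0.9)
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            x, y = z[:, 0], z[:, 1]
            nc, nr = xc.scott_bins(x), xc.scott_bins(y)
            expected = plugin_histogram_mi(x, y, nc, nr)
            got = xc.xmi(x, y, bandwidth=0.0, normalized=False)
            assert abs(got - expected) < 1e-9

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(size=300)
        assert xc.xmi(x, y) == pytest.approx(xc.xmi(y, x), abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            x = rng.normal(size=200)
            y = rng.normal(size=200) + rng.uniform(0, 1) * x
            v = xc.xmi(x, y)
            assert 0.0 <= v <= 1.0

    def test_monotone_in_coupling(self):
        """Mean XMI rises with latent-factor coupling c in {0, 0.3, 0.6, 0.9}."""
        rng = np.random.default_rng(15)
        means = []
        for c in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for _ in range(20):
                latent = rng.standard_normal(154)
                x = np.sqrt(1 - c**2) * rng.standard_normal(154) + c * latent
                y = np.sqrt(1 - c**2) * rng.standard_normal(154) + c * latent
                vals.append(xc.xmi(x, y))
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_errors(self):
        x = np.arange(100, dtype=float)
        with pytest.raises(SpecValidationError, match="mismatch"):
            xc.xmi(x, x[:-1])
        with pytest.raises(DegenerateInputError):
            xc.xmi(np.ones(100), x)


class TestMedianSplit:
    def test_examples(self):
        np.testing.assert_array_equal(
            xc.median_split([10, 20, 30, 40]), [0, 0, 1, 1]
        )
        np.testing.assert_array_equal(xc.median_split([1, 2, 2, 3]), [0, 0, 0, 1])

    def test_single_value_errors(self):
        with pytest.raises(DegenerateInputError):
            xc.median_split([5.0])
        with pytest.raises(DegenerateInputError):
            xc.median_split([2.0, 2.0, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=100
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_split_is_binary_and_high_means_above_median(self, values):
        out = xc.median_split(values)
        med = np.median(values)
        assert set(out.tolist()) <= {0, 1}
        np.testing.assert_array_equal(out, np.asarray(values) > med)


class TestBuildDataset:
    @staticmethod
    def _labels(pids):
        return pd.DataFrame(
            {
                "participant_id": pids,
                "diagnosis": [0, 1][: len(pids)],
                "igt_score": range(len(pids)),
                "igt_class": [0, 1][: len(pids)],
            }
        )

    def test_shape_two_participants_three_cois(self):
        rng = np.random.default_rng(16)
        series = [
            RegionalTimeSeries(pid, 0, rng.normal(size=(5, 64))) for pid in ("A", "B")
        ]
        ds = xc.build_connectivity_dataset(
            series, [(0, 1), (1, 2), (3, 4)], self._labels(["A", "B"])
        )
        assert ds.features.shape == (2, 3)
        assert ds.feature_names == ["0-1", "1-2", "3-4"]

    def test_missing_label_named(self):
        rng = np.random.default_rng(17)
        series = [RegionalTimeSeries("ZZZ", 0, rng.normal(size=(4, 64)))]
        with pytest.raises(SpecValidationError, match="ZZZ"):
            xc.build_connectivity_dataset(series, [(0, 1)], self._labels(["A"]))

    def test_degenerate_series_not_swallowed(self):
        series = [RegionalTimeSeries("A", 0, np.ones((4, 64)))]
        with pytest.raises(DegenerateInputError):
            xc.build_connectivity_dataset(
                series, [(0, 1)], self._labels(["A", "B"])
            )

    def test_empty_cois_rejected(self):
        with pytest.raises(SpecValidationError, match="empty"):
            xc.build_connectivity_dataset([], [], self._labels(["A"]))

    def test_study_scale_row_count(self, recovery_dataset):
        # 40 participants x 4 runs -> 160 tagged vectors, one per run
        assert recovery_dataset.n_vectors == 160
        assert recovery_dataset.tags.groupby("participant_id").size().eq(4).all()


class TestConnectivityExtractor:
    def test_transformer_matches_functional_route(self, tiny_cohort):
        _, series, labels, _ = tiny_cohort
        ext = xc.ConnectivityExtractor().fit(series)
        X = ext.transform(series[:4])
        clean = [xc.preprocess_series(ts) for ts in series]
        mats = [xc.correlation_matrix(ts) for ts in clean]
        cois = xc.select_cois(mats)
        assert ext.cois_ == cois
        ds = xc.build_connectivity_dataset(clean[:4], cois, labels, preprocessed=True)
        np.testing.assert_allclose(X, ds.features, atol=1e-12)

    def test_sklearn_param_interface(self):
        ext = xc.ConnectivityExtractor(top_frac=0.1)
        assert ext.get_params()["top_frac"] == 0.1
        ext.set_params(min_prop=0.5)
        assert ext.min_prop == 0.5
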