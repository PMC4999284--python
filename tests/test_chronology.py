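"""Chronology construction: detrending cascade, biweight robustness,
rbar/EPS statistics, variance stabilization, and calibration."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import popforce as pf
from popforce.chronology import eps_table


class TestDetrend:
    def test_exact_negexp_self_fit(self):
        t = np.arange(80, dtype=float)
        widths = 2.0 * np.exp(-0.05 * t) + 0.1
        d = pf.detrend_series(widths, 1900 + t.astype(int))
        assert d.curve_kind == "negexp"
        np.testing.assert_allclose(d.index, 1.0, atol=1e-6)

    def test_constant_series_mean_fallback(self):
        d = pf.detrend_series(np.full(40, 1.5), np.arange(1900, 1940))
        assert d.curve_kind == "mean"
        np.testing.assert_allclose(d.index, 1.0, atol=1e-12)

    def test_linear_decline_uses_linear_fallback_or_better(self):
        t = np.arange(60, dtype=float)
        widths = 3.0 - 0.02 * t
        d = pf.detrend_series(widths, 1900 + t.astype(int))
        # either curve family may win, but the trend must be removed
        assert d.curve_kind in ("negexp", "linear")
        np.testing.assert_allclose(d.index.mean(), 1.0, atol=0.01)
        # residual trend in the index is < 3% of the removed one
        assert abs(np.polyfit(t, d.index / d.index.mean(), 1)[0]) < 2e-4

    def test_preserves_length_and_mean_near_one(self, noisy_tree_set):
        for sid, fy, widths in noisy_tree_set:
            d = pf.detrend_series(widths, np.arange(fy, fy + widths.size), sid)
            assert len(d) == widths.size
            assert d.index.mean() == pytest.approx(1.0, abs=0.15)

    def test_signal_recovery_at_low_noise(self, ring_signal):
        ts = pf.gen_tree_ring_set(10, 120, ring_signal, noise_sd=0.1, seed=21)
        cors = []
        for sid, fy, widths in ts:
            d = pf.detrend_series(widths, np.arange(fy, fy + widths.size), sid)
            sig = ring_signal.window(fy, widths.size)
            cors.append(np.corrcoef(d.index, sig)[0, 1])
        assert np.mean(cors) > 0.9

    def test_too_short_series_rejected(self):
        with pytest.raises(pf.ChronologyError):
            pf.detrend_series(np.ones(5), np.arange(1900, 1905))

    def test_all_zero_series_rejected(self):
        with pytest.raises(pf.ChronologyError):
            pf.detrend_series(np.zeros(20), np.arange(1900, 1920))


class TestBiweightMean:
    def test_constant_values(self):
        assert pf.biweight_mean([5.0, 5.0, 5.0]) == 5.0

    def test_symmetric_values(self):
        assert pf.biweight_mean([1.0, 2.0, 3.0]) == pytest.approx(2.0, abs=1e-8)

    def test_downweights_outlier(self):
        m = pf.biweight_mean([1.0, 2.0, 3.0, 100.0])
        assert 1.8 <= m <= 2.2
        assert abs(m - 2.0) < abs(np.mean([1, 2, 3, 100]) - 2.0)

    def test_matches_mean_for_clean_symmetric_data(self):
        rng = np.random.default_rng(3)
        v = np.linspace(-1, 1, 41) + 10.0
        assert pf.biweight_mean(v) == pytest.approx(v.mean(), abs=1e-6)
        del rng

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pf.biweight_mean([])

    @given(st.floats(10.0, 1e12))
    @settings(max_examples=30, deadline=None)
    def test_bounded_influence(self, outlier):
        # moving one point to arbitrarily large values cannot drag the
        # estimate beyond the span where its weight vanishes
        base = [1.0, 1.2, 0.8, 1.1, 0.9, 1.05]
        m = pf.biweight_mean(base + [outlier])
        assert m < 3.0


class TestBuildChronology:
    def test_identical_series_reproduced(self):
        idx = 1.0 + 0.2 * np.sin(np.arange(50) / 3.0)
        detr = [
            pf.DetrendedSeries(f"s{i}", np.arange(1900, 1950), idx.copy(), "mean", (1.0,))
            for i in range(4)
        ]
        chron = pf.build_chronology(detr)
        np.testing.assert_allclose(chron.index, idx, atol=1e-9)
        assert chron.rbar == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(chron.stabilized_index, chron.index, atol=1e-9)

    def test_constant_series_excluded_from_rbar(self):
        years = np.arange(1900, 1950)
        wiggly = 1.0 + 0.3 * np.cos(np.arange(50) / 2.0)
        detr = [
            pf.DetrendedSeries("a", years, wiggly, "mean", (1.0,)),
            pf.DetrendedSeries("b", years, wiggly * 1.1, "mean", (1.0,)),
            pf.DetrendedSeries("flat", years, np.ones(50), "mean", (1.0,)),
        ]
        chron = pf.build_chronology(detr)
        # only the (a, b) pair contributes: r = 1
        assert chron.rbar == pytest.approx(1.0, abs=1e-12)

    def test_requires_overlap(self):
        detr = [
            pf.DetrendedSeries("a", np.arange(1900, 1930), np.ones(30), "mean", (1.0,)),
            pf.DetrendedSeries("b", np.arange(1950, 1980), np.ones(30), "mean", (1.0,)),
        ]
        with pytest.raises(pf.ChronologyError):
            pf.build_chronology(detr)

    def test_chronology_beats_single_series(self, ring_signal, noisy_tree_set):
        detr = pf.detrend_set(noisy_tree_set)
        chron = pf.build_chronology(detr)
        sig = np.array([ring_signal.value_at(int(y)) for y in chron.years])
        r_chron = np.corrcoef(chron.index, sig)[0, 1]
        singles = []
        for d in detr:
            s = np.array([ring_signal.value_at(int(y)) for y in d.years])
            singles.append(np.corrcoef(d.index, s)[0, 1])
        # averaging cancels independent noise: the chronology should track
        # the common signal better than any individual tree
        assert r_chron > max(singles)

    def test_stabilization_flattens_depth_driven_variance(self, ring_signal):
        # staggered starts: early years carried by few trees
        ts = pf.gen_tree_ring_set(25, 120, ring_signal, noise_sd=0.4, seed=13,
                                  stagger_fraction=0.6)
        chron = pf.build_chronology(pf.detrend_set(ts))
        half = len(chron) // 2
        depth_lo = chron.sample_depth[:half].mean()
        depth_hi = chron.sample_depth[half:].mean()
        assert depth_lo < depth_hi  # fixture sanity

        def var_ratio(values):
            return np.var(values[:half]) / np.var(values[half:])

        raw = var_ratio(chron.index)
        stab = var_ratio(chron.stabilized_index)
        assert abs(math.log(stab)) < abs(math.log(raw))


class TestEps:
    def test_perfect_agreement(self):
        assert pf.eps(17, 1.0) == 1.0

    def test_single_series_limit(self):
        assert pf.eps(1, 0.42) == pytest.approx(0.42, abs=1e-12)

    def test_closed_form_value(self):
        assert pf.eps(30, 0.3) == pytest.approx(9.0 / 9.7, abs=1e-12)
        assert pf.eps(30, 0.3) == pytest.approx(0.92784, abs=1e-5)

    def test_nonpositive_rbar_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert pf.eps(10, -0.1) == 0.0

    @given(n=st.integers(1, 200), rbar=st.floats(0.01, 0.99),
           dn=st.integers(1, 50), dr=st.floats(0.001, 0.5))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_n_and_rbar(self, n, rbar, dn, dr):
        assert pf.eps(n + dn, rbar) > pf.eps(n, rbar)
        assert pf.eps(n, min(rbar + dr, 0.999)) > pf.eps(n, rbar)

    def test_windowed_eps_geometry_and_range(self, noisy_tree_set):
        detr = pf.detrend_set(noisy_tree_set)
        windows = pf.eps_series(detr, window=30, overlap=15)
        table = eps_table(windows)
        assert (table["win_end"] - table["win_start"] + 1).max() <= 30
        starts = table["win_start"].to_numpy()
        assert np.all(np.diff(starts) == 15)
        valid = table.dropna()
        assert len(valid) >= 3
        assert ((valid["eps"] >= 0) & (valid["eps"] <= 1)).all()
        # windowed rbar is a local quantity: it should vary across windows
        assert valid["rbar"].nunique() > 1

    def test_final_partial_window_included(self, noisy_tree_set):
        detr = pf.detrend_set(noisy_tree_set)
        windows = pf.eps_series(detr, window=30, overlap=15)
        last = windows[-1]
        first, _, _, _ = windows[0]
        span_end = max(int(d.years[-1]) for d in detr)
        assert last[1] == span_end


class TestCalibrate:
    def test_identity_series(self):
        years = np.arange(1961, 2007)
        vals = 1.0 + 0.1 * np.sin(years / 3.0)
        chron = pf.AnnualSeries(years, vals)
        r = pf.calibrate(chron, pf.AnnualSeries(years, vals.copy()))
        slope, intercept, pearson = r
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert pearson == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(8)
        years = np.arange(2000)
        a = pf.AnnualSeries(years, rng.standard_normal(2000))
        b = pf.AnnualSeries(years, rng.standard_normal(2000))
        _, _, r = pf.calibrate(a, b)
        assert abs(r) < 0.05

    def test_slope_equals_pearson_on_zscores(self, ring_signal):
        rng = np.random.default_rng(9)
        instr = pf.AnnualSeries(ring_signal.years,
                                ring_signal.values + 0.3 * rng.standard_normal(len(ring_signal)))
        slope, _, r = pf.calibrate(ring_signal, instr)
        assert slope == pytest.approx(r, abs=1e-12)

    def test_common_period_restriction(self, ring_signal):
        short = pf.AnnualSeries(ring_signal.years[:5], ring_signal.values[:5])
        with pytest.raises(pf.ChronologyError):
            pf.calibrate(ring_signal, short)
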