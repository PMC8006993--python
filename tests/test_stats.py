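"""Group statistics: summaries, histograms, spectra, Welch t-test, reports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootspeckle as rs
from rootspeckle.errors import InputError


def _rer(values, dt=0.5, label=None):
    values = np.asarray(values, float)
    return rs.RERTrace(times_s=np.arange(len(values)) * dt, rate=values, group_label=label)


def brute_force_five_number(x):
    """Independent quartile/fence computation by explicit order statistics."""
    x = np.sort(np.asarray(x, float))
    n = len(x)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = x[(x < lo_f) | (x > hi_f)]
    return x[0], q1, med, q3, x[-1], (lo_f, hi_f), outliers


class TestFiveNumberSummary:
    def test_symmetric_small_set(self):
        s = rs.five_number_summary([1, 2, 3, 4, 5])
        assert (s.min, s.q1, s.median, s.q3, s.max) == (1, 2, 3, 4, 5)
        assert len(s.outliers) == 0

    def test_tukey_outlier(self):
        s = rs.five_number_summary([1, 2, 3, 4, 100])
        assert s.q1 == 2 and s.q3 == 4
        assert s.fences == (-1.0, 7.0)
        np.testing.assert_array_equal(s.outliers, [100])

    def test_constant_sample(self):
        s = rs.five_number_summary([3.0] * 10)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 3.0
        assert len(s.outliers) == 0

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            rs.five_number_summary([1, 2, 3])

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = rng.integers(4, 50)
            x = rng.normal(0, rng.uniform(0.5, 20), n)
            if rng.random() < 0.3:  # heavy tail to provoke outliers
                x[0] *= 25
            s = rs.five_number_summary(x)
            mn, q1, med, q3, mx, fences, outliers = brute_force_five_number(x)
            assert s.min == pytest.approx(mn)
            assert s.q1 == pytest.approx(q1)
            assert s.median == pytest.approx(med)
            assert s.q3 == pytest.approx(q3)
            assert s.max == pytest.approx(mx)
            assert s.fences == pytest.approx(fences)
            np.testing.assert_allclose(s.outliers, outliers)


class TestHistogram:
    def test_fixed_bins(self):
        h = rs.histogram_compare([0, 0, 1, 1], [0, 1], bin_rule=2, labels=("a", "b"))
        np.testing.assert_array_equal(h.counts["a"], [2, 2])
        np.testing.assert_array_equal(h.counts["b"], [1, 1])

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            rs.histogram_compare([], [1.0])

    @given(
        a=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=80),
        b=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=80),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_counts_conserved(self, a, b):
        h = rs.histogram_compare(a, b, bin_rule=7)
        assert h.counts["a"].sum() == len(a)
        assert h.counts["b"].sum() == len(b)
        assert np.all(np.diff(h.bin_edges) > 0)

    def test_dry_mass_extends_further_negative(self, presets, geom):
        """The dry group's lower tail reaches much further left than the wet."""
        wet = np.concatenate(
            [rs.generate_rer_trace(presets["wet"], 150.0, geom, [1, i]).rate for i in range(20)]
        )
        dry = np.concatenate(
            [rs.generate_rer_trace(presets["dry"], 150.0, geom, [2, i]).rate for i in range(20)]
        )
        assert np.percentile(dry, 5) < np.percentile(wet, 5) - 10


class TestGroupMoments:
    def test_constant_trace(self):
        m = rs.group_moments([_rer([4.0] * 10)])
        assert m.pooled_mean == 4.0
        assert m.pooled_std == 0.0
        assert m.n_samples == 10

    def test_pooled_vs_per_trace(self):
        m = rs.group_moments([_rer([1.0, 2.0]), _rer([3.0, 4.0])])
        assert m.pooled_mean == pytest.approx(2.5)
        np.testing.assert_allclose(m.trace_means, [1.5, 3.5])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rs.group_moments([])


class TestPowerSpectrum:
    def test_constant_trace_no_ac_power(self):
        sp = rs.power_spectrum(_rer([5.0] * 32))
        np.testing.assert_allclose(sp.amplitude[1:], 0.0, atol=1e-12)

    def test_pure_sinusoid_closed_form(self):
        """A unit sinusoid at 0.1 Hz lands entirely in bin 15 of a 150-s trace."""
        t = np.arange(300) * 0.5
        sp = rs.power_spectrum(_rer(np.sin(2 * np.pi * t / 10.0)))
        assert sp.dominant_freq_hz == pytest.approx(0.1)
        assert sp.dominant_period_s == pytest.approx(10.0)
        assert sp.peak_amplitude == pytest.approx(1.0, rel=1e-9)
        others = np.delete(sp.amplitude, 15)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_parseval(self):
        """Summed spectral power equals the variance of the mean-removed trace."""
        rng = np.random.default_rng(3)
        for n in (64, 127, 300):
            x = rng.normal(0, 2.0, n)
            sp = rs.power_spectrum(_rer(x))
            amp = sp.amplitude
            if n % 2 == 0:
                power = np.sum(amp[1:-1] ** 2) / 2 + amp[-1] ** 2
            else:
                power = np.sum(amp[1:] ** 2) / 2
            assert power == pytest.approx(np.var(x), rel=1e-9)

    def test_nonuniform_sampling_rejected(self):
        trace = rs.RERTrace(times_s=np.array([0, 0.5, 1.7, 2.0] + list(np.arange(3, 8.0))),
                            rate=np.zeros(9))
        with pytest.raises(InputError):
            rs.power_spectrum(trace)

    def test_dc_excluded_from_dominant(self):
        """A large mean offset must not masquerade as the dominant frequency."""
        t = np.arange(128) * 0.5
        sp = rs.power_spectrum(_rer(100.0 + 0.5 * np.sin(2 * np.pi * t / 8.0)))
        assert sp.dominant_freq_hz == pytest.approx(1.0 / 8.0)


class TestSpectralCompare:
    def test_identical_groups_unit_ratio(self):
        t = np.arange(64) * 0.5
        sp = [rs.power_spectrum(_rer(np.sin(2 * np.pi * t / 8.0)))]
        cmp = rs.spectral_group_compare(sp, sp)
        assert cmp.peak_amplitude_ratio == pytest.approx(1.0)
        assert cmp.all_below_band_limit

    def test_double_amplitude_ratio(self):
        t = np.arange(64) * 0.5
        a = [rs.power_spectrum(_rer(2.0 * np.sin(2 * np.pi * t / 8.0)))]
        b = [rs.power_spectrum(_rer(np.sin(2 * np.pi * t / 8.0)))]
        cmp = rs.spectral_group_compare(a, b)
        assert cmp.peak_amplitude_ratio == pytest.approx(2.0, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        t = np.arange(64) * 0.5
        a = [rs.power_spectrum(_rer(np.sin(t)))]
        b = [rs.power_spectrum(_rer(np.sin(np.arange(32) * 0.5)))]
        with pytest.raises(InputError):
            rs.spectral_group_compare(a, b)


class TestWelch:
    def test_identical_groups(self):
        r = rs.welch_t_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # t = -3 / sqrt(1/3 + 1/3), Welch-Satterthwaite df = 4
        r = rs.welch_t_test([1, 2, 3], [4, 5, 6])
        assert r.t_stat == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert r.df == pytest.approx(4.0, rel=1e-9)
        assert r.p_value == pytest.approx(0.021312, rel=1e-3)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(InputError):
            rs.welch_t_test([1.0, 1.0], [1.0, 1.0])

    @given(
        data=st.data(),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_and_affine_equivariance(self, data, scale, shift):
        a = data.draw(st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=20))
        b = data.draw(st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=20))
        a, b = np.asarray(a) + np.arange(len(a)) * 1e-6, np.asarray(b) + 1.0
        r1 = rs.welch_t_test(a, b)
        r2 = rs.welch_t_test(b, a)
        assert r2.t_stat == pytest.approx(-r1.t_stat, rel=1e-9, abs=1e-12)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9, abs=1e-12)
        r3 = rs.welch_t_test(scale * a + shift, scale * b + shift)
        assert r3.p_value == pytest.approx(r1.p_value, rel=1e-6, abs=1e-12)


class TestGroupReport:
    def test_identical_groups(self, presets, geom):
        traces = [rs.generate_rer_trace(presets["wet"], 30.0, geom, [9, i]) for i in range(3)]
        report = rs.compare_groups(traces, traces, labels=("x", "y"))
        assert report.ttest.t_stat == pytest.approx(0.0)
        assert report.spectral.peak_amplitude_ratio == pytest.approx(1.0)
        assert report.summaries["x"].median == report.summaries["y"].median

    def test_json_round_trip(self, presets, geom):
        wet = [rs.generate_rer_trace(presets["wet"], 30.0, geom, [10, i]) for i in range(3)]
        dry = [rs.generate_rer_trace(presets["dry"], 30.0, geom, [11, i]) for i in range(3)]
        report = rs.compare_groups(wet, dry, labels=("wet", "dry"))
        blob = json.dumps(report.to_dict())
        back = rs.GroupReport.from_dict(json.loads(blob))
        assert back.to_dict() == report.to_dict()
        assert back.ttest.p_value == report.ttest.p_value
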