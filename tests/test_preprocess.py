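"""Confound removal: regression, detrending, peaks, phases, displacement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boldcv.io_formats import BoldSeries, MotionParams, PhysioTrace
from boldcv.phantom import PhantomSpec, synth_physio
from boldcv.preprocess import (
    CardiacPeaks,
    PeakDetectionError,
    RegressorSet,
    cardiac_phase,
    detect_cardiac_peaks,
    detrend_linear,
    mean_displacement,
    motion_regressors,
    regress_confounds,
    resp_phase,
    retroicor_regressors,
)


def _series_from_voxels(voxels: np.ndarray, tr=2.0) -> BoldSeries:
    """Wrap an (n_voxels, T) array as a (n,1,1,T) series."""
    return BoldSeries(data=voxels[:, None, None, :], tr_s=tr)


class TestRegressConfounds:
    def test_perfect_confound_leaves_constant_mean(self, rng):
        t = np.arange(100)
        confound = np.sin(0.3 * t)
        y = 50.0 + 3.0 * confound
        series = _series_from_voxels(np.array([y]))
        regs = RegressorSet(matrix=confound[:, None], labels=["c"])
        out = regress_confounds(series, regs).data[0, 0, 0]
        # residual is flat at the voxel's temporal mean; its CV is 0
        np.testing.assert_allclose(out, y.mean(), atol=1e-10)
        assert out.std(ddof=1) / out.mean() < 1e-12

    def test_orthogonal_regressors_change_nothing(self):
        t = np.arange(128)
        y = 10.0 + np.cos(2 * np.pi * 4 * t / 128)
        reg = np.sin(2 * np.pi * 9 * t / 128)  # orthogonal Fourier mode
        series = _series_from_voxels(np.array([y]))
        out = regress_confounds(series, RegressorSet(reg[:, None], ["r"])).data
        np.testing.assert_allclose(out[0, 0, 0], y, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: explicit normal-equations solve with intercept
        T, k = 180, 6
        y = rng.standard_normal(T)
        X = rng.standard_normal((T, k))
        design = np.column_stack([np.ones(T), X - X.mean(axis=0)])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid_oracle = y - design @ beta + beta[0]  # keep the intercept (mean)
        series = _series_from_voxels(np.array([y]))
        out = regress_confounds(series, RegressorSet(X, [f"x{i}" for i in range(k)]))
        np.testing.assert_allclose(out.data[0, 0, 0], resid_oracle, atol=1e-9)

    def test_idempotent_and_variance_monotone(self, rng):
        y = rng.standard_normal((12, 64)) + 100
        X = rng.standard_normal((64, 4))
        series = _series_from_voxels(y)
        regs = RegressorSet(X, list("abcd"))
        once = regress_confounds(series, regs)
        twice = regress_confounds(once, regs)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)
        assert (once.data.var(-1) <= series.data.var(-1) + 1e-12).all()
        np.testing.assert_allclose(once.data.mean(-1), series.data.mean(-1),
                                   atol=1e-10)

    def test_residual_orthogonal_to_regressors(self, rng):
        y = rng.standard_normal((5, 80))
        X = rng.standard_normal((80, 3))
        out = regress_confounds(_series_from_voxels(y), RegressorSet(X, list("abc")))
        resid = out.data.reshape(5, 80)
        xc = X - X.mean(0)
        np.testing.assert_allclose(resid @ xc, 0.0, atol=1e-8)

    def test_rank_deficient_design_warns(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        series = _series_from_voxels(rng.standard_normal((3, 50)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_confounds(series, RegressorSet(X, list("abc")))

    def test_all_zero_voxel_passes_through(self, rng):
        y = np.zeros((1, 60))
        X = rng.standard_normal((60, 2))
        out = regress_confounds(_series_from_voxels(y), RegressorSet(X, list("ab")))
        assert (out.data == 0).all()

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            RegressorSet(np.zeros((10, 1)), ["z"])


class TestDetrend:
    def test_pure_ramp_becomes_constant(self):
        t = np.arange(180.0)
        y = 100.0 * (1 + 0.01 * t / 180)
        out = detrend_linear(_series_from_voxels(np.array([y]))).data[0, 0, 0]
        np.testing.assert_allclose(out, y.mean(), atol=1e-9)

    def test_idempotent(self, rng):
        series = _series_from_voxels(rng.standard_normal((6, 90)))
        once = detrend_linear(series)
        twice = detrend_linear(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_matches_polyfit_oracle(self, rng):
        t = np.arange(120.0)
        y = np.sin(2 * np.pi * t / 30) + 0.004 * t + 10
        slope, intercept = np.polyfit(t, y, 1)
        oracle = y - slope * (t - t.mean())
        out = detrend_linear(_series_from_voxels(np.array([y]))).data[0, 0, 0]
        np.testing.assert_allclose(out, oracle, atol=1e-10)
        assert abs(np.polyfit(t, out, 1)[0]) < 1e-12


class TestCardiacPeaks:
    def test_phantom_rate_recovered_within_1pct(self):
        spec = PhantomSpec(seed=5)
        trace, _ = synth_physio(spec)
        peaks = detect_cardiac_peaks(trace)
        assert peaks.mean_rate_hz() == pytest.approx(1.13, rel=0.01)

    def test_constant_trace_is_error(self):
        with pytest.raises(PeakDetectionError):
            detect_cardiac_peaks(np.ones(2000), sample_hz=100.0)

    def test_noisy_peaks_match_truth_within_one_sample(self):
        spec = PhantomSpec(seed=21)
        trace, truth = synth_physio(spec)
        rng = np.random.default_rng(0)
        noisy = trace.cardiac + 0.05 * trace.cardiac.std() * rng.standard_normal(
            trace.cardiac.size
        )
        peaks = detect_cardiac_peaks(noisy, sample_hz=trace.cardiac_hz)
        interior = truth[(truth > 1.0) & (truth < peaks.peak_times_s[-1] - 1.0)]
        for t in interior:
            assert np.abs(peaks.peak_times_s - t).min() < 1.0 / trace.cardiac_hz

    def test_refractory_enforced(self):
        with pytest.raises(ValueError, match="refractory"):
            CardiacPeaks(peak_times_s=np.array([0.0, 0.1, 1.0]))


class TestPhases:
    def test_phase_zero_at_peak_pi_at_midpoint(self):
        peaks = CardiacPeaks(peak_times_s=np.array([0.0, 1.0, 2.2, 3.0]))
        assert cardiac_phase(peaks, 1.0)[0] == pytest.approx(0.0)
        assert cardiac_phase(peaks, 1.6)[0] == pytest.approx(np.pi)

    def test_jittered_intervals_match_piecewise_oracle(self, rng):
        times = np.cumsum(0.8 + 0.2 * rng.random(20))
        peaks = CardiacPeaks(peak_times_s=times)
        t = rng.uniform(times[0], times[-1] - 1e-6, 50)
        got = cardiac_phase(peaks, t)
        for ti, phi in zip(t, got):
            k = np.searchsorted(times, ti, side="right") - 1
            expect = 2 * np.pi * (ti - times[k]) / (times[k + 1] - times[k])
            assert phi == pytest.approx(expect, abs=1e-10)

    def test_phase_in_range_outside_peaks(self):
        peaks = CardiacPeaks(peak_times_s=np.array([1.0, 2.0, 3.0]))
        phi = cardiac_phase(peaks, np.array([0.4, 3.7]))
        assert ((phi >= 0) & (phi < 2 * np.pi)).all()

    def test_resp_phase_extremes_and_monotonicity(self):
        fs, f = 100.0, 0.3
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        # near the maximum the cumulative histogram is ~1, so |phi| ~ pi
        t_max = (np.pi / 2 - 0.05) / (2 * np.pi * f)
        phi = resp_phase(x, t_max, sample_hz=fs)
        assert abs(phi[0]) > 0.9 * np.pi
        # rising half-cycle: phase monotone (analytic equalisation of the
        # sinusoid's arcsine amplitude distribution is monotone)
        rise = np.linspace(-np.pi / 2 + 0.1, np.pi / 2 - 0.1, 25) / (2 * np.pi * f)
        rise = rise + 1 / f  # shift into the sampled support
        phis = resp_phase(x, rise, sample_hz=fs)
        assert (np.diff(phis) > 0).all()

    def test_inverted_trace_flips_sign_pattern(self):
        fs = 100.0
        t = np.arange(int(40 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        query = np.linspace(5, 30, 40)
        a = resp_phase(x, query, sample_hz=fs)
        b = resp_phase(-x, query, sample_hz=fs)
        nz = (np.abs(a) > 0.1) & (np.abs(b) > 0.1)
        assert (np.sign(a[nz]) == -np.sign(b[nz])).all()

    def test_constant_resp_trace_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            resp_phase(np.ones(1000), 1.0, sample_hz=100.0)


class TestRetroicor:
    def test_eight_columns_order_two(self, default_subject):
        sub = default_subject
        regs = retroicor_regressors(
            sub.physio, sub.bold.n_timepoints, sub.bold.tr_s, sub.bold.slice_offsets_s
        )
        assert regs.n_columns == 8
        assert regs.slice_specific
        assert regs.matrix.shape == (sub.bold.n_slices, sub.bold.n_timepoints, 8)

    def test_zero_offsets_give_identical_slices(self, default_subject):
        sub = default_subject
        regs = retroicor_regressors(
            sub.physio, sub.bold.n_timepoints, sub.bold.tr_s,
            np.zeros(sub.bold.n_slices),
        )
        np.testing.assert_array_equal(regs.matrix[0], regs.matrix[-1])

    def test_removes_injected_physiological_variance(self):
        from boldcv.phantom import generate_subject

        spec = PhantomSpec(
            tissue_cv={"GM": 0.0, "WM": 0.0, "CSF": 0.0},
            drift_slope_frac_per_scan=0.0, thermal_sd_frac=0.0, seed=7,
        )
        sub = generate_subject(spec)
        var0 = sub.bold.data.var(-1, ddof=1)
        regs = retroicor_regressors(
            sub.physio, sub.bold.n_timepoints, sub.bold.tr_s, sub.bold.slice_offsets_s
        )
        var1 = regress_confounds(sub.bold, regs).data.var(-1, ddof=1)
        hi = sub.brain_mask.data & (
            var0 > np.percentile(var0[sub.brain_mask.data], 75)
        )
        assert 1 - var1[hi].sum() / var0[hi].sum() >= 0.90


class TestDisplacement:
    def test_zero_motion(self):
        assert mean_displacement(MotionParams(np.zeros((180, 6)))) == 0.0

    def test_single_step_translation(self):
        params = np.zeros((180, 6))
        params[100:, 3] = 1.0  # one 1 mm x-translation step
        assert mean_displacement(MotionParams(params)) == pytest.approx(1 / 179)

    def test_manual_five_frame_fixture(self):
        params = np.array([
            [0.000, 0.000, 0.000, 0.0, 0.0, 0.0],
            [0.001, 0.000, 0.000, 0.1, 0.0, 0.0],
            [0.001, -0.002, 0.000, 0.1, 0.2, 0.0],
            [0.001, -0.002, 0.001, 0.1, 0.2, -0.3],
            [0.000, -0.002, 0.001, 0.0, 0.2, -0.3],
        ])
        # hand computation: per-step |dtrans| sums + 50 * |drot| sums
        steps = [0.1 + 50 * 0.001, 0.2 + 50 * 0.002, 0.3 + 50 * 0.001,
                 0.1 + 50 * 0.001]
        expect = np.mean(steps)
        assert mean_displacement(MotionParams(params)) == pytest.approx(expect)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 6))
def test_property_regression_never_inflates_variance(seed, k):
    """Any nuisance design: variance non-increasing, temporal mean preserved."""
    rng = np.random.default_rng(seed)
    y = 100 + rng.standard_normal((4, 40))
    X = rng.standard_normal((40, k))
    out = regress_confounds(_series_from_voxels(y), RegressorSet(X, [str(i) for i in range(k)]))
    resid = out.data.reshape(4, 40)
    assert (resid.var(-1) <= y.var(-1) + 1e-12).all()
    np.testing.assert_allclose(resid.mean(-1), y.mean(-1), atol=1e-9)


def test_motion_regressors_from_params(rng):
    motion = MotionParams(rng.standard_normal((30, 6)) * 0.01)
    regs = motion_regressors(motion)
    assert regs.n_columns == 6 and not regs.slice_specific
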