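"""Tests of the ordered RSFC denoising stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netseg.denoise import (
    CLEAN,
    BoldTimeSeries,
    MotionTrace,
    NuisanceSet,
    Stage,
    bandpass,
    build_nuisance,
    censor_and_interpolate,
    compute_fd,
    demean_detrend,
    denoise_subject,
    drop_interpolated,
    qc_and_select,
    regress_nuisance,
)
from netseg.errors import (
    AllFramesCensoredError,
    DesignMatrixError,
    FormatError,
    PipelineOrderError,
)

from .oracles import normal_equations_beta


def ts_at(data, stage, tr=3.0, status=None):
    out = BoldTimeSeries(data=np.asarray(data, dtype=float), tr=tr,
                         frame_status=status)
    out.stage = Stage(stage)
    return out


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero(self):
        assert np.all(compute_fd(np.ones((10, 6))) == 0.0)

    def test_translation_step_equals_step_size(self):
        p = np.zeros((5, 6))
        p[3:, 0] = 0.1  # 0.1 mm x-translation from frame 4 on
        fd = compute_fd(p)
        np.testing.assert_allclose(fd, [0, 0, 0, 0.1, 0])

    def test_rotation_converted_at_head_radius(self):
        p = np.zeros((4, 6))
        p[2:, 3] = 0.002  # rad
        fd = compute_fd(p, head_radius=50.0)
        np.testing.assert_allclose(fd, [0, 0, 0.1, 0])

    def test_first_frame_is_zero_by_convention(self):
        rng = np.random.default_rng(0)
        fd = compute_fd(rng.normal(size=(20, 6)))
        assert fd[0] == 0.0 and np.all(fd[1:] > 0)

    def test_malformed_table_rejected(self):
        with pytest.raises(FormatError):
            compute_fd(np.zeros((10, 5)))


class TestNuisanceDesign:
    def test_friston24_and_tissue_column_count(self):
        rng = np.random.default_rng(1)
        ts = ts_at(rng.normal(size=(60, 8)), Stage.DETRENDED)
        motion = MotionTrace.from_params(rng.normal(size=(60, 6)))
        nuis = build_nuisance(ts, motion, rng.normal(size=(60, 2)))
        assert nuis.k == 30  # 3 tissue signals x 2 + 24 motion columns
        assert sum(n.startswith(("motion", "d_motion")) for n in nuis.names) == 24

    def test_zero_motion_columns_dropped(self):
        rng = np.random.default_rng(2)
        ts = ts_at(rng.normal(size=(40, 5)), Stage.DETRENDED)
        motion = MotionTrace.from_params(np.zeros((40, 6)))
        nuis = build_nuisance(ts, motion, rng.normal(size=(40, 2)))
        assert nuis.k == 6  # only the tissue block survives
        assert not any(n.startswith("motion") for n in nuis.names)

    def test_difference_of_ramp_is_constant(self):
        ts = ts_at(np.random.default_rng(3).normal(size=(30, 4)), Stage.DETRENDED)
        params = np.zeros((30, 6))
        params[:, 0] = np.arange(30.0)  # linear ramp
        nuis = build_nuisance(ts, MotionTrace.from_params(params))
        d_col = nuis.regressors[:, nuis.names.index("d_motion_1")]
        assert np.all(d_col[1:] == 1.0)


class TestDetrend:
    def test_linear_ramp_removed_entirely(self):
        data = np.outer(np.arange(20.0), [1.0, -2.0]) + 5.0
        out = demean_detrend(ts_at(data, Stage.RAW))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_zero_mean_sinusoid_unchanged(self):
        # even about the series midpoint, so orthogonal to the fitted line
        t = np.arange(64.0)
        data = np.cos(2 * np.pi * (t - 31.5) / 8.0)[:, None]
        out = demean_detrend(ts_at(data, Stage.RAW))
        np.testing.assert_allclose(out.data, data, atol=1e-8)

    def test_ramp_plus_sinusoid_recovers_sinusoid(self):
        t = np.arange(64.0)
        sine = np.cos(2 * np.pi * (t - 31.5) / 8.0)
        data = (sine + 0.5 * t + 3.0)[:, None]
        out = demean_detrend(ts_at(data, Stage.RAW))
        # oracle: explicit least-squares line fit
        X = np.column_stack([np.ones_like(t), t])
        line = X @ normal_equations_beta(X, data[:, 0])
        np.testing.assert_allclose(out.data[:, 0], data[:, 0] - line, atol=1e-8)
        assert np.max(np.abs(out.data[:, 0] - sine)) < 1e-8


class TestNuisanceRegression:
    def _toy(self, n=20, k=3, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        return rng, X

    def test_exact_combination_leaves_zero_residual(self):
        rng, X = self._toy()
        y = X @ np.array([1.0, -2.0, 0.5])
        ts = ts_at(y[:, None], Stage.DETRENDED)
        out = regress_nuisance(ts, NuisanceSet(X, [f"c{i}" for i in range(3)]))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_every_regressor(self):
        rng, X = self._toy(n=100)
        y = rng.normal(size=(100, 4))
        out = regress_nuisance(ts_at(y, Stage.DETRENDED),
                               NuisanceSet(X, ["a", "b", "c"]))
        gram = X.T @ out.data
        assert np.max(np.abs(gram)) < 1e-10 * np.abs(X.T @ y).max()

    def test_matches_normal_equations_oracle(self):
        rng, X = self._toy(n=20)
        y = rng.normal(size=20)
        beta = normal_equations_beta(X, y)
        out = regress_nuisance(ts_at(y[:, None], Stage.DETRENDED),
                               NuisanceSet(X, ["a", "b", "c"]))
        np.testing.assert_allclose(out.data[:, 0], y - X @ beta, atol=1e-10)

    def test_fit_uses_only_uncensored_frames(self):
        rng, X = self._toy(n=40)
        y = X @ np.array([2.0, 1.0, -1.0])
        y_corrupt = y.copy()
        y_corrupt[5] += 100.0  # censored frame may be arbitrarily bad
        censor = np.zeros(40, dtype=bool)
        censor[5] = True
        out = regress_nuisance(ts_at(y_corrupt[:, None], Stage.DETRENDED),
                               NuisanceSet(X, ["a", "b", "c"]),
                               censor_mask=censor)
        clean = ~censor
        np.testing.assert_allclose(out.data[clean, 0], 0.0, atol=1e-9)

    def test_collinear_design_names_columns(self):
        rng, X = self._toy(n=30)
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(DesignMatrixError, match="dup"):
            regress_nuisance(ts_at(rng.normal(size=(30, 2)), Stage.DETRENDED),
                             NuisanceSet(X, ["a", "b", "c", "dup"]))


class TestScrubbing:
    def test_fd_threshold_censors_expected_frames(self):
        data = np.random.default_rng(5).normal(size=(4, 3))
        fd = np.array([0.0, 0.1, 0.4, 0.1])
        out = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, 0.3)
        assert out.n_clean == 3 and out.n_censored == 1
        assert out.frame_status[2] != CLEAN

    def test_all_below_threshold_is_identity(self):
        data = np.random.default_rng(6).normal(size=(10, 3))
        out = censor_and_interpolate(ts_at(data, Stage.REGRESSED),
                                     np.full(10, 0.1), 0.3)
        np.testing.assert_array_equal(out.data, data)
        assert out.n_clean == 10

    def test_interior_gap_filled_by_exact_line(self):
        data = np.arange(10.0)[:, None] * 3.0 + 1.0
        fd = np.zeros(10)
        fd[4] = 1.0
        out = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, 0.3)
        assert out.data[4, 0] == pytest.approx(data[4, 0])

    def test_edge_gaps_take_nearest_clean_value(self):
        data = np.arange(6.0)[:, None]
        fd = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 1.0])
        fd[0] = 1.0  # first frame also censored
        out = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, 0.3)
        assert out.data[0, 0] == pytest.approx(2.0)   # first clean frame
        assert out.data[5, 0] == pytest.approx(3.0)   # last clean frame

    def test_everything_censored_is_an_error(self):
        data = np.zeros((5, 2))
        with pytest.raises(AllFramesCensoredError):
            censor_and_interpolate(ts_at(data, Stage.REGRESSED),
                                   np.full(5, 1.0), 0.3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=60),
           st.floats(0.05, 0.6), st.floats(0.05, 0.6))
    def test_lower_threshold_never_increases_clean_count(self, fds, t1, t2):
        fd = np.asarray(fds)
        fd[0] = 0.0
        lo, hi = sorted((t1, t2))
        if np.all(fd > lo):
            return  # degenerate: everything censored at the lower threshold
        data = np.zeros((fd.size, 2))
        n_lo = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, lo).n_clean
        n_hi = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, hi).n_clean
        assert n_lo <= n_hi
        # frame conservation at either threshold
        out = censor_and_interpolate(ts_at(data, Stage.REGRESSED), fd, hi)
        assert out.n_clean + out.n_censored == fd.size


class TestBandpass:
    def _sine(self, freq_hz, n=400, tr=3.0):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq_hz * t)[:, None]

    def test_passband_tone_survives(self):
        x = self._sine(0.04)
        y = bandpass(ts_at(x, Stage.SCRUBBED)).data
        assert np.std(y[50:-50]) >= 0.9 * np.std(x[50:-50])

    def test_stopband_tone_suppressed(self):
        x = self._sine(0.15)
        y = bandpass(ts_at(x, Stage.SCRUBBED)).data
        assert np.std(y[50:-50]) <= 0.1 * np.std(x[50:-50])

    def test_low_stopband_tone_suppressed(self):
        x = self._sine(0.0045)  # one octave below the 0.009 Hz edge
        y = bandpass(ts_at(x, Stage.SCRUBBED)).data
        assert np.std(y[50:-50]) <= 0.1 * np.std(x[50:-50])

    def test_constant_signal_removed(self):
        x = np.full((200, 2), 7.0)
        y = bandpass(ts_at(x, Stage.SCRUBBED)).data
        assert np.max(np.abs(y)) < 1e-6

    def test_infeasible_band_rejected(self):
        with pytest.raises(FormatError):
            bandpass(ts_at(np.zeros((50, 1)), Stage.SCRUBBED), 0.009, 0.4)


class TestFrameSelection:
    def _scrubbed(self, n, n_censored, seed=7):
        rng = np.random.default_rng(seed)
        status = np.zeros(n, dtype=np.int8)
        status[rng.choice(n, size=n_censored, replace=False)] = 2
        return ts_at(rng.normal(size=(n, 3)), Stage.FILTERED, status=status)

    def test_drop_interpolated_counts(self):
        out = drop_interpolated(self._scrubbed(140, 30))
        assert out.n_frames == 110

    def test_drop_interpolated_identity_when_all_clean(self):
        ts = self._scrubbed(50, 0)
        out = drop_interpolated(ts)
        np.testing.assert_array_equal(out.data, ts.data)

    def test_drop_preserves_order(self):
        data = np.arange(8.0)[:, None]
        status = np.array([0, 2, 0, 0, 2, 0, 0, 0], dtype=np.int8)
        out = drop_interpolated(ts_at(data, Stage.FILTERED, status=status))
        np.testing.assert_array_equal(out.data[:, 0], [0, 2, 3, 5, 6, 7])

    @pytest.mark.parametrize(
        "n_clean,retained", [(99, False), (100, True), (140, True)]
    )
    def test_hundred_frame_rule(self, n_clean, retained):
        ts = ts_at(np.random.default_rng(8).normal(size=(n_clean, 3)),
                   Stage.TRIMMED)
        selected, verdict = qc_and_select(ts, min_frames=100, n_select=100)
        assert verdict.retained is retained
        assert verdict.clean_frames == n_clean
        if retained:
            assert selected.n_frames == 100
            np.testing.assert_array_equal(selected.data, ts.data[:100])
        else:
            assert selected is None


class TestPipelineOrder:
    def test_stages_cannot_run_out_of_order(self):
        data = np.random.default_rng(9).normal(size=(50, 4))
        raw = ts_at(data, Stage.RAW)
        with pytest.raises(PipelineOrderError):
            bandpass(raw)
        with pytest.raises(PipelineOrderError):
            drop_interpolated(raw)
        with pytest.raises(PipelineOrderError):
            censor_and_interpolate(raw, np.zeros(50), 0.3)
        detrended = demean_detrend(raw)
        with pytest.raises(PipelineOrderError):
            demean_detrend(detrended)


def test_denoise_subject_full_sequence():
    rng = np.random.default_rng(10)
    data = rng.normal(size=(200, 12))
    steps = np.column_stack([0.01 * rng.normal(size=(200, 3)),
                             0.0002 * rng.normal(size=(200, 3))])
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    motion[50, 0] += 1.0  # one spike: frames 50 and 51 exceed FD 0.3
    res = denoise_subject(data, motion, tr=3.0,
                          tissue_surrogates=rng.normal(size=(200, 2)))
    assert res.verdict.retained
    assert res.ts.n_frames == 100
    assert res.n_frames_in == 200
    assert res.pct_frames_lost > 0
    assert res.mean_fd_pre > res.mean_fd_post
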