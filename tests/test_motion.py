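import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweptsa.beamform import BeamformedImage
from sweptsa.motion import (
    BoundaryPeakError,
    CorrelationCurve,
    build_multilag_system,
    channel_correlate_pair,
    interpolate_event_positions,
    solve_wls,
    speckle_track_pair,
    subsample_peak,
)


class TestSubsamplePeak:
    def test_symmetric_curve_peaks_on_sample(self):
        lags = np.arange(-5.0, 6.0)
        curve = CorrelationCurve(lags, 1.0 / (1.0 + lags**2))
        for method in ("iterative", "polynomial"):
            lag, peak = subsample_peak(curve, method)
            assert lag == pytest.approx(0.0, abs=1e-3)
            assert peak == pytest.approx(1.0, abs=1e-3)

    def test_band_limited_offset_recovered(self):
        # band-limited to half Nyquist: sinc^2 has a triangular spectrum
        true_offset = 0.37
        k = np.arange(-8.0, 9.0)
        curve = CorrelationCurve(k, np.sinc((k - true_offset) / 2.0) ** 2)
        lag, _ = subsample_peak(curve, "iterative")
        # dense-evaluation oracle of the same continuous function
        dense = np.linspace(-1, 1, 200001)
        oracle = dense[np.argmax(np.sinc((dense - true_offset) / 2.0) ** 2)]
        assert lag == pytest.approx(oracle, abs=0.01)

    def test_monotone_curve_raises_boundary_error(self):
        curve = CorrelationCurve(np.arange(5.0), np.arange(5.0) / 10.0)
        with pytest.raises(BoundaryPeakError):
            subsample_peak(curve)

    @given(offset=st.floats(-0.45, 0.45))
    @settings(max_examples=20, deadline=None)
    def test_sub_half_sample_offsets(self, offset):
        k = np.arange(-8.0, 9.0)
        curve = CorrelationCurve(k, np.sinc((k - offset) / 2.0) ** 2)
        lag, _ = subsample_peak(curve, "iterative")
        assert lag == pytest.approx(offset, abs=0.02)


class TestSpeckleTracking:
    def test_identity_pair(self, tracking_pair):
        _, images, _ = tracking_pair
        est, curve = speckle_track_pair(images[0], images[0])
        # the speckle autocovariance is not exactly symmetric, so the refined
        # peak may sit a few hundredths of a pixel off zero
        assert est.displacement == pytest.approx(0.0, abs=0.05 * images[0].grid.dx)
        assert est.peak_corr == pytest.approx(1.0, abs=1e-6)
        assert np.all(curve.values <= 1.0 + 1e-9)

    def test_constructed_roll_gives_negated_shift(self, tracking_pair):
        _, images, _ = tracking_pair
        img = images[0]
        rolled = BeamformedImage(
            img.grid, np.roll(img.pixels, 3, axis=1), {"frame_index": 1}
        )
        est, _ = speckle_track_pair(img, rolled)
        # scene moved +3 px, so the transducer moved -3 px
        assert est.displacement == pytest.approx(-3 * img.grid.dx, abs=0.1 * img.grid.dx)

    def test_simulated_tenth_millimeter_step(self, tracking_pair):
        _, images, poses = tracking_pair
        est, _ = speckle_track_pair(images[0], images[1])
        assert est.displacement - (poses[1] - poses[0]) == pytest.approx(0.0, abs=5e-6)
        assert est.peak_corr > 0.95

    def test_kernel_exceeding_image_rejected(self, tracking_pair):
        _, images, _ = tracking_pair
        with pytest.raises(ValueError, match="beyond the image extent"):
            speckle_track_pair(images[0], images[1], search=20e-3)


class TestChannelCorrelation:
    def test_identity_pair(self, tracking_pair):
        frames, _, _ = tracking_pair
        est, _ = channel_correlate_pair(frames[0], frames[0])
        assert est.displacement == pytest.approx(0.0, abs=1e-7)
        assert est.peak_corr == pytest.approx(1.0, abs=1e-6)

    def test_integer_pitch_shift_recovered_exactly(self, tracking_pair):
        frames, _, _ = tracking_pair
        ref = frames[0]
        # array moved +2 pitches: element e now sees what element e+2 saw
        shifted_rf = np.zeros_like(ref.rf)
        shifted_rf[:, :-2] = ref.rf[:, 2:]
        tgt = dataclasses.replace(ref, rf=shifted_rf, frame_index=1)
        est, _ = channel_correlate_pair(ref, tgt)
        assert abs(est.displacement) == pytest.approx(0.6e-3, abs=1e-6)
        assert est.displacement > 0
        assert est.peak_corr > 0.99

    def test_simulated_tenth_millimeter_step(self, tracking_pair):
        frames, _, poses = tracking_pair
        est, _ = channel_correlate_pair(frames[0], frames[1])
        assert est.displacement - (poses[1] - poses[0]) == pytest.approx(0.0, abs=5e-6)

    def test_sound_speed_choice_only_moves_the_window(self, tracking_pair):
        # the depth window shifts but the correlation is data-domain
        frames, _, _ = tracking_pair
        est_lo, _ = channel_correlate_pair(frames[0], frames[1], sound_speed=1240.0)
        est_hi, _ = channel_correlate_pair(frames[0], frames[1], sound_speed=1840.0)
        assert abs(est_lo.displacement - est_hi.displacement) < 10e-6

    def test_window_outside_samples_rejected(self, tracking_pair):
        frames, _, _ = tracking_pair
        with pytest.raises(ValueError, match="outside recorded samples"):
            channel_correlate_pair(frames[0], frames[1], depth=80e-3)


class TestMultilagSystem:
    @staticmethod
    def _const_pair(d=0.0, w=1.0):
        def fn(a, b):
            from sweptsa.motion import PairEstimate

            return PairEstimate(i=a, j=b, displacement=d * (b - a), peak_corr=w)

        return fn

    def test_three_frames_max_lag_two(self):
        H, Y, W = build_multilag_system([0, 1, 2], self._const_pair(), max_lag=2)
        assert H.shape == (3, 3)
        pairs = {tuple(np.flatnonzero(row)) for row in H}
        assert pairs == {(0, 1), (1, 2), (0, 2)}
        assert np.all(H.sum(axis=1) == 0)  # each row is a pure difference

    def test_chain_has_n_minus_one_rows(self):
        H, _, _ = build_multilag_system(list(range(7)), self._const_pair(), max_lag=1)
        assert H.shape == (6, 7)

    def test_stationary_frames_give_zero_observations(self):
        _, Y, W = build_multilag_system(list(range(4)), self._const_pair(0.0), max_lag=3)
        assert np.all(Y == 0)
        assert np.all(W == 1)


class TestSolveWLS:
    def test_single_observation(self):
        est = solve_wls(np.array([[-1.0, 1.0]]), np.array([0.7]), np.array([1.0]))
        np.testing.assert_allclose(est.positions, [0.0, 0.7])

    def test_zero_observations_give_zero_positions(self):
        H, Y, W = build_multilag_system(
            list(range(5)), TestMultilagSystem._const_pair(0.0), max_lag=3
        )
        est = solve_wls(H, Y, W)
        np.testing.assert_allclose(est.positions, 0.0, atol=1e-12)

    def test_chain_reduces_to_cumulative_sum(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=9)
        H = np.zeros((9, 10))
        for r in range(9):
            H[r, r], H[r, r + 1] = -1.0, 1.0
        est = solve_wls(H, d, np.ones(9))
        np.testing.assert_allclose(est.positions, np.concatenate([[0], np.cumsum(d)]), atol=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_matches_dense_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        rows = [(i, i + 1) for i in range(n - 1)]
        rows += [tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(6)]
        rows = [r for r in rows if r[0] != r[1]]
        H = np.zeros((len(rows), n))
        for r, (i, j) in enumerate(rows):
            H[r, i], H[r, j] = -1.0, 1.0
        Y = rng.normal(size=len(rows))
        W = rng.uniform(0.1, 1.0, size=len(rows))
        est = solve_wls(H, Y, W, anchor=0)
        # independent oracle: explicit weighted normal equations on reduced system
        Hr = H[:, 1:]
        x = np.linalg.solve(Hr.T @ (W[:, None] * Hr), Hr.T @ (W * Y))
        np.testing.assert_allclose(est.positions[1:], x, rtol=1e-9, atol=1e-12)

    def test_disconnected_graph_names_components(self):
        H = np.zeros((2, 4))
        H[0, 0], H[0, 1] = -1, 1
        H[1, 2], H[1, 3] = -1, 1
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            solve_wls(H, np.zeros(2), np.ones(2))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            solve_wls(np.array([[-1.0, 1.0]]), np.array([0.0]), np.array([-0.1]))


class TestInterpolateEventPositions:
    def test_knot_midpoint_and_clamp(self):
        times = np.array([0.0, 1.0, 2.0])
        pos = np.array([0.0, 1.0e-3, 1.1e-3])
        out = interpolate_event_positions(pos, times, [1.0, 1.5, -0.5, 5.0])
        np.testing.assert_allclose(out, [1.0e-3, 1.05e-3, 0.0, 1.1e-3])
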