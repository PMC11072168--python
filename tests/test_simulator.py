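import numpy as np
import pytest
from scipy.signal import hilbert, welch

from sweptsa.acquisition import ArraySpec, TransmitEvent, make_sequence, make_trajectory
from sweptsa.simulate import (
    ScattererField,
    add_band_noise,
    depth_time_window,
    make_phantom,
    simulate_frame,
    simulate_sweep,
    ssa_resolution_cell,
)


def _box(lateral, depth):
    return np.array([list(lateral), [0.0, 0.0], list(depth)])


class TestPhantom:
    def test_expected_count_poisson(self, spec):
        # density chosen so the expected count is 1000
        cell = (1e-3, None, 1e-3)
        field = make_phantom(
            _box((-5e-3, 5e-3), (0.0, 10e-3)), density=10.0, resolution_cell=cell, seed=3
        )
        assert abs(field.n_scatterers - 1000) < 3 * np.sqrt(1000)

    def test_lesion_carved_out(self):
        center = (0.0, 0.0, 60e-3)
        field = make_phantom(
            _box((-10e-3, 10e-3), (50e-3, 70e-3)),
            density=10,
            resolution_cell=(0.5e-3, None, 0.5e-3),
            lesions=((center, 4e-3),),
            seed=0,
        )
        d = np.linalg.norm(field.positions - np.asarray(center), axis=1)
        assert np.all(d >= 4e-3)

    def test_point_target_dominates_speckle(self):
        field = make_phantom(
            _box((-10e-3, 10e-3), (95e-3, 105e-3)),
            density=10,
            resolution_cell=(0.5e-3, None, 0.5e-3),
            points=((0.0, 0.0, 100e-3),),
            seed=0,
        )
        strongest = np.argmax(np.abs(field.amplitudes))
        np.testing.assert_allclose(field.positions[strongest], [0.0, 0.0, 100e-3])
        speckle_rms = np.sqrt(np.mean(field.amplitudes[:-1] ** 2))
        assert np.abs(field.amplitudes[strongest]) > 30 * speckle_rms

    def test_point_inside_lesion_warns(self):
        with pytest.warns(UserWarning):
            make_phantom(
                _box((-10e-3, 10e-3), (50e-3, 70e-3)),
                density=10,
                resolution_cell=(0.5e-3, None, 0.5e-3),
                lesions=(((0.0, 0.0, 60e-3), 4e-3),),
                points=((0.0, 0.0, 60e-3),),
                seed=0,
            )

    def test_resolution_cell_default(self, spec):
        cx, cy, cz = ssa_resolution_cell(spec)
        lam = spec.wavelength
        assert cz == pytest.approx(lam / 2)
        assert cx == pytest.approx(lam * 60e-3 / 70e-3)
        assert cy is None


class TestSimulateFrame:
    def test_empty_field_is_silent(self, spec):
        empty = ScattererField(
            np.empty((0, 3)), np.empty(0), _box((-1e-3, 1e-3), (0.0, 1e-3))
        )
        frame = simulate_frame(empty, spec, TransmitEvent("plane"))
        assert np.all(frame.rf == 0)

    def test_on_axis_echo_arrives_at_two_z_over_c(self, spec, single_point_frame):
        frame = single_point_frame
        center = spec.n_elements // 2
        env = np.abs(hilbert(frame.rf[:, center].astype(float)))
        t_peak = frame.t0 + np.argmax(env) / frame.fs
        assert t_peak == pytest.approx(2 * 10e-3 / spec.sound_speed, abs=1.5 / frame.fs)

    def test_linearity_in_scatterers(self, spec):
        rng = np.random.default_rng(1)
        box = _box((-5e-3, 5e-3), (15e-3, 25e-3))
        pos = np.column_stack(
            [rng.uniform(-5e-3, 5e-3, 40), np.zeros(40), rng.uniform(15e-3, 25e-3, 40)]
        )
        amp = rng.standard_normal(40)
        t0, n = depth_time_window((15e-3, 25e-3), spec)
        kwargs = dict(t0=t0, n_samples=n)
        a = simulate_frame(ScattererField(pos[:20], amp[:20], box), spec, TransmitEvent("plane"), **kwargs)
        b = simulate_frame(ScattererField(pos[20:], amp[20:], box), spec, TransmitEvent("plane"), **kwargs)
        both = simulate_frame(ScattererField(pos, amp, box), spec, TransmitEvent("plane"), **kwargs)
        np.testing.assert_allclose(
            both.rf, a.rf + b.rf, atol=1e-6 * np.abs(both.rf).max()
        )

    def test_translation_equivariance(self, spec):
        # moving the array by +d equals moving the world by -d
        rng = np.random.default_rng(2)
        n = 100
        pos = np.column_stack(
            [rng.uniform(-6e-3, 6e-3, n), np.zeros(n), rng.uniform(15e-3, 25e-3, n)]
        )
        amp = rng.standard_normal(n)
        box = _box((-8e-3, 8e-3), (14e-3, 26e-3))
        d = 0.47e-3
        t0, ns = depth_time_window((14e-3, 26e-3), spec)
        moved_array = simulate_frame(
            ScattererField(pos, amp, box), spec, TransmitEvent("plane"),
            pose=d, t0=t0, n_samples=ns,
        )
        moved_world = simulate_frame(
            ScattererField(pos - [d, 0, 0], amp, box), spec, TransmitEvent("plane"),
            pose=0.0, t0=t0, n_samples=ns,
        )
        np.testing.assert_allclose(
            moved_array.rf, moved_world.rf, atol=1e-9 * np.abs(moved_array.rf).max()
        )

    def test_steered_plane_does_not_insonify_off_beam_targets(self, spec):
        # at 45 degrees the beam at 100 mm depth is ~100 mm off to the side
        field = ScattererField(
            np.array([[0.0, 0.0, 100e-3]]), np.array([1.0]),
            _box((-1e-3, 1e-3), (99e-3, 101e-3)),
        )
        frame = simulate_frame(field, spec, TransmitEvent("plane", angle=np.deg2rad(45)))
        assert np.abs(frame.rf).max() == 0


class TestSimulateSweep:
    def test_stationary_sweep_repeats_exactly(self, spec):
        field = ScattererField(
            np.array([[1e-3, 0.0, 20e-3]]), np.array([1.0]),
            _box((-2e-3, 2e-3), (18e-3, 22e-3)),
        )
        seq = make_sequence("alternating_center", spec)
        traj = make_trajectory(0.0, 0.01, 500.0)
        frames = simulate_sweep(field, spec, seq, traj, depth_window=(18e-3, 22e-3))
        assert len(frames) == 2 * traj.n_frames
        planes = [f for f in frames if f.event.kind == "plane"]
        np.testing.assert_array_equal(planes[0].rf, planes[1].rf)

    def test_event_poses_follow_trajectory(self, spec):
        seq = make_sequence("left_right", spec, frame_rate=500.0)
        traj = make_trajectory(5e-3, 0.1, 500.0)  # 50 repetitions, 0.1 mm steps
        field = ScattererField(
            np.array([[0.0, 0.0, 20e-3]]), np.array([1.0]),
            _box((-1e-3, 1e-3), (19e-3, 21e-3)),
        )
        frames = simulate_sweep(field, spec, seq, traj, depth_window=(18e-3, 22e-3))
        planes = [f for f in frames if f.event.kind == "plane"]
        steps = np.diff([f.pose for f in planes])
        np.testing.assert_allclose(steps, traj.extent / (traj.n_frames - 1))
        # diverging events occur later within the frame, so sit further along
        div = [f for f in frames if f.event.kind == "diverging"]
        assert div[0].pose > planes[0].pose


class TestBandNoise:
    def test_infinite_snr_is_identity(self, single_point_frame):
        out = add_band_noise(single_point_frame, np.inf, 10e-3)
        np.testing.assert_array_equal(out.rf, single_point_frame.rf)

    def test_zero_db_power_ratio(self, spec, tracking_pair):
        frames, _, _ = tracking_pair
        frame = frames[0]
        ratios = []
        for seed in range(5):
            noisy = add_band_noise(frame, 0.0, 20e-3, seed=seed)
            noise = noisy.rf.astype(float) - frame.rf.astype(float)
            t = frame.sample_times
            sel = np.abs(t - 2 * 20e-3 / spec.sound_speed) <= 10e-3 / spec.sound_speed
            ratios.append(
                10 * np.log10(np.mean(frame.rf[sel].astype(float) ** 2) / np.mean(noise[sel] ** 2))
            )
        assert np.all(np.abs(ratios) < 0.5)

    def test_noise_is_band_limited(self, tracking_pair):
        frames, _, _ = tracking_pair
        frame = frames[0]
        noisy = add_band_noise(frame, -20.0, 20e-3, seed=1)
        noise = (noisy.rf - frame.rf).astype(float).ravel(order="F")
        f, p = welch(noise, fs=frame.fs, nperseg=256)
        in_band = p[(f > 1.8e6) & (f < 4.2e6)].mean()
        out_band = p[f > 8e6].mean()
        assert in_band > 100 * out_band

    def test_seeds_change_noise_not_signal(self, single_point_frame):
        a = add_band_noise(single_point_frame, 0.0, 10e-3, seed=0)
        b = add_band_noise(single_point_frame, 0.0, 10e-3, seed=1)
        assert not np.array_equal(a.rf, b.rf)
        # same seed reproduces exactly
        c = add_band_noise(single_point_frame, 0.0, 10e-3, seed=0)
        np.testing.assert_array_equal(a.rf, c.rf)

    def test_silent_frame_rejected(self, spec):
        empty = ScattererField(
            np.empty((0, 3)), np.empty(0), _box((-1e-3, 1e-3), (0.0, 1e-3))
        )
        frame = simulate_frame(empty, spec, TransmitEvent("plane"), n_samples=2000)
        with pytest.raises(ValueError, match="SNR undefined"):
            add_band_noise(frame, 0.0, 20e-3)
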