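import numpy as np
import pytest

from rumblecam import beamforming as bf
from rumblecam.array_model import (
    ArrayGeometry,
    ImagePlane,
    PropagationModel,
    relative_delays,
    run_times,
)
from rumblecam.synthetic_data import (
    CallSpec,
    MultichannelRecording,
    SceneSpec,
    simulate_scene,
)


def integer_delay_scene(source, delays, n_pad=0):
    """Channels = source shifted by exact integer sample counts."""
    n = source.size + max(delays) + n_pad
    ch = np.zeros((len(delays), n))
    for i, d in enumerate(delays):
        ch[i, d : d + source.size] = source
    return MultichannelRecording(ch, 1000)


class TestDelayAndSum:
    def test_identical_channels_equidistant_point_identity(self):
        geom = ArrayGeometry(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        rec = MultichannelRecording(np.stack([x, x]), 1000)
        out = bf.delay_and_sum(rec, geom, [0, 0, 5.0], PropagationModel(), (0.0, 1.0))
        assert np.allclose(out.samples, x)

    def test_matches_brute_force_on_integer_delay_scene(self):
        # geometry whose run-time delays are exactly 0 and 3 samples at 1 kHz
        v, fs = 343.0, 1000
        d_extra = 3 * v / fs  # 1.029 m extra path for mic 2
        z = 8.0
        x_off = np.sqrt((z + d_extra) ** 2 - z**2)
        geom = ArrayGeometry(np.array([[0.0, 0, 0], [x_off, 0.0, 0.0]]))
        point = [0.0, 0.0, z]
        delays = relative_delays(run_times(geom, point, PropagationModel()))
        assert np.allclose(delays * fs, [0, 3], atol=1e-9)

        rng = np.random.default_rng(1)
        src = rng.standard_normal(800)
        rec = integer_delay_scene(src, [0, 3], n_pad=10)
        out = bf.delay_and_sum(rec, geom, point, PropagationModel(), (0.0, 0.8))
        # brute-force oracle: advance each channel by its delay, average
        oracle = 0.5 * (rec.samples[0, :800] + rec.samples[1, 3 : 3 + 800])
        interior = slice(5, 795)
        assert np.allclose(out.samples[interior], oracle[interior], rtol=1e-6)

    def test_off_source_focus_loses_coherence(self, star48, propagation):
        fs = 6000
        t = np.arange(fs) / fs
        src = np.sin(2 * np.pi * 800 * t)
        pos = np.array([0.0, -0.5, 8.0])
        rts = run_times(star48, pos, propagation)
        from rumblecam.synthetic_data import fractional_delay

        ch = np.stack([fractional_delay(src, rt * fs) for rt in rts])
        rec = MultichannelRecording(ch, fs)
        on = bf.delay_and_sum(rec, star48, pos, propagation, (0.3, 0.7))
        off = bf.delay_and_sum(
            rec, star48, pos + [2.0, 1.0, 0.0], propagation, (0.3, 0.7)
        )
        assert np.sqrt(np.mean(off.samples**2)) < np.sqrt(np.mean(on.samples**2))

    def test_window_out_of_range(self):
        rec = MultichannelRecording(np.zeros((2, 100)), 1000)
        geom = ArrayGeometry(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError):
            bf.delay_and_sum(rec, geom, [0, 0, 8.0], PropagationModel(), (0.0, 0.5))


class TestEffectiveSpl:
    def test_one_pascal_sine_is_90_97_db(self):
        t = np.arange(48000) / 48000
        sig = bf.BeamformedSignal(np.sin(2 * np.pi * 100 * t), 48000, np.zeros(3))
        assert bf.effective_spl(sig) == pytest.approx(90.97, abs=0.01)

    def test_doubling_amplitude_adds_6_db(self):
        t = np.arange(48000) / 48000
        s1 = bf.BeamformedSignal(np.sin(2 * np.pi * 50 * t), 48000, np.zeros(3))
        s2 = bf.BeamformedSignal(2 * np.sin(2 * np.pi * 50 * t), 48000, np.zeros(3))
        assert bf.effective_spl(s2) - bf.effective_spl(s1) == pytest.approx(
            6.02, abs=0.01
        )

    def test_zero_signal_returns_below_floor_sentinel(self):
        sig = bf.BeamformedSignal(np.zeros(100), 1000, np.zeros(3))
        assert bf.effective_spl(sig) == bf.BELOW_FLOOR_DB


@pytest.fixture(scope="module")
def nasal_scene(star48, propagation):
    plane = ImagePlane(nx=40, ny=30)
    spec = CallSpec("nasal", 2.0, 20.0, 2.0, 1.5, 52.0, seed=21)
    scene = SceneSpec(
        calls=[], array=star48, plane=plane, propagation=propagation, noise_spl=42.0
    )
    scene.calls = [(spec, scene.nasal_position)]
    rec, gt = simulate_scene(scene, seed=22)
    return scene, rec.decimate(8), gt


class TestAcousticMap:
    def test_single_source_peak_within_one_cell(self, nasal_scene, propagation):
        scene, rec, gt = nasal_scene
        mid = gt["calls"][0]["mid_time"]
        amap = bf.acoustic_map(
            rec, scene.array, scene.plane, propagation,
            (mid - 0.1, mid + 0.1), band=bf.ALLOCATION_BAND,
        )
        true_px = np.array(scene.plane.nearest_pixel(scene.nasal_position))
        assert np.abs(np.array(amap.peak_pixel) - true_px).max() <= 1

    def test_amplitude_scaling_shifts_every_pixel(self, nasal_scene, propagation):
        scene, rec, gt = nasal_scene
        mid = gt["calls"][0]["mid_time"]
        plane = ImagePlane(nx=8, ny=6)
        w = (mid - 0.05, mid + 0.05)
        m1 = bf.acoustic_map(rec, scene.array, plane, propagation, w)
        rec2 = MultichannelRecording(2.0 * rec.samples, rec.sample_rate)
        m2 = bf.acoustic_map(rec2, scene.array, plane, propagation, w)
        assert np.allclose(m2.spl_grid - m1.spl_grid, 6.02, atol=0.01)

    def test_noise_only_map_is_diffuse(self, star48, propagation):
        plane = ImagePlane(nx=20, ny=15)
        scene = SceneSpec(
            calls=[], array=star48, plane=plane, propagation=propagation,
            noise_spl=45.0,
        )
        rec, _ = simulate_scene(scene, seed=31)
        rec = rec.decimate(8)
        amap = bf.acoustic_map(
            rec, star48, plane, propagation, (0.1, 0.3), band=bf.ALLOCATION_BAND
        )
        assert amap.peak_db - np.median(amap.spl_grid) < 3.0

    def test_peak_field_is_grid_maximum(self, nasal_scene, propagation):
        scene, rec, gt = nasal_scene
        plane = ImagePlane(nx=8, ny=6)
        amap = bf.acoustic_map(rec, scene.array, plane, propagation, (0.3, 0.4))
        assert amap.peak_db == amap.spl_grid.max()


class TestMovieFrames:
    @pytest.mark.parametrize("rate,expected", [(25.0, 50), (5.0, 10)])
    def test_frame_count_matches_rate(self, star48, propagation, rate, expected):
        rec = MultichannelRecording(
            np.random.default_rng(0).standard_normal((48, 2 * 1000)) * 1e-3, 1000
        )
        plane = ImagePlane(nx=4, ny=3)
        frames = bf.movie_frames(rec, star48, plane, propagation, frame_rate=rate)
        assert len(frames) == expected

    def test_stationary_signal_gives_stable_frames(self, star48, propagation):
        rng = np.random.default_rng(5)
        rec = MultichannelRecording(
            np.tile(rng.standard_normal(1000) * 0.01, (48, 1)), 1000
        )
        plane = ImagePlane(nx=4, ny=3)
        frames = bf.movie_frames(rec, star48, plane, propagation, frame_rate=5.0)
        grids = np.stack([f.spl_grid for f in frames])
        assert grids.std(axis=0).max() < 1.0


class TestClassifyEmission:
    def _map_with_peak(self, plane, pos, peak_db=60.0, floor_db=30.0):
        grid = np.full((plane.ny, plane.nx), floor_db)
        iy, ix = plane.nearest_pixel(pos)
        grid[iy, ix] = peak_db
        return bf.AcousticMap(grid, plane, (0.0, 0.1))

    def test_peak_at_nasal_position(self, small_plane):
        nasal, oral = [0.0, -0.5, 8.0], [0.0, 0.3, 8.0]
        amap = self._map_with_peak(small_plane, nasal)
        res = bf.classify_emission(amap, nasal, oral)
        assert res.label == "nasal"
        assert res.peak_distance_nasal < res.peak_distance_oral

    def test_peak_far_from_both_is_ambiguous(self, small_plane):
        nasal, oral = [0.0, -0.5, 8.0], [0.0, 0.3, 8.0]
        amap = self._map_with_peak(small_plane, [1.5, 1.0, 8.0])
        assert bf.classify_emission(amap, nasal, oral).label == "ambiguous"

    def test_small_margin_is_ambiguous(self, small_plane):
        nasal, oral = [0.0, -0.5, 8.0], [0.0, 0.3, 8.0]
        grid = np.full((small_plane.ny, small_plane.nx), 50.0)
        iy, ix = small_plane.nearest_pixel(nasal)
        grid[iy, ix] = 50.03  # below the 0.07 dB margin
        amap = bf.AcousticMap(grid, small_plane, (0.0, 0.1))
        assert bf.classify_emission(amap, nasal, oral).label == "ambiguous"

    def test_overlapping_disks_rejected(self, small_plane):
        amap = self._map_with_peak(small_plane, [0.0, 0.0, 8.0])
        with pytest.raises(ValueError):
            bf.classify_emission(
                amap, [0.0, 0.0, 8.0], [0.0, 0.25, 8.0], radius=0.3
            )

    def test_simulated_oral_call_allocated_oral(self, star48, propagation):
        plane = ImagePlane(nx=40, ny=30)
        spec = CallSpec("oral", 0.7, 27.0, 2.7, 1.2, 74.0, seed=41)
        scene = SceneSpec(
            calls=[], array=star48, plane=plane, propagation=propagation,
            noise_spl=64.0,
        )
        scene.calls = [(spec, scene.oral_position)]
        rec, gt = simulate_scene(scene, seed=42)
        mid = gt["calls"][0]["mid_time"]
        amap = bf.acoustic_map(
            rec.decimate(8), star48, plane, propagation,
            (mid - 0.1, mid + 0.1), band=bf.ALLOCATION_BAND,
        )
        res = bf.classify_emission(amap, scene.nasal_position, scene.oral_position)
        assert res.label == "oral"


class TestPeakCallSpl:
    def test_round_trip_at_calibrated_level(self, nasal_scene, propagation):
        scene, rec, gt = nasal_scene
        call = gt["calls"][0]
        mid = call["mid_time"]
        # focused full-band signal at the source point carries the call SPL
        sig = bf.delay_and_sum(
            rec, scene.array, scene.nasal_position, propagation,
            (mid - 0.15, mid + 0.15),
        )
        assert bf.effective_spl(sig) == pytest.approx(52.0, abs=1.5)

    def test_midpoint_frame_selection(self, small_plane):
        grids = [np.full((3, 4), v, dtype=float) for v in (10.0, 30.0, 20.0)]
        plane = ImagePlane(nx=4, ny=3)
        frames = [
            bf.AcousticMap(g, plane, (k * 0.1, (k + 1) * 0.1))
            for k, g in enumerate(grids)
        ]
        assert bf.peak_call_spl(frames, (0.1, 0.2)) == 30.0
        with pytest.raises(ValueError):
            bf.peak_call_spl(frames, (5.0, 6.0))
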