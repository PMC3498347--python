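import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import normaltest

from rumblecam.array_model import ImagePlane, PropagationModel
from rumblecam.synthetic_data import (
    CallSpec,
    NASAL_STATS,
    ORAL_STATS,
    SceneSpec,
    fractional_delay,
    glottal_source,
    sample_call_population,
    simulate_scene,
    synthesize_call,
    vocal_tract_filter,
)


class TestGlottalSource:
    def test_zero_jitter_is_exactly_periodic(self):
        x = glottal_source(20.0, 0.0, 2.0, 48000, seed=0)
        pulses = np.flatnonzero(x > 0.999 * x.max())
        periods = np.diff(pulses)
        assert np.all(periods == 2400)  # 0.05 s at 48 kHz

    def test_deterministic_given_seed(self):
        a = glottal_source(19.7, 2.7, 2.94, 48000, seed=42)
        b = glottal_source(19.7, 2.7, 2.94, 48000, seed=42)
        assert np.array_equal(a, b)

    def test_autocorrelation_f0_near_target(self):
        f0 = 26.9
        x = glottal_source(f0, 1.0, 1.79, 48000, seed=7)
        x = x - x.mean()
        ac = sps.correlate(x, x, mode="full")[x.size - 1 :]
        lo, hi = int(48000 / 40), int(48000 / 15)
        lag = lo + int(np.argmax(ac[lo:hi]))
        assert 48000 / lag == pytest.approx(f0, rel=0.05)

    def test_invalid_duration_raises(self):
        with pytest.raises(ValueError):
            glottal_source(20.0, 0.0, 0.0, 48000)


class TestVocalTractFilter:
    @pytest.mark.parametrize(
        "vtl,targets",
        [(1.0, (87.5, 262.5)), (2.5, (35.0, 105.0)), (0.75, (116.7, 350.0))],
    )
    def test_white_noise_spectrum_peaks_at_tube_formants(self, vtl, targets):
        rng = np.random.default_rng(0)
        y = vocal_tract_filter(rng.standard_normal(48000 * 20), vtl, sample_rate=48000)
        f, p = sps.welch(y, fs=48000, nperseg=1 << 15, noverlap=1 << 14)
        db = sps.savgol_filter(10 * np.log10(p), 21, 2)
        for target in targets:
            m = (f > 0.8 * target) & (f < 1.2 * target)
            peak_f = f[m][np.argmax(db[m])]
            assert peak_f == pytest.approx(target, rel=0.05)

    def test_formant_above_nyquist_names_offender(self):
        with pytest.raises(ValueError, match="formant 2"):
            vocal_tract_filter(np.zeros(100), vtl=0.3, n_formants=2, sample_rate=1000)

    def test_nonpositive_vtl_raises(self):
        with pytest.raises(ValueError):
            vocal_tract_filter(np.zeros(10), vtl=0.0)


class TestSynthesizeCall:
    def test_length_and_determinism(self):
        spec = CallSpec("nasal", 2.0, 20.0, 1.0, 1.5, 52.0, seed=5)
        a = synthesize_call(spec)
        b = synthesize_call(spec)
        assert a.waveform.size == round(1.5 * 48000)
        assert np.array_equal(a.waveform, b.waveform)

    def test_calibrated_rms_matches_spl(self):
        spec = CallSpec("oral", 0.7, 27.0, 1.0, 2.0, 74.0, seed=6)
        call = synthesize_call(spec)
        core = call.waveform[4800:-4800]
        spl = 20 * np.log10(np.sqrt(np.mean(core**2)) / 20e-6)
        assert spl == pytest.approx(74.0, abs=0.2)

    def test_nasal_formants_near_tube_targets(self):
        # vtl 2.0 -> F1 43.75, F2 131.25 Hz on the call's own spectrum
        spec = CallSpec("nasal", 2.0, 20.0, 2.0, 3.0, 52.0, seed=8)
        call = synthesize_call(spec)
        f, p = sps.welch(call.waveform, fs=48000, nperseg=1 << 15)
        db = 10 * np.log10(p + 1e-30)
        for target in (43.75, 131.25):
            m = (f > 0.75 * target) & (f < 1.25 * target)
            assert db[m].max() > db[(f > 160) & (f < 180)].max()


class TestSampleCallPopulation:
    def test_population_means_match_study_statistics(self):
        specs = sample_call_population(1000, 1000, seed=3)
        nasal = [s for s in specs if s.emission == "nasal"]
        oral = [s for s in specs if s.emission == "oral"]
        assert np.mean([s.f0_mean for s in nasal]) == pytest.approx(19.7, abs=0.3)
        assert np.mean([s.f0_mean for s in oral]) == pytest.approx(26.9, abs=0.5)
        assert np.mean([s.spl_at_array for s in nasal]) == pytest.approx(51.9, abs=0.7)
        assert np.mean([s.spl_at_array for s in oral]) == pytest.approx(74.45, abs=0.8)

    def test_vtl_ranges_and_duration_floor(self):
        specs = sample_call_population(300, 300, seed=4)
        for s in specs:
            lo, hi = (
                (NASAL_STATS["vtl_low"], NASAL_STATS["vtl_high"])
                if s.emission == "nasal"
                else (ORAL_STATS["vtl_low"], ORAL_STATS["vtl_high"])
            )
            assert lo <= s.vtl <= hi
            assert s.duration >= 0.5

    def test_empty_population(self):
        assert sample_call_population(0, 0, seed=1) == []

    def test_deterministic(self):
        assert sample_call_population(5, 5, seed=9) == sample_call_population(
            5, 5, seed=9
        )


class TestFractionalDelay:
    def test_integer_delay_is_exact_shift(self):
        x = np.sin(np.arange(200) * 0.1)
        y = fractional_delay(x, 7.0)
        assert np.allclose(y[7:], x[:-7])
        assert np.allclose(y[:7], 0.0)

    def test_half_sample_delay_on_bandlimited_signal(self):
        n = np.arange(4000)
        x = np.sin(2 * np.pi * 0.02 * n)
        y = fractional_delay(x, 10.5)
        expect = np.sin(2 * np.pi * 0.02 * (n - 10.5))
        assert np.allclose(y[50:-50], expect[50:-50], atol=5e-3)


class TestSimulateScene:
    def _scene(self, geom, plane, calls, noise=None, **kw):
        return SceneSpec(
            calls=calls,
            array=geom,
            plane=plane,
            propagation=PropagationModel(),
            noise_spl=noise,
            **kw,
        )

    def test_equidistant_mics_get_identical_channels(self, small_plane):
        from rumblecam.array_model import ArrayGeometry

        geom = ArrayGeometry(np.array([[0.5, 0, 0], [-0.5, 0, 0]]))
        spec = CallSpec("nasal", 2.0, 20.0, 0.0, 0.6, 50.0, seed=2)
        scene = self._scene(geom, small_plane, [(spec, [0.0, 0.0, 8.0])])
        rec, _ = simulate_scene(scene, seed=0)
        assert np.allclose(rec.samples[0], rec.samples[1])

    def test_noise_only_channels_are_zero_mean_gaussian(self, star48, small_plane):
        scene = self._scene(star48, small_plane, [], noise=40.0)
        rec, _ = simulate_scene(scene, seed=11)
        ch = rec.samples[0]
        assert abs(ch.mean()) < 5 * ch.std() / np.sqrt(ch.size)
        assert normaltest(ch).pvalue > 1e-3

    def test_ground_truth_records_call_layout(self, star48, small_plane):
        spec = CallSpec("oral", 0.7, 27.0, 1.0, 0.8, 70.0, seed=3)
        scene = self._scene(star48, small_plane, [(spec, [0.0, 0.3, 8.0])])
        rec, gt = simulate_scene(scene, seed=1)
        assert len(gt["calls"]) == 1
        assert gt["calls"][0]["position"] == [0.0, 0.3, 8.0]
        assert gt["sample_rate"] == 48000
        assert rec.duration > spec.duration

    def test_scene_determinism(self, star48, small_plane):
        spec = CallSpec("nasal", 2.0, 20.0, 1.0, 0.6, 52.0, seed=5)
        scene = self._scene(star48, small_plane, [(spec, [0.0, -0.5, 8.0])], noise=35.0)
        r1, _ = simulate_scene(scene, seed=7)
        r2, _ = simulate_scene(scene, seed=7)
        assert np.array_equal(r1.samples, r2.samples)

    def test_identical_positions_rejected(self, star48, small_plane):
        with pytest.raises(ValueError):
            SceneSpec(
                calls=[],
                array=star48,
                plane=small_plane,
                nasal_position=[0, 0, 8.0],
                oral_position=[0, 0, 8.0],
            )


def test_invalid_call_specs_rejected():
    with pytest.raises(ValueError):
        CallSpec("sideways", 2.0, 20.0, 1.0, 1.0, 50.0)
    with pytest.raises(ValueError):
        CallSpec("nasal", -1.0, 20.0, 1.0, 1.0, 50.0)
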