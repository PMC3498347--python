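# rumblecam

Acoustic-camera analysis of elephant rumble vocalizations: delay-and-sum
source localization on a 48-channel star array, tube-model formant and
vocal-tract-length analysis, and LPC-descriptor classification of
nasally (trunk) versus orally (mouth) emitted rumbles — exercised end to
end on synthetic rumble scenes with known ground truth.

African elephants produce low-frequency rumbles (F0 ≈ 15–30 Hz) either
through the trunk or through the mouth. The two paths differ in length
by roughly a factor of three, and for a uniform tube closed at the
vocal folds and open at the radiating end the resonances sit at

    F_n = (2n − 1) · c / (4 L),          ΔF = c / (2 L),

so the emission route is readable from the first two formants, and the
apparent vocal tract length follows from the formant spacing as
**VTL = c / (2 (F2 − F1))** with c = 350 m/s. An acoustic camera — a
microphone array whose channels are delayed and summed to focus on each
pixel of an image plane,

    f(x, t) = (1/Σ w_i) Σ_i w_i f_i(t + Δ_i),    Δ_i = π_i − min π_i,

with per-pixel effective SPL `20·log10(rms/20 µPa)` — shows *where* on
the animal the call radiates from. This package implements that whole
chain for researchers in bioacoustics who want to study, teach or
stress-test the method without the original (undeposited) recordings:
a source–filter rumble synthesizer with the published per-class call
statistics, an array/scene simulator, the beamformer and allocation
rule, the per-call acoustic measurements, and the three-classifier
evaluation protocol.

## Worked example

```python
import rumblecam as rc
from rumblecam import beamforming as bf

geometry = rc.build_star_array()          # 48 mics, 3.4 m span
plane = rc.ImagePlane(nx=40, ny=30)       # 4 x 3 m at 8 m
model = rc.PropagationModel()             # 343 m/s, spherical spreading

spec = rc.CallSpec(emission="nasal", vtl=2.0, f0_mean=20.0,
                   f0_sd_within=2.0, duration=1.5, spl_at_array=52.0, seed=11)
scene = rc.SceneSpec(calls=[], array=geometry, plane=plane,
                     propagation=model, noise_spl=42.0)
scene.calls = [(spec, scene.nasal_position)]

recording, truth = rc.simulate_scene(scene, seed=12)
mid = truth["calls"][0]["mid_time"]
amap = bf.acoustic_map(recording.decimate(8), geometry, plane, model,
                       window=(mid - 0.1, mid + 0.1), band=bf.ALLOCATION_BAND)
print(bf.classify_emission(amap, scene.nasal_position, scene.oral_position))
```

prints

```
EmissionCall(label='nasal', peak_distance_nasal=0.0707...,
             peak_distance_oral=0.7516..., margin_db=0.1205...)
```

the map peak lands 7 cm from the trunk-tip reference point (one pixel),
75 cm from the mouth, so the call is allocated as nasally emitted; the
margin is the peak's excess in dB over the best pixel around the mouth.
Measuring the same call (`rc.featurize`) returns F1 = 46 Hz,
F2 = 119 Hz, hence VTL = 2.4 m — clearly the long trunk path, with the
single-call scatter the population tests quantify (median VTL error
5–10%). An oral call with vtl = 0.7 m measures F1 = 124, F2 = 372.5 Hz
and VTL = 0.70 m instead: a roughly threefold formant shift.

The `examples/` directory holds one short script per capability
(tube-model arithmetic, localization, feature measurement,
classification); each prints the numbers it computes and what they
mean. For an orchestrated run (scene synthesis → allocation → features
→ classification → summary) use the library's `rc.run_experiment` /
`rc.RunConfig`, or the thin CLI:

```bash
rumblecam run --seed 7 --out runs/demo
rumblecam report runs/demo
```

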