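"""Simulate a rumble scene and localize the emission point on the map.

A single nasal rumble is emitted at the trunk-tip position 8 m in front
of a 48-microphone star array, recorded with background noise, and then
beamformed: the effective-SPL map over the image plane should peak at
the trunk tip, and the allocation rule labels the call "nasal".
"""

import numpy as np

import rumblecam as rc
from rumblecam import beamforming as bf

geometry = rc.build_star_array()  # 48 mics, 3.4 m span
plane = rc.ImagePlane(distance=8.0, width=4.0, height=3.0, nx=40, ny=30)
model = rc.PropagationModel()

spec = rc.CallSpec(
    emission="nasal", vtl=2.0, f0_mean=20.0, f0_sd_within=2.0,
    duration=1.5, spl_at_array=52.0, seed=11,
)
scene = rc.SceneSpec(
    calls=[], array=geometry, plane=plane, propagation=model, noise_spl=42.0
)
scene.calls = [(spec, scene.nasal_position)]

recording, truth = rc.simulate_scene(scene, seed=12)
print(f"recorded {recording.n_channels} channels x {recording.duration:.2f} s")

mid = truth["calls"][0]["mid_time"]
recording = recording.decimate(8)
amap = bf.acoustic_map(
    recording, geometry, plane, model,
    window=(mid - 0.1, mid + 0.1), band=bf.ALLOCATION_BAND,
)
result = bf.classify_emission(amap, scene.nasal_position, scene.oral_position)

x, y = amap.peak_position[:2]
print(f"map peak: ({x:+.2f}, {y:+.2f}) m at {amap.peak_db:.1f} dB SPL")
print(f"true source: ({scene.nasal_position[0]:+.2f}, {scene.nasal_position[1]:+.2f}) m")
print(f"allocation: {result.label} (margin {result.margin_db:.2f} dB)")

# The peak lands on the trunk-tip pixel; the margin is the peak's excess
# over the best pixel around the mouth, small because a 3.4 m aperture
# at 8 m focuses these frequencies only weakly.

# calibrated SPL at the source point (full band, no allocation filter)
focused = bf.delay_and_sum(
    rc.MultichannelRecording(recording.samples, recording.sample_rate),
    geometry, scene.nasal_position, model, (mid - 0.2, mid + 0.2),
)
print(f"focused SPL at source: {bf.effective_spl(focused):.1f} dB "
      f"(calibrated {spec.spl_at_array} dB)")
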