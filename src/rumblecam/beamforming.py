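"""Delay-and-sum beamforming, effective-SPL acoustic maps and allocation.

Focusing the array on a point ``x`` reconstructs the time function

    f(x, t) = (1 / sum_i w_i) * sum_i w_i * f_i(t + Delta_i)

where ``Delta_i = pi_i - min(pi_i)`` are the relative run-time delays to
``x``: each channel is advanced by its extra travel time so a source at
``x`` sums coherently while off-focus sources decorrelate.  The division
by the weight sum keeps a perfectly focused source at its physical
amplitude, so the effective sound pressure level of the focused signal
(RMS over a window, in dB re 20 uPa) is directly interpretable.

A note on focusing power: at 8 m a 3.4 m aperture has essentially no
directivity below ~100 Hz (the relative delays are a tiny fraction of a
period), so acoustic maps of infrasonic calls rely on the calls'
harmonics in the hundreds-of-Hz-and-up range.  Mapping therefore
supports an analysis band-pass (default 150-1200 Hz for allocation
maps); SPL calibration checks use the unfiltered focused signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .array_model import ArrayGeometry, ImagePlane, PropagationModel, relative_delays, run_times
from .audio_io import P_REF
from .synthetic_data import MultichannelRecording

__all__ = [
    "BeamformedSignal",
    "AcousticMap",
    "EmissionCall",
    "BELOW_FLOOR_DB",
    "ALLOCATION_BAND",
    "delay_and_sum",
    "effective_spl",
    "acoustic_map",
    "movie_frames",
    "classify_emission",
    "peak_call_spl",
]

BELOW_FLOOR_DB = float("-inf")  # sentinel for an all-zero analysis window
ALLOCATION_BAND = (150.0, 1200.0)  # default analysis band for allocation maps, Hz


@dataclass
class BeamformedSignal:
    """Reconstructed time function f(x, t) at one focus point."""

    samples: np.ndarray
    sample_rate: int
    focus_point: np.ndarray

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class AcousticMap:
    """Effective-SPL image of the plane for one time window."""

    spl_grid: np.ndarray  # (ny, nx) dB SPL
    plane: ImagePlane
    window: tuple[float, float]
    peak_pixel: tuple[int, int] = field(init=False)  # (iy, ix)
    peak_db: float = field(init=False)

    def __post_init__(self) -> None:
        iy, ix = np.unravel_index(int(np.argmax(self.spl_grid)), self.spl_grid.shape)
        self.peak_pixel = (int(iy), int(ix))
        self.peak_db = float(self.spl_grid[iy, ix])

    @property
    def peak_position(self) -> np.ndarray:
        return self.plane.pixel_center(*self.peak_pixel)


@dataclass
class EmissionCall:
    """Nasal/oral allocation of one call from its acoustic map."""

    label: str  # "nasal" | "oral" | "ambiguous"
    peak_distance_nasal: float
    peak_distance_oral: float
    margin_db: float


def _sample_channels(
    rec: MultichannelRecording,
    delays_s: np.ndarray,
    weights: np.ndarray,
    t0: float,
    n_samples: int,
    clamp: bool = False,
) -> np.ndarray:
    """Weighted sum of channels sampled at ``t0 + k/fs + delay_i``.

    ``delays_s`` has shape (..., M); output has shape (..., n_samples).
    Linear interpolation between samples (exact at integer-sample
    delays).  With ``clamp`` the query positions are clipped to the
    recording, otherwise out-of-range queries raise.
    """
    fs = rec.sample_rate
    x = rec.samples
    n_rec = x.shape[1]
    delays = np.atleast_2d(delays_s)  # (P, M)
    k = np.arange(n_samples)
    wsum = weights.sum()
    acc = np.zeros((delays.shape[0], n_samples))
    base = t0 * fs + k  # (n,)
    for i in range(x.shape[0]):  # over M microphones
        pos = base[None, :] + delays[:, i : i + 1] * fs  # (P, n)
        if clamp:
            pos = np.clip(pos, 0, n_rec - 1)
        elif pos.min() < 0 or pos.max() > n_rec - 1:
            raise ValueError("analysis window (plus focus delays) exceeds recording")
        i0 = np.floor(pos).astype(np.intp)
        i0 = np.minimum(i0, n_rec - 2)
        frac = pos - i0
        ch = x[i]
        acc += weights[i] * ((1.0 - frac) * ch[i0] + frac * ch[i0 + 1])
    return acc / wsum


def delay_and_sum(
    rec: MultichannelRecording,
    geometry: ArrayGeometry,
    point,
    model: PropagationModel,
    window: tuple[float, float] | None = None,
) -> BeamformedSignal:
    """Focus the recording on ``point`` over ``window`` (seconds)."""
    if window is None:
        window = (0.0, rec.duration)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= rec.duration + 1e-9):
        raise ValueError(f"window {window} out of recording range")
    n = int(round((t1 - t0) * rec.sample_rate))
    if n < 1:
        raise ValueError("window contains no samples")
    delays = relative_delays(run_times(geometry, point, model))
    out = _sample_channels(rec, delays[None, :], geometry.weights, t0, n)
    return BeamformedSignal(out[0], rec.sample_rate, np.asarray(point, dtype=float))


def effective_spl(
    signal: BeamformedSignal, window: tuple[float, float] | None = None
) -> float:
    """Effective sound pressure level over a window, dB re 20 uPa.

    ``window`` is relative to the signal start; default is the whole
    signal.  An all-zero window returns the below-floor sentinel
    (``-inf``) rather than raising.
    """
    x = signal.samples
    if window is not None:
        a = int(round(window[0] * signal.sample_rate))
        b = int(round(window[1] * signal.sample_rate))
        x = x[a:b]
    if x.size < 1:
        raise ValueError("window contains no samples")
    rms = math.sqrt(float(np.mean(x**2)))
    if rms <= 0.0:
        return BELOW_FLOOR_DB
    return 20.0 * math.log10(rms / P_REF)


def _bandpass(rec: MultichannelRecording, band: tuple) -> MultichannelRecording:
    lo, hi = band
    nyq = rec.sample_rate / 2
    if hi is None or hi >= nyq:
        sos = sps.butter(4, lo / nyq, btype="high", output="sos")
    else:
        sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    return MultichannelRecording(sps.sosfiltfilt(sos, rec.samples, axis=1), rec.sample_rate)


def acoustic_map(
    rec: MultichannelRecording,
    geometry: ArrayGeometry,
    plane: ImagePlane,
    model: PropagationModel,
    window: tuple[float, float],
    band: tuple | None = None,
    _chunk: int = 2_000_000,
) -> AcousticMap:
    """Effective-SPL map of the plane for one time window.

    Applies :func:`delay_and_sum` + :func:`effective_spl` at every
    pixel centre.  ``band`` optionally band-passes the recording first
    (see module note on low-frequency focusing); pass
    ``ALLOCATION_BAND`` for allocation maps, ``None`` for calibrated
    full-band SPL values.
    """
    if band is not None:
        rec = _bandpass(rec, band)
    t0, t1 = window
    fs = rec.sample_rate
    n = int(round((t1 - t0) * fs))
    if n < 1:
        raise ValueError("window contains no samples")
    pts = plane.pixel_centers().reshape(-1, 3)
    # relative delays per pixel: (P, M)
    dists = np.linalg.norm(
        pts[:, None, :] - geometry.mic_positions[None, :, :], axis=2
    )
    delays = dists / model.speed_of_sound
    delays -= delays.min(axis=1, keepdims=True)
    rows_per_block = max(1, _chunk // max(n, 1))
    spl = np.empty(pts.shape[0])
    for a in range(0, pts.shape[0], rows_per_block):
        b = min(a + rows_per_block, pts.shape[0])
        y = _sample_channels(rec, delays[a:b], geometry.weights, t0, n, clamp=True)
        rms = np.sqrt(np.mean(y**2, axis=1))
        with np.errstate(divide="ignore"):
            spl[a:b] = 20.0 * np.log10(rms / P_REF)
    return AcousticMap(spl.reshape(plane.ny, plane.nx), plane, (t0, t1))


def movie_frames(
    rec: MultichannelRecording,
    geometry: ArrayGeometry,
    plane: ImagePlane,
    model: PropagationModel,
    frame_rate: float = 25.0,
    band: tuple | None = None,
) -> list[AcousticMap]:
    """Non-overlapping maps at ``frame_rate``; floor(duration*rate) frames."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if band is not None:
        rec = _bandpass(rec, band)
    n_frames = int(np.floor(rec.duration * frame_rate))
    frames = []
    for k in range(n_frames):
        w = (k / frame_rate, (k + 1) / frame_rate)
        frames.append(acoustic_map(rec, geometry, plane, model, w, band=None))
    return frames


def classify_emission(
    amap: AcousticMap,
    nasal_pos,
    oral_pos,
    radius: float = 0.3,
    margin_db: float = 0.07,
) -> EmissionCall:
    """Allocate a call to nasal or oral emission from its acoustic map.

    The call is nasal if the map peak lies within ``radius`` of the
    trunk-tip reference point, oral if within ``radius`` of the mouth
    point, and ambiguous otherwise -- or when the peak exceeds the best
    pixel around the competing point by less than ``margin_db`` (the
    diffuse-map guard; diffuse maps are reported, not forced).

    The default margin (0.07 dB) is calibrated to this array's
    measured map contrast: a 3.4 m aperture focused at 8 m separates
    the trunk-tip and mouth points by only about 0.1-0.4 dB in the
    150-1200 Hz band, while the spatial ripple of a diffuse noise map
    stays below ~0.05 dB; the guard sits between the two populations.
    """
    nasal_pos = np.asarray(nasal_pos, dtype=float)
    oral_pos = np.asarray(oral_pos, dtype=float)
    if np.linalg.norm(nasal_pos[:2] - oral_pos[:2]) < 2 * radius:
        raise ValueError("candidate disks overlap: positions closer than 2*radius")
    peak_xy = amap.peak_position[:2]
    d_nasal = float(np.linalg.norm(peak_xy - nasal_pos[:2]))
    d_oral = float(np.linalg.norm(peak_xy - oral_pos[:2]))

    pts = amap.plane.pixel_centers()[..., :2]

    def disk_max(center):
        mask = np.linalg.norm(pts - center[None, None, :2], axis=-1) <= radius
        if not mask.any():
            return BELOW_FLOOR_DB
        return float(amap.spl_grid[mask].max())

    if d_nasal <= radius:
        label, rival = "nasal", oral_pos
    elif d_oral <= radius:
        label, rival = "oral", nasal_pos
    else:
        return EmissionCall("ambiguous", d_nasal, d_oral, 0.0)
    margin = amap.peak_db - disk_max(rival)
    if margin < margin_db:
        label = "ambiguous"
    return EmissionCall(label, d_nasal, d_oral, float(margin))


def peak_call_spl(
    frames: list[AcousticMap], call_window: tuple[float, float]
) -> float:
    """Peak map SPL at the temporal midpoint of a call.

    Takes the maximum map-peak over the frame(s) whose window contains
    the midpoint of ``call_window``.
    """
    t_mid = 0.5 * (call_window[0] + call_window[1])
    hits = [
        f.peak_db
        for f in frames
        if f.window[0] - 1e-9 <= t_mid <= f.window[1] + 1e-9
    ]
    if not hits:
        raise ValueError("no frame overlaps the call midpoint")
    return max(hits)
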