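"""WAV input/output with a fixed pressure calibration.

All in-memory waveforms in this package are sound pressures in pascals.
WAV files are written as 32-bit float with full scale (sample value 1.0)
equal to 20 Pa, so dB SPL = 20*log10(rms_Pa / 20e-6) is recoverable from
file content alone.  20 Pa full scale puts a 120 dB SPL sine at 0 dBFS,
comfortably above any rumble level handled here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

FULL_SCALE_PA = 20.0
P_REF = 20e-6  # reference pressure, Pa (dB SPL reference)


def write_wav(path, samples_pa: np.ndarray, sample_rate: int) -> None:
    """Write mono (N,) or multichannel (M, N) pressure samples to WAV."""
    x = np.asarray(samples_pa, dtype=np.float64) / FULL_SCALE_PA
    if x.ndim == 2:  # scipy expects (N, channels)
        x = x.T
    wavfile.write(str(path), int(sample_rate), x.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV written by :func:`write_wav`; returns (pressure, rate).

    Multichannel files come back as (M, N).  Integer PCM files are
    rescaled assuming the same full-scale = 20 Pa convention.
    """
    rate, data = wavfile.read(str(Path(path)))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.T
    return data * FULL_SCALE_PA, int(rate)


def spl_db(rms_pa: float) -> float:
    """dB SPL (re 20 uPa) of an RMS pressure; -inf for zero."""
    if rms_pa <= 0:
        return float("-inf")
    return 20.0 * np.log10(rms_pa / P_REF)
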