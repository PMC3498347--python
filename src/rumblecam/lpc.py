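"""Linear predictive coding: autocorrelation method, envelope, formant roots.

An order-p LPC model fits the signal with an all-pole filter
``H(z) = g / A(z)``, ``A(z) = 1 + a_1 z^-1 + ... + a_p z^-p``.  The
coefficients solve the Toeplitz normal equations built from the sample
autocorrelation (Levinson-Durbin via ``scipy.linalg.solve_toeplitz``).
Resonance (formant) candidates are the complex roots of ``A`` with small
bandwidth.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz

__all__ = ["lpc_coefficients", "lpc_envelope_db", "lpc_formant_candidates"]


def lpc_coefficients(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Return (a, gain): ``a`` of length order+1 with a[0] = 1.

    ``gain`` is the RMS of the model residual, so the model PSD matches
    the signal PSD in scale.  Degenerate (near-silent) frames fall back
    to a flat model.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= order:
        raise ValueError(f"need more than order={order} samples, got {n}")
    r = np.correlate(x, x, mode="full")[n - 1 : n + order] / n
    if r[0] <= 0 or not np.isfinite(r[0]):
        return np.r_[1.0, np.zeros(order)], 0.0
    # tiny diagonal load guards singular autocorrelation (pure sinusoids)
    r0 = r.copy()
    r0[0] *= 1.0 + 1e-9
    try:
        a_tail = solve_toeplitz((r0[:-1], r0[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return np.r_[1.0, np.zeros(order)], float(np.sqrt(r[0]))
    a = np.r_[1.0, a_tail]
    err = r[0] + a_tail @ r[1:]
    gain = float(np.sqrt(max(err, 1e-20)))
    return a, gain


def lpc_envelope_db(
    a: np.ndarray, gain: float, freqs_hz: np.ndarray, sample_rate: float
) -> np.ndarray:
    """Model magnitude response ``20*log10|g / A(e^{jw})|`` at given Hz."""
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / sample_rate
    z = np.exp(-1j * np.outer(w, np.arange(a.size)))
    mag = np.abs(gain) / np.maximum(np.abs(z @ a), 1e-12)
    return 20.0 * np.log10(np.maximum(mag, 1e-12))


def lpc_formant_candidates(
    a: np.ndarray, sample_rate: float, max_bandwidth_hz: float = 150.0
) -> list[tuple[float, float]]:
    """(frequency, bandwidth) pairs from the roots of A(z), ascending in f.

    Keeps roots in the upper half plane with positive frequency and
    -3 dB bandwidth below ``max_bandwidth_hz`` (wide roots model
    spectral tilt, not resonances).
    """
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-9]
    out = []
    for r in roots:
        f = float(np.angle(r) * sample_rate / (2 * np.pi))
        mag = min(abs(r), 1 - 1e-12)
        bw = float(-np.log(mag) * sample_rate / np.pi)
        if f > 0 and bw < max_bandwidth_hz:
            out.append((f, bw))
    return sorted(out)
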