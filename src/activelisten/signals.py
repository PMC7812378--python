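"""Shared signal-processing primitives.

Small helpers used by both the forward (synthesis) and inverse
(recognition/segmentation) paths: orthonormal DCT bases evaluated at an
arbitrary number of points, a frequency-domain Gaussian band-pass, and
the smoothed amplitude envelope.  Keeping these in one place guarantees
that synthesis calibrates amplitude against exactly the same envelope
the segmentation stage later measures.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "dct_basis",
    "gaussian_bandpass",
    "smoothed_envelope",
    "round_half_away",
]


def dct_basis(n_points: int, n_coeffs: int) -> np.ndarray:
    """DCT-II basis evaluated at ``n_points``, first ``n_coeffs`` columns.

    Columns are orthonormal whenever ``n_points >= n_coeffs``, so the
    basis doubles as interpolator (synthesis) and projector (analysis):
    ``U.T @ U == I``.
    """
    if n_points < 1 or n_coeffs < 1:
        raise ValueError("basis dimensions must be positive")
    i = np.arange(n_points)[:, None]
    p = np.arange(n_coeffs)[None, :]
    basis = np.cos(np.pi * p * (2 * i + 1) / (2 * n_points))
    basis *= np.sqrt(2.0 / n_points)
    basis[:, 0] /= np.sqrt(2.0)
    return basis


def gaussian_bandpass(x: np.ndarray, rate: float, centre: float,
                      sigma: float) -> np.ndarray:
    """Zero-phase band-pass with a Gaussian passband in the frequency domain."""
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    window = np.exp(-0.5 * ((freqs - centre) / sigma) ** 2)
    return np.fft.irfft(np.fft.rfft(x) * window, n=n)


def smoothed_envelope(x: np.ndarray, rate: float, highpass: float = 100.0,
                      sigma: float = 0.016) -> np.ndarray:
    """Amplitude envelope: high-pass, rectify, Gaussian-smooth, subtract min.

    ``sigma`` is the smoothing kernel width in seconds.  The output is
    non-negative and has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot take the envelope of an empty signal")
    if np.allclose(x, 0.0):
        return np.zeros_like(x)
    if highpass > 0:
        sos = sps.butter(4, highpass, btype="highpass", fs=rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    env = gaussian_filter1d(np.abs(x), sigma * rate, mode="nearest")
    env = env - env.min()
    return np.maximum(env, 0.0)


def round_half_away(x: float) -> int:
    """Round half away from zero (unlike banker's rounding of ``round``)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))
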