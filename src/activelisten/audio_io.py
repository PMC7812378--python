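"""WAV reading and writing.

Audio moves in and out of the package as RIFF PCM WAV.  Output is
peak-normalised 16-bit PCM with the scale factor recorded in a JSON
sidecar, so the numeric waveform can be recovered exactly up to
quantisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .synthesis import AcousticEpoch

__all__ = ["read_wav", "write_wav"]

log = logging.getLogger(__name__)

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): 2 ** 7}


def read_wav(path: str | Path, target_rate: float | None = None,
             ) -> AcousticEpoch:
    """Read a mono (or channel-averaged) waveform scaled to [-1, 1].

    Multichannel input is averaged with a warning; when ``target_rate``
    differs from the file rate the signal is polyphase-resampled.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # unreadable/compressed/truncated
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path.name}: averaging {data.shape[1]} channels "
                      "to mono", RuntimeWarning, stacklevel=2)
        data = data.mean(axis=1)
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[np.dtype(data.dtype)]
        offset = scale if data.dtype == np.uint8 else 0
        data = (data.astype(float) - offset) / scale
    else:
        data = data.astype(float)
    if target_rate is not None and target_rate != rate:
        from math import gcd
        g = gcd(int(target_rate), int(rate))
        log.info("resampling %s from %d Hz to %d Hz", path.name, rate,
                 int(target_rate))
        data = resample_poly(data, int(target_rate) // g, int(rate) // g)
        rate = int(target_rate)
    return AcousticEpoch(samples=data, rate=float(rate))


def write_wav(epoch: AcousticEpoch, path: str | Path) -> None:
    """Write peak-normalised 16-bit PCM plus a JSON sidecar with the scale."""
    path = Path(path)
    x = np.asarray(epoch.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples")
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    scaled = x / peak if peak > 0 else x
    pcm = np.round(scaled * (2 ** 15 - 1)).astype(np.int16)
    wavfile.write(path, int(epoch.rate), pcm)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"peak": peak, "rate": epoch.rate,
                                   "n_samples": int(x.size)}, indent=1))
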