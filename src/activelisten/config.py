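"""Model configuration.

A single dataclass holds every tunable constant of the generative model,
the recognition front end, the envelope-based segmentation scheme and the
belief-updating (neuronal) simulator, so that a run is fully specified by
a (config, seed) pair.  All constants that shape behaviour — the 1/16
envelope threshold fraction, the 1250 ms analysis epoch, the eight
frequency bins per formant interval, the 16 ms belief-update bin and the
1–16 Hz ERP pass band — live here rather than being hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    #: audio sample rate (Hz)
    rate: int = 22050
    #: number of formant-grid frequency bins
    nf: int = 64
    #: number of frequency DCT coefficients of the log time-frequency image;
    #: an analysis segment of one first-formant period resolves only the
    #: slowest few frequency components of the 64-bin trajectory, so the
    #: lexical code is kept within that invertible subspace
    nq_f: int = 3
    #: number of temporal DCT coefficients
    nq_t: int = 8
    #: prior expectation of the speaker fundamental frequency (Hz)
    f0_prior: float = 100.0
    #: reference first-formant frequency at formant scale 1 (Hz)
    f1_reference: float = 500.0
    #: formant-grid bins per inter-formant interval (grid spacing = F1 / this)
    bins_per_interval: int = 8
    #: hard limits on the instantaneous fundamental frequency (Hz)
    f0_min: float = 50.0
    f0_max: float = 500.0
    #: Gaussian smoothing width of the amplitude envelope (s)
    envelope_sigma: float = 0.016
    #: high-pass cutoff applied before envelope extraction (Hz)
    envelope_highpass: float = 100.0
    #: envelope threshold as a fraction of the epoch maximum
    threshold_fraction: float = 1.0 / 16.0
    #: length of the boundary-search analysis epoch (s)
    epoch_len: float = 1.25
    #: plausible word duration range (s)
    min_dur: float = 0.2
    max_dur: float = 1.0
    #: ERP band-pass edges (Hz)
    erp_band: tuple[float, float] = (1.0, 16.0)
    #: belief-update time bin (s)
    dt: float = 0.016
    #: gradient-flow rate constant
    kappa: float = 0.25
    #: number of belief-update steps per word (~500 ms at 16 ms bins)
    n_steps: int = 32
    #: noise variance multiplier (0 = clean speech)
    gamma: float = 0.0
    #: floor applied to categorical beliefs in the neuronal simulator;
    #: log-expectations saturate at log(belief_floor)
    belief_floor: float = math.exp(-8.0)
    #: candidate formant scales examined during recognition
    scale_grid: tuple[float, ...] = (0.8, 1.0, 1.2)
    #: default word duration when nothing else is known (s)
    default_duration: float = 0.5
    #: seed for every stochastic operation
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        if self.rate <= 0 or self.nf <= 0 or self.nq_f <= 0 or self.nq_t <= 0:
            raise ValueError("rate and coefficient shapes must be positive")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.erp_band[1] >= 0.5 / self.dt:
            raise ValueError("erp_band upper edge must be below the Nyquist "
                             "frequency of the belief-update rate")
        if self.min_dur <= 0 or self.max_dur <= self.min_dur:
            raise ValueError("need 0 < min_dur < max_dur")

    # ------------------------------------------------------------------
    def formant_grid(self, scale: float = 1.0) -> np.ndarray:
        """Formant frequencies f_j = scale * F1 * (1 + j/bins), j = 0..nf-1."""
        f1 = scale * self.f1_reference
        j = np.arange(self.nf)
        return f1 * (1.0 + j / self.bins_per_interval)

    @property
    def coeff_shape(self) -> tuple[int, int]:
        return (self.nq_f, self.nq_t)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erp_band"] = list(self.erp_band)
        d["scale_grid"] = list(self.scale_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in d.items() if k in known}
        if "erp_band" in kw:
            kw["erp_band"] = tuple(kw["erp_band"])
        if "scale_grid" in kw:
            kw["scale_grid"] = tuple(kw["scale_grid"])
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=False)
                if path.suffix in {".yml", ".yaml"}
                else json.dumps(self.to_dict(), indent=2))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        d = (yaml.safe_load(text) if path.suffix in {".yml", ".yaml"}
             else json.loads(text))
        return cls.from_dict(d)
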