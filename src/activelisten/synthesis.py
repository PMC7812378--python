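"""The forward generative model: from discrete causes to a waveform.

A spoken word is generated in four steps:

1. The prosodic inflection and speaker fundamental frequency define an
   instantaneous F0 contour; its reciprocal gives the spacing of glottal
   transients over the word's duration.
2. The word's lexical coefficients (a compact DCT parameterisation of the
   log time-frequency trajectory) are expanded — after scaling by the
   timbre parameter and exponentiation — into a strictly positive
   spectral trajectory ``W`` with one column per transient.
3. Each transient is a time-symmetric shockwave: a raised-cosine windowed
   sum of cosines at the formant-grid frequencies, weighted by the
   corresponding column of ``W``.  Its duration is one period of the
   first formant, which bounds the longest formant wavelength.
4. Transients are overlap-added at the transient centre times and the
   result is scaled so that the peak of its smoothed amplitude envelope
   equals the prosodic amplitude parameter.

Everything is deterministic given parameters; the only randomness lives
in :func:`synthesize_utterance`, which jitters parameters around lexicon
means under a caller-supplied seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ModelConfig
from .lexicon import Lexicon
from .signals import dct_basis, round_half_away, smoothed_envelope

__all__ = [
    "SpeakerState",
    "ProsodyState",
    "WordParameters",
    "SpectralTrajectory",
    "AcousticEpoch",
    "fundamental_contour",
    "spectral_trajectory",
    "render_transient",
    "synthesize_word",
    "synthesize_utterance",
]


# ----------------------------------------------------------------------
@dataclass
class SpeakerState:
    """Who is speaking: average F0 (Hz) and vocal-tract formant scaling."""

    f0_mean: float = 100.0
    formant_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.f0_mean <= 0 or self.formant_scale <= 0:
            raise ValueError("speaker parameters must be positive")


@dataclass
class ProsodyState:
    """How it is spoken: gain, duration, spectral contrast, F0 contour.

    ``inflection`` holds (relative offset, slope, curvature) of the F0
    contour on an orthogonalised quadratic basis over normalised time.
    """

    amplitude: float = 1.0
    duration: float = 0.5
    timbre: float = 1.0
    inflection: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.inflection = np.asarray(self.inflection, dtype=float)
        if self.inflection.shape != (3,):
            raise ValueError("inflection must be a 3-vector")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.timbre < 0:
            raise ValueError("timbre must be non-negative")


@dataclass
class WordParameters:
    """Continuous causes of one word."""

    coeffs: np.ndarray
    prosody: ProsodyState = field(default_factory=ProsodyState)
    speaker: SpeakerState = field(default_factory=SpeakerState)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("lexical coefficients must be finite")


@dataclass
class SpectralTrajectory:
    """Strictly positive formant-bin x transient spectral weights."""

    W: np.ndarray
    formant_grid: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.formant_grid = np.asarray(self.formant_grid, dtype=float)
        if np.any(self.W <= 0):
            raise ValueError("spectral weights must be strictly positive")
        if len(self.formant_grid) != self.W.shape[0]:
            raise ValueError("formant grid must match the number of bins")
        if np.any(np.diff(self.formant_grid) <= 0):
            raise ValueError("formant grid must be ascending")


@dataclass
class AcousticEpoch:
    """A sampled waveform segment."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def slice(self, onset: int, offset: int) -> "AcousticEpoch":
        return AcousticEpoch(self.samples[onset:offset], self.rate)


# ----------------------------------------------------------------------
def inflection_basis(u: np.ndarray) -> np.ndarray:
    """Orthogonalised quadratic basis over normalised time u in [0, 1].

    Columns: constant offset, centred slope, centred-and-orthogonalised
    curvature (the 1/12 term removes the mean of the squared slope term).
    """
    u = np.asarray(u, dtype=float)
    return np.stack([np.ones_like(u), u - 0.5, (u - 0.5) ** 2 - 1.0 / 12.0],
                    axis=-1)


def instantaneous_f0(u: np.ndarray, speaker: SpeakerState,
                     prosody: ProsodyState,
                     f0_min: float = 50.0, f0_max: float = 500.0,
                     warn: bool = True) -> np.ndarray:
    """F0(u) = f0_mean * (1 + inflection . basis(u)), clipped to [f0_min, f0_max]."""
    basis = inflection_basis(u)
    f0 = speaker.f0_mean * (1.0 + basis @ prosody.inflection)
    if warn and np.any(f0 <= 0):
        warnings.warn("inflection drives F0 non-positive; clipping",
                      RuntimeWarning, stacklevel=2)
    return np.clip(f0, f0_min, f0_max)


def fundamental_contour(speaker: SpeakerState, prosody: ProsodyState,
                        f0_min: float = 50.0,
                        f0_max: float = 500.0) -> np.ndarray:
    """Transient centre times (s): intervals accumulate the reciprocal F0.

    Starting from t = 0, each successive centre is one fundamental period
    (evaluated at the current normalised time) after the previous one;
    accumulation stops once the word duration is exceeded.
    """
    if prosody.duration <= 0:
        raise ValueError("duration must be positive")
    centres = []
    t = 0.0
    warned = False
    while t < prosody.duration:
        centres.append(t)
        u = np.array(t / prosody.duration)
        f0 = instantaneous_f0(u, speaker, prosody, f0_min, f0_max,
                              warn=not warned)
        warned = True
        t = t + 1.0 / float(f0)
    return np.asarray(centres)


def spectral_trajectory(coeffs: np.ndarray, timbre: float, k: int,
                        formant_grid: np.ndarray) -> SpectralTrajectory:
    """Expand lexical coefficients into K spectral columns.

    ``W = exp(timbre * U_f @ coeffs @ U_t.T)`` where the frequency basis
    has one row per formant bin and the temporal DCT basis is evaluated
    at ``k`` points — a duration-normalised resampling of the word's
    temporal profile.
    """
    if k < 1:
        raise ValueError("need at least one transient column")
    coeffs = np.asarray(coeffs, dtype=float)
    nq_f, nq_t = coeffs.shape
    nf = len(formant_grid)
    u_f = dct_basis(nf, nq_f)
    u_t = dct_basis(max(k, 1), nq_t)
    log_w = timbre * (u_f @ coeffs @ u_t.T)
    return SpectralTrajectory(W=np.exp(log_w),
                              formant_grid=np.asarray(formant_grid, float))


def render_transient(column: np.ndarray, formant_grid: np.ndarray,
                     f1: float, rate: float) -> np.ndarray:
    """Render one time-symmetric transient.

    The segment spans one period of the first formant (``round(rate/f1)``
    samples, rounded half away from zero) and is a raised-cosine windowed
    sum of cosines at the grid frequencies, phase-aligned at the segment
    midpoint — hence exactly equal to its own time reverse.
    """
    if f1 <= 0:
        raise ValueError("first formant frequency must be positive")
    formant_grid = np.asarray(formant_grid, dtype=float)
    if np.any(formant_grid >= rate / 2):
        raise ValueError("formant grid exceeds the Nyquist frequency")
    column = np.asarray(column, dtype=float)
    n = round_half_away(rate / f1)
    t = np.arange(n, dtype=float)
    t_mid = (n - 1) / 2.0
    window = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - t_mid) / n))
    phases = 2.0 * np.pi * np.outer(formant_grid, (t - t_mid) / rate)
    return window * (column @ np.cos(phases))


def synthesize_word(params: WordParameters,
                    config: ModelConfig) -> AcousticEpoch:
    """Overlap-add transients into a word-length buffer and set its gain.

    The buffer is normalised so the peak of its smoothed amplitude
    envelope equals ``prosody.amplitude``; the recognition path measures
    amplitude with the same envelope, making the gain a round-trippable
    parameter.
    """
    prosody, speaker = params.prosody, params.speaker
    centres = fundamental_contour(speaker, prosody,
                                  config.f0_min, config.f0_max)
    k = len(centres)
    grid = config.formant_grid(speaker.formant_scale)
    traj = spectral_trajectory(params.coeffs, prosody.timbre, k, grid)
    f1 = speaker.formant_scale * config.f1_reference
    n_total = round_half_away(prosody.duration * config.rate)
    buf = np.zeros(n_total)
    for idx, centre in enumerate(centres):
        seg = render_transient(traj.W[:, idx], grid, f1, config.rate)
        start = round_half_away(centre * config.rate) - len(seg) // 2
        lo, hi = max(start, 0), min(start + len(seg), n_total)
        if hi > lo:
            buf[lo:hi] += seg[lo - start:hi - start]
    env = smoothed_envelope(buf, config.rate, config.envelope_highpass,
                            config.envelope_sigma)
    peak = env.max()
    if peak > 0:
        buf *= prosody.amplitude / peak
    return AcousticEpoch(samples=buf, rate=config.rate)


# ----------------------------------------------------------------------
def sample_word_parameters(label: str, lexicon: Lexicon,
                           config: ModelConfig,
                           rng: np.random.Generator,
                           duration: float | None = None,
                           jitter_scale: float = 0.25) -> WordParameters:
    """Draw continuous word parameters around the lexicon entry mean.

    Coefficients get Gaussian jitter proportional to the entry's
    per-coefficient standard deviation (1/sqrt(precision)), scaled down
    by ``jitter_scale``: the trained variance also absorbs recognition
    noise (alignment, spectral-analysis error), which is not production
    variability, so speaking with the full variance would over-disperse
    tokens.  Prosody and speaker parameters get mild proportional jitter
    so no two tokens of a word are acoustically identical.
    """
    entry = lexicon[label]
    sd = jitter_scale / np.sqrt(entry.coeff_precision)
    coeffs = entry.coeff_mean + rng.standard_normal(entry.shape) * sd
    base_dur = duration if duration is not None else lexicon.duration_of(
        label, config.default_duration)
    prosody = ProsodyState(
        amplitude=float(np.exp(rng.normal(0.0, 0.05))),
        duration=float(np.clip(base_dur * np.exp(rng.normal(0.0, 0.03)),
                               config.min_dur, config.max_dur)),
        timbre=1.0,
        inflection=rng.normal(0.0, [0.01, 0.02, 0.02]),
    )
    speaker = SpeakerState(
        f0_mean=float(config.f0_prior * np.exp(rng.normal(0.0, 0.03))),
        formant_scale=1.0,
    )
    return WordParameters(coeffs=coeffs, prosody=prosody, speaker=speaker)


def synthesize_utterance(words: Sequence[str | WordParameters],
                         lexicon: Lexicon | None,
                         config: ModelConfig,
                         gap: float = 0.0,
                         rng_seed: int | None = None,
                         ) -> tuple[AcousticEpoch, list[dict]]:
    """Concatenate words (with optional inter-word gaps) into an utterance.

    String entries are looked up in the lexicon and their continuous
    parameters sampled under ``rng_seed``; :class:`WordParameters`
    entries are rendered verbatim.  Returns the waveform and ground-truth
    annotations (onset_s, offset_s, label).
    """
    rng = np.random.default_rng(rng_seed)
    pieces: list[np.ndarray] = []
    truth: list[dict] = []
    t = 0.0
    gap_samples = round_half_away(gap * config.rate)
    for item in words:
        if isinstance(item, WordParameters):
            params, label = item, None
        else:
            if lexicon is None or item not in lexicon:
                raise KeyError(f"unknown word {item!r}")
            params = sample_word_parameters(item, lexicon, config, rng)
            label = item
        epoch = synthesize_word(params, config)
        n = len(epoch.samples)
        truth.append({"onset_s": t, "offset_s": t + n / config.rate,
                      "label": label})
        pieces.append(epoch.samples)
        if gap_samples > 0:
            pieces.append(np.zeros(gap_samples))
        t += (n + gap_samples) / config.rate
    samples = (np.concatenate(pieces) if pieces
               else np.zeros(0))
    if gap_samples > 0 and pieces:
        samples = samples[:-gap_samples]  # no trailing gap
        truth[-1]["offset_s"] = len(samples) / config.rate
    return AcousticEpoch(samples=samples, rate=config.rate), truth
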