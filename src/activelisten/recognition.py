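"""Model inversion: from a waveform epoch to word parameters and beliefs.

The inversion mirrors the forward model step by step.  The fundamental
intervals are found by band-pass filtering around the prior speaker F0
and picking peaks of the filtered signal; short segments centred on each
interval are then projected onto cosines at the formant-grid
frequencies (the cosine transform of their autocovariance, i.e. the
power spectrum at the grid), recovering a spectral trajectory.  The
standardised log trajectory is projected back onto the DCT coefficient
basis to give MAP lexical coefficients, which are scored under each
word's Gaussian model and combined with a categorical prior.

Because the trajectory is measured as *power* while it is generated as
*amplitude*, the recovered log trajectory is a scaled version of the
generative one; standardising by its own dispersion (the timbre
estimate) removes that scale, so the same convention serves both paths.

Speech in noise is modelled by a single multiplier ``gamma`` on the
observation noise variance: the MAP coefficients shrink towards their
prior mean (zero) by ``lambda = 1/(1+gamma)`` and the categorical
likelihood is evaluated with correspondingly inflated variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .config import ModelConfig
from .lexicon import (AttributeModel, CategoricalBelief, Lexicon,
                      default_attribute_models, log_likelihood,
                      posterior_from_likelihoods)
from .signals import dct_basis, gaussian_bandpass, round_half_away, \
    smoothed_envelope
from .synthesis import (AcousticEpoch, ProsodyState, SpeakerState,
                        SpectralTrajectory, WordParameters, inflection_basis)

__all__ = [
    "UnvoicedEpochError",
    "FundamentalEstimate",
    "RecognitionResult",
    "NoiseModel",
    "estimate_fundamental",
    "estimate_formant_scale",
    "epoch_to_trajectory",
    "map_parameters",
    "recognize_word",
]

#: relative floor applied to spectral power before taking logs
POWER_FLOOR = 1e-8


class UnvoicedEpochError(ValueError):
    """Raised when an epoch contains no usable voiced structure."""


# ----------------------------------------------------------------------
# Amortisation calibration.
#
# The analysis window (one first-formant period) smears the spectral
# trajectory across neighbouring formant bins, so the projection of the
# standardised log trajectory onto the coefficient basis attenuates each
# frequency row of the coefficient matrix by a geometry-dependent gain.
# The gains are measured once per configuration by pushing random probe
# words through the full synthesis-analysis loop and regressing the
# recovered rows on the generative ones; dividing them out makes the
# recogniser's coefficient estimates live in the generative template
# space (and the generate-recognise loop approximately idempotent).

_GAIN_CACHE: dict[tuple, np.ndarray] = {}
_CALIBRATION_SEED = 987654321
_N_PROBES = 24


def frequency_mode_gains(config: ModelConfig) -> np.ndarray:
    """Per-frequency-row gains of the synthesis-analysis loop (cached)."""
    key = (config.rate, config.nf, config.nq_f, config.nq_t,
           round(config.f0_prior, 6), round(config.f1_reference, 6),
           config.bins_per_interval)
    cached = _GAIN_CACHE.get(key)
    if cached is not None:
        return cached
    from .fixtures import random_probe_template  # lazy: avoids cycle
    from .synthesis import synthesize_word
    rng = np.random.default_rng(_CALIBRATION_SEED)
    num = np.zeros(config.nq_f)
    den = np.zeros(config.nq_f)
    for _ in range(_N_PROBES):
        q = random_probe_template(rng, int(rng.integers(1, 4)), config)
        prosody = ProsodyState(duration=float(rng.uniform(0.3, 0.65)))
        speaker = SpeakerState(f0_mean=float(
            config.f0_prior * np.exp(rng.normal(0.0, 0.03))))
        epoch = synthesize_word(WordParameters(q, prosody, speaker), config)
        fundamental = estimate_fundamental(epoch, config.f0_prior,
                                           config.f0_min, config.f0_max)
        traj = epoch_to_trajectory(epoch, fundamental,
                                   config.f1_reference, config)
        params = map_parameters(traj, fundamental, 1.0, NoiseModel(0.0),
                                config, 1.0, _apply_gains=False)
        num += np.sum(params.coeffs * q, axis=1)
        den += np.sum(q * q, axis=1)
    gains = num / np.maximum(den, 1e-12)
    gains = np.clip(gains, 0.05, None)
    _GAIN_CACHE[key] = gains
    return gains


# ----------------------------------------------------------------------
@dataclass
class FundamentalEstimate:
    """Glottal-pulse timing recovered from one epoch."""

    peak_times: np.ndarray
    instantaneous_f0: np.ndarray
    f0_mean: float
    inflection_hat: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, float)
        self.instantaneous_f0 = np.asarray(self.instantaneous_f0, float)
        self.inflection_hat = np.asarray(self.inflection_hat, float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def interval_centres(self) -> np.ndarray:
        return 0.5 * (self.peak_times[:-1] + self.peak_times[1:])

    @property
    def span(self) -> float:
        """Voiced span: first to last peak plus one mean period."""
        if len(self.instantaneous_f0) == 0:
            return 0.0
        return float(self.peak_times[-1] - self.peak_times[0]
                     + 1.0 / self.f0_mean)


@dataclass
class RecognitionResult:
    """Everything inferred about one word epoch."""

    params_hat: WordParameters
    lexical_posterior: CategoricalBelief
    logliks: dict[str, float]
    prosody_posteriors: dict[str, CategoricalBelief] = field(
        default_factory=dict)
    speaker_posteriors: dict[str, CategoricalBelief] = field(
        default_factory=dict)
    low_confidence: bool = False

    @property
    def map_label(self) -> str:
        return self.lexical_posterior.map_label()

    def to_record(self) -> dict:
        return {
            "label": self.map_label,
            "posterior": {s: float(p) for s, p in zip(
                self.lexical_posterior.support,
                self.lexical_posterior.probs)},
            "f0_mean": self.params_hat.speaker.f0_mean,
            "formant_scale": self.params_hat.speaker.formant_scale,
            "amplitude": self.params_hat.prosody.amplitude,
            "duration": self.params_hat.prosody.duration,
            "timbre": self.params_hat.prosody.timbre,
            "inflection": self.params_hat.prosody.inflection.tolist(),
        }


@dataclass
class NoiseModel:
    """Precision-scaling account of speech in noise.

    ``gamma`` multiplies the ambient observation-noise variance.  The
    implied shrinkage of MAP coefficient estimates towards their prior
    mean is ``lambda = Pi_e / (Pi_e + Pi_p)`` with evidence precision
    ``Pi_e = Pi_p / gamma``, i.e. ``lambda = 1 / (1 + gamma)``: unity in
    the noiseless limit and monotonically decreasing in ``gamma``.
    """

    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("the noise multiplier must be non-negative")

    @property
    def shrinkage(self) -> float:
        return 1.0 / (1.0 + self.gamma)

    def extra_variance(self, lexicon: Lexicon) -> np.ndarray | None:
        """Observation-noise variance added to each entry's likelihood."""
        if self.gamma == 0:
            return None
        return self.gamma * lexicon.prior_variance()

    def extra_duration_variance(self, lexicon: Lexicon) -> float | None:
        """Noise-inflated duration observation variance.

        Background noise blurs the perceived word boundaries just as it
        corrupts the spectral evidence, so the duration observation is
        degraded by the same multiplier against the pooled (pre-lexical)
        duration variance.
        """
        if self.gamma == 0:
            return None
        base = lexicon.prior_duration_variance()
        return None if base is None else self.gamma * base


# ----------------------------------------------------------------------
def estimate_fundamental(epoch: AcousticEpoch, f0_prior: float,
                         f0_min: float = 50.0,
                         f0_max: float = 500.0) -> FundamentalEstimate:
    """Recover fundamental intervals by band-pass filtering and peak picking.

    The pass band is Gaussian, centred on the prior speaker F0 with a
    half-octave half-width.  Peaks above zero with a minimum separation
    of half the prior period define the fundamental intervals; their
    reciprocals give the instantaneous F0, and the prosodic inflection is
    the least-squares projection of the relative F0 contour onto the
    orthogonalised quadratic basis.
    """
    x = epoch.samples
    if len(x) < 3 * epoch.rate / f0_prior:
        raise UnvoicedEpochError("epoch shorter than three fundamental "
                                 "periods")
    sigma = f0_prior * (np.sqrt(2.0) - 1.0 / np.sqrt(2.0)) / 2.0
    filtered = gaussian_bandpass(x, epoch.rate, f0_prior, sigma)
    distance = max(1, round_half_away(epoch.rate / (2.0 * f0_prior)))
    peaks, _ = find_peaks(filtered, height=0.0, distance=distance)
    if len(peaks) < 2:
        raise UnvoicedEpochError("fewer than two glottal peaks found")
    peak_times = peaks / epoch.rate
    intervals = np.diff(peak_times)
    inst_f0 = np.clip(1.0 / intervals, f0_min, f0_max)
    f0_mean = float(inst_f0.mean())
    centres = 0.5 * (peak_times[:-1] + peak_times[1:])
    span = peak_times[-1] - peak_times[0]
    u = ((centres - peak_times[0]) / span if span > 0
         else np.zeros_like(centres))
    basis = inflection_basis(u)
    rel = inst_f0 / f0_mean - 1.0
    coef, *_ = np.linalg.lstsq(basis, rel, rcond=None)
    return FundamentalEstimate(peak_times=peak_times,
                               instantaneous_f0=inst_f0,
                               f0_mean=f0_mean, inflection_hat=coef)


def _power_at(freqs: np.ndarray, x: np.ndarray, rate: float) -> np.ndarray:
    """Windowed periodogram of ``x`` evaluated at arbitrary frequencies."""
    n = len(x)
    xw = x * np.hanning(n)
    phases = np.outer(freqs, np.arange(n)) * (2.0 * np.pi / rate)
    real = phases.copy()
    np.cos(real, out=real)
    imag = phases
    np.sin(imag, out=imag)
    return (real @ xw) ** 2 + (imag @ xw) ** 2


def estimate_formant_scale(epoch: AcousticEpoch,
                           config: ModelConfig,
                           scale_grid: tuple[float, ...] | None = None,
                           lexicon: Lexicon | None = None,
                           fundamental: FundamentalEstimate | None = None,
                           ) -> tuple[float, bool]:
    """Select the formant scale whose grid best captures the epoch's power.

    With a lexicon available, each candidate scale is scored by the model
    evidence of the spectral trajectory analysed at that scale (summed
    power at the implied grid, assessed through the word likelihoods) —
    Bayesian model selection over scale hypotheses, which undoes the
    speaker's formant scaling exactly when the hypothesis is right.
    Without a lexicon a spectral score is used instead: the mean log
    power of the epoch at the candidate grid frequencies, which penalises
    grids extending into empty spectral regions.  Ties break towards
    1.0.  Returns ``(scale, low_confidence)``; the flag is set when the
    scores barely discriminate (e.g. white noise).
    """
    grid_scales = tuple(scale_grid if scale_grid is not None
                        else config.scale_grid)
    if len(grid_scales) == 0:
        raise ValueError("scale grid must be non-empty")
    x = epoch.samples
    neutral = min(grid_scales, key=lambda s: abs(s - 1.0))
    if np.allclose(x, 0.0):
        return neutral, True

    scores = []
    if lexicon is not None:
        try:
            fundamental = fundamental or estimate_fundamental(
                epoch, config.f0_prior, config.f0_min, config.f0_max)
        except UnvoicedEpochError:
            fundamental = None
        if fundamental is not None:
            n_words = len(lexicon)
            for s in grid_scales:
                traj = epoch_to_trajectory(epoch, fundamental,
                                           s * config.f1_reference, config)
                params = map_parameters(traj, fundamental, 1.0,
                                        NoiseModel(0.0), config, s)
                lls = np.array([log_likelihood(params, e)
                                for e in lexicon.entries])
                scores.append(float(logsumexp(lls) - np.log(n_words)))
    if not scores:  # no lexicon (or unvoiced): spectral fallback
        total = float(np.sum(x ** 2)) * len(x)
        for s in grid_scales:
            power = _power_at(config.formant_grid(s), x, epoch.rate)
            floor = POWER_FLOOR * max(total, 1e-300)
            scores.append(float(np.mean(np.log(np.maximum(power, floor)))))
    scores = np.asarray(scores)
    best = scores.max()
    candidates = [s for s, sc in zip(grid_scales, scores)
                  if sc >= best - 1e-12]
    scale = min(candidates, key=lambda s: abs(s - 1.0))
    spread = scores.max() - scores.min()
    return float(scale), bool(spread < 0.05 * abs(best) + 1e-12)


def epoch_to_trajectory(epoch: AcousticEpoch,
                        fundamental: FundamentalEstimate,
                        f1: float, config: ModelConfig,
                        ) -> SpectralTrajectory:
    """Project per-interval segments onto the formant grid.

    Each fundamental interval contributes one column: a segment one
    first-formant period long — the transient duration — centred on the
    glottal peak that opens the interval, zero-padded at the epoch
    edges.  Its power spectrum (the cosine transform of its
    autocovariance) is evaluated at the grid frequencies and floored at
    a small positive value so logs stay finite.
    """
    if len(fundamental.peak_times) < 2:
        raise UnvoicedEpochError("need at least one fundamental interval")
    scale = f1 / config.f1_reference
    grid = config.formant_grid(scale)
    n_seg = round_half_away(epoch.rate / f1)
    x = epoch.samples
    cols = []
    for c in fundamental.peak_times:
        mid = round_half_away(c * epoch.rate)
        start = mid - n_seg // 2
        seg = np.zeros(n_seg)
        lo, hi = max(start, 0), min(start + n_seg, len(x))
        if hi > lo:
            seg[lo - start:hi - start] = x[lo:hi]
        cols.append(_power_at(grid, seg, epoch.rate))
    w = np.stack(cols, axis=1)
    floor = max(POWER_FLOOR * w.max(), 1e-30)
    return SpectralTrajectory(W=np.maximum(w, floor), formant_grid=grid)


def map_parameters(traj: SpectralTrajectory,
                   fundamental: FundamentalEstimate,
                   envelope_peak: float,
                   noise: NoiseModel,
                   config: ModelConfig,
                   formant_scale: float = 1.0,
                   _apply_gains: bool = True) -> WordParameters:
    """MAP word parameters from the recovered trajectory and timing.

    The log trajectory is centred and standardised (its dispersion is the
    timbre estimate), projected onto the DCT coefficient basis, truncated
    to the configured shape, corrected for the calibrated per-row gains
    of the analysis, and shrunk towards the zero prior mean by the noise
    model's ``lambda``.
    """
    log_w = np.log(traj.W)
    timbre_hat = float(log_w.std())
    eps = 1e-6
    z = (log_w - log_w.mean()) / max(timbre_hat, eps)
    nf, k = z.shape
    u_f = dct_basis(nf, config.nq_f)
    u_t = dct_basis(k, config.nq_t)
    if k >= config.nq_t:
        coeffs = u_f.T @ z @ u_t
    else:  # fewer transients than temporal coefficients: least squares
        coeffs = u_f.T @ z @ np.linalg.pinv(u_t).T
    if _apply_gains:
        coeffs = coeffs / frequency_mode_gains(config)[:, None]
    coeffs = noise.shrinkage * coeffs
    prosody = ProsodyState(
        amplitude=max(envelope_peak, 1e-12),
        duration=float(np.clip(fundamental.span, 1e-3, None)),
        timbre=max(timbre_hat, eps),
        inflection=fundamental.inflection_hat,
    )
    speaker = SpeakerState(f0_mean=fundamental.f0_mean,
                           formant_scale=formant_scale)
    return WordParameters(coeffs=coeffs, prosody=prosody, speaker=speaker)


def recognize_word(epoch: AcousticEpoch,
                   priors: CategoricalBelief,
                   lexicon: Lexicon,
                   config: ModelConfig,
                   noise: NoiseModel | None = None,
                   attribute_models: dict[str, AttributeModel] | None = None,
                   formant_scale: float | None = None,
                   ) -> RecognitionResult:
    """Full inversion chain for a single word epoch.

    Chains fundamental estimation, formant-scale selection, trajectory
    recovery and MAP parameter estimation, then scores the coefficients
    under every lexicon entry and combines with the categorical prior.
    Raises :class:`UnvoicedEpochError` for unvoiced/empty epochs.
    """
    noise = noise or NoiseModel(config.gamma)
    attribute_models = attribute_models or default_attribute_models()
    fundamental = estimate_fundamental(epoch, config.f0_prior,
                                       config.f0_min, config.f0_max)
    low_conf = False
    if formant_scale is None:
        formant_scale, low_conf = estimate_formant_scale(
            epoch, config, lexicon=lexicon, fundamental=fundamental)
    f1 = formant_scale * config.f1_reference
    traj = epoch_to_trajectory(epoch, fundamental, f1, config)
    env = smoothed_envelope(epoch.samples, epoch.rate,
                            config.envelope_highpass, config.envelope_sigma)
    params = map_parameters(traj, fundamental, float(env.max()),
                            noise, config, formant_scale)
    extra = noise.extra_variance(lexicon)
    extra_dur = noise.extra_duration_variance(lexicon)
    logliks = {e.label: log_likelihood(params, e, extra_variance=extra,
                                       extra_duration_variance=extra_dur)
               for e in lexicon.entries}
    loglik_vec = np.array([logliks[label] for label in priors.support])
    posterior = posterior_from_likelihoods(loglik_vec, priors)

    attr_values = {
        "amplitude": params.prosody.amplitude,
        "duration": params.prosody.duration,
        "timbre": params.prosody.timbre,
        "inflection": params.prosody.inflection,
        "f0_speaker": params.speaker.f0_mean,
        "formant_scale": params.speaker.formant_scale,
    }
    prosody_post = {name: attribute_models[name].posterior(attr_values[name])
                    for name in ("amplitude", "duration", "timbre",
                                 "inflection")}
    speaker_post = {name: attribute_models[name].posterior(attr_values[name])
                    for name in ("f0_speaker", "formant_scale")}
    return RecognitionResult(params_hat=params,
                             lexical_posterior=posterior,
                             logliks=logliks,
                             prosody_posteriors=prosody_post,
                             speaker_posteriors=speaker_post,
                             low_confidence=low_conf)
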