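"""End-to-end simulation scenarios.

These functions wire the full pipeline together the way the simulation
studies use it: synthesise a scripted utterance, actively parse it,
replay the belief updating as neuronal dynamics, and summarise surprise
and evoked responses per word.  They are the substrate for the
command-line ``simulate`` subcommands and for the package's acceptance
checks.

Conventions
-----------
Belief trajectories for word ``k`` start at the word's offset (belief
updating is triggered once the boundary is committed).  ERP traces are
the band-passed temporal derivative of log-expectations; the per-word
response amplitude is the peak absolute value over populations and
update steps; evoked power is the variance across populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .fixtures import ambiguous_stream
from .lexicon import CategoricalBelief, Lexicon
from .neurodynamics import (bayesian_surprise, belief_gradient_flow,
                            evoked_power, floored_log, simulated_erp)
from .recognition import NoiseModel
from .segmentation import ParseResult, parse_sentence
from .synthesis import (AcousticEpoch, ProsodyState, SpeakerState,
                        WordParameters, synthesize_utterance,
                        synthesize_word)

__all__ = [
    "WordDynamics",
    "ListeningRun",
    "active_listen",
    "word_dynamics",
    "regenerate",
    "round_trip",
    "prior_comparison",
    "noise_sweep",
    "surprise_power_profile",
    "mismatch_response",
    "sentence_priors",
    "uniform_priors",
]


# ----------------------------------------------------------------------
@dataclass
class WordDynamics:
    """Neuronal summary of recognising one word."""

    label: str
    onset_s: float
    offset_s: float
    kl: float
    peak_erp: float
    peak_power: float
    trajectory_v: np.ndarray
    erp: np.ndarray
    power: np.ndarray


@dataclass
class ListeningRun:
    """A parse plus the belief-updating dynamics of each word."""

    parse: ParseResult
    words: list[WordDynamics] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.words]

    def mean_peak_erp(self) -> float:
        return float(np.mean([w.peak_erp for w in self.words])) if \
            self.words else 0.0

    def mean_kl(self) -> float:
        return float(np.mean([w.kl for w in self.words])) if self.words \
            else 0.0


# ----------------------------------------------------------------------
def uniform_priors(lexicon: Lexicon) -> str:
    return "uniform"


def sentence_priors(lexicon: Lexicon,
                    candidate_sets: list[dict[str, float]],
                    ) -> list[CategoricalBelief]:
    """Per-word categorical priors from plausible candidate sets."""
    return [CategoricalBelief.from_mapping(lexicon.labels, weights)
            for weights in candidate_sets]


def word_dynamics(prior: CategoricalBelief, posterior: CategoricalBelief,
                  logliks: dict[str, float], config: ModelConfig,
                  label: str = "", onset_s: float = 0.0,
                  offset_s: float = 0.0) -> WordDynamics:
    """Belief-updating dynamics for one recognised word."""
    ll = np.array([logliks[lb] for lb in prior.support])
    log_prior = floored_log(prior.probs, config.belief_floor)
    traj = belief_gradient_flow(log_prior, ll, n_steps=config.n_steps,
                                kappa=config.kappa, dt=config.dt,
                                support=prior.support,
                                floor=config.belief_floor)
    erp = simulated_erp(traj, config.erp_band)
    power, peak_power = evoked_power(erp, dt=config.dt)
    prior_f = CategoricalBelief(prior.support, np.exp(
        floored_log(prior.probs, config.belief_floor)))
    post_f = CategoricalBelief(posterior.support, np.exp(
        floored_log(posterior.probs, config.belief_floor)))
    return WordDynamics(
        label=label or posterior.map_label(),
        onset_s=onset_s, offset_s=offset_s,
        kl=bayesian_surprise(prior_f, post_f),
        peak_erp=float(np.max(np.abs(erp))),
        peak_power=peak_power,
        trajectory_v=traj.v, erp=erp, power=power,
    )


def active_listen(audio: AcousticEpoch,
                  priors,
                  lexicon: Lexicon,
                  config: ModelConfig,
                  noise: NoiseModel | None = None) -> ListeningRun:
    """Parse an utterance and replay belief updating word by word."""
    noise = noise or NoiseModel(config.gamma)
    parse = parse_sentence(audio, priors, lexicon, config, noise=noise)
    run = ListeningRun(parse=parse)
    for record in parse.words:
        run.words.append(word_dynamics(
            record["prior"], record["posterior"], record["logliks"],
            config, label=record["label"], onset_s=record["onset_s"],
            offset_s=record["offset_s"]))
    return run


# ----------------------------------------------------------------------
def regenerate(run: ListeningRun, lexicon: Lexicon,
               config: ModelConfig) -> AcousticEpoch:
    """Synthesise a new utterance from the recognised states.

    The lexical cause of each word is its recognised *discrete* state,
    so the coefficients come from the lexicon entry of the inferred
    label; the prosodic timing, gain, inflection and the speaker
    fundamental come from the recognised continuous estimates.
    """
    pieces = []
    for record in run.parse.words:
        params = record["params_hat"]
        regen = WordParameters(
            coeffs=lexicon[record["label"]].coeff_mean,
            prosody=ProsodyState(
                amplitude=params.prosody.amplitude,
                duration=float(np.clip(params.prosody.duration,
                                       config.min_dur, config.max_dur)),
                timbre=1.0,
                inflection=np.clip(params.prosody.inflection, -0.3, 0.3),
            ),
            speaker=SpeakerState(
                f0_mean=params.speaker.f0_mean,
                formant_scale=params.speaker.formant_scale,
            ),
        )
        pieces.append(synthesize_word(regen, config).samples)
    samples = np.concatenate(pieces) if pieces else np.zeros(0)
    return AcousticEpoch(samples, config.rate)


def round_trip(lexicon: Lexicon, script: list[str], config: ModelConfig,
               seed: int = 0, priors="uniform") -> dict:
    """Recognise a scripted utterance, regenerate it, recognise again.

    The recursive generate-recognise loop: the first parse recovers
    discrete states from the synthesised script; those states are pushed
    back through the generative model and the synthetic speech is parsed
    a second time.  A faithful amortised inversion recovers the same
    words both times.
    """
    audio, truth = ambiguous_stream(lexicon, script, config, gap=0.0,
                                    seed=seed)
    first = active_listen(audio, priors, lexicon, config)
    resynth = regenerate(first, lexicon, config)
    second = active_listen(resynth, priors, lexicon, config)
    return {
        "script": list(script),
        "audio": audio,
        "resynthesis": resynth,
        "first": first,
        "second": second,
        "first_labels": first.labels,
        "second_labels": second.labels,
        "match": first.labels == second.labels == list(script),
    }


def prior_comparison(lexicon: Lexicon, script: list[str],
                     candidate_sets: list[dict[str, float]],
                     config: ModelConfig, seed: int = 0) -> dict:
    """One utterance heard twice: informative vs uniform priors.

    Returns both runs and the percentage increase in mean peak ERP
    amplitude without informative priors — uncertainty expressed as
    more vigorous simulated electrophysiological responses.
    """
    audio, _ = ambiguous_stream(lexicon, script, config, gap=0.0,
                                seed=seed)
    informative = active_listen(
        audio, sentence_priors(lexicon, candidate_sets), lexicon, config)
    uniform = active_listen(audio, "uniform", lexicon, config)
    base = informative.mean_peak_erp()
    increase = (100.0 * (uniform.mean_peak_erp() - base) / base
                if base > 0 else np.nan)
    return {
        "audio": audio,
        "informative": informative,
        "uniform": uniform,
        "erp_increase_percent": float(increase),
    }


def noise_sweep(lexicon: Lexicon, script: list[str],
                gammas: list[float], config: ModelConfig,
                seed: int = 0, priors="uniform") -> dict:
    """Listen to one utterance under increasing background noise.

    Larger noise multipliers shrink the coefficient estimates towards
    their prior mean and down-weight the sensory evidence, so belief
    updating (KL) and the evoked responses it drives are attenuated.
    The utterance is segmented once, under clean conditions, and the
    same word intervals are re-evaluated at every noise level — the
    comparison isolates the effect of noise on belief updating rather
    than on boundary placement.
    """
    from .segmentation import Interval, evaluate_interval
    audio, _ = ambiguous_stream(lexicon, script, config, gap=0.0,
                                seed=seed)
    clean = active_listen(audio, priors, lexicon, config,
                          noise=NoiseModel(0.0))
    intervals = [Interval(*w["interval"]) for w in clean.parse.words]
    word_priors = [w["prior"] for w in clean.parse.words]
    runs: dict[float, list[WordDynamics]] = {}
    for gamma in gammas:
        noise = NoiseModel(gamma)
        words = []
        for iv, prior in zip(intervals, word_priors):
            ev = evaluate_interval(audio, iv, prior, lexicon, config,
                                   noise=noise)
            if ev.result is None:
                continue
            words.append(word_dynamics(prior, ev.posterior,
                                       ev.result.logliks, config,
                                       onset_s=iv.onset / config.rate,
                                       offset_s=iv.offset / config.rate))
        runs[gamma] = words
    return {
        "audio": audio,
        "clean": clean,
        "runs": runs,
        "mean_kl": {g: float(np.mean([w.kl for w in ws])) if ws else 0.0
                    for g, ws in runs.items()},
        "mean_peak_power": {g: float(np.mean([w.peak_power for w in ws]))
                            if ws else 0.0 for g, ws in runs.items()},
        "coeff_norms": {g: float(np.mean(
            [np.linalg.norm(w.trajectory_v[-1]) for w in ws]))
            for g, ws in runs.items()},
    }


def surprise_power_profile(lexicon: Lexicon, script: list[str],
                           sharpness: list[float], config: ModelConfig,
                           seed: int = 0) -> dict:
    """Graded prior sharpness: Bayesian surprise vs evoked power.

    Word ``k`` of the utterance is heard under a prior placing
    ``sharpness[k]`` mass on the true word (the rest spread uniformly).
    Sharper priors leave less to update, so per-word surprise (KL) and
    the peak evoked power should rise and fall together; the Spearman
    correlation across words quantifies the monotone relationship.
    """
    from scipy.stats import spearmanr
    from .segmentation import Interval, evaluate_interval
    if len(sharpness) < len(script):
        raise ValueError("need one sharpness value per scripted word")
    audio, _ = ambiguous_stream(lexicon, script, config, gap=0.0,
                                seed=seed)
    clean = active_listen(audio, "uniform", lexicon, config)
    n = len(lexicon)
    words = []
    for k, record in enumerate(clean.parse.words):
        s = sharpness[min(k, len(sharpness) - 1)]
        true_label = script[min(k, len(script) - 1)]
        probs = np.full(n, (1.0 - s) / (n - 1))
        probs[lexicon.labels.index(true_label)] = s
        prior = CategoricalBelief(lexicon.labels, probs)
        iv = Interval(*record["interval"])
        ev = evaluate_interval(audio, iv, prior, lexicon, config)
        words.append(word_dynamics(prior, ev.posterior, ev.result.logliks,
                                   config, onset_s=record["onset_s"],
                                   offset_s=record["offset_s"]))
    kls = [w.kl for w in words]
    peaks = [w.peak_power for w in words]
    rho = float(spearmanr(kls, peaks).statistic) if len(words) > 2 else np.nan
    return {"audio": audio, "words": words, "kl": kls,
            "peak_power": peaks, "spearman": rho}


def mismatch_response(lexicon: Lexicon, script: list[str],
                      candidate_sets: list[dict[str, float]],
                      gammas: list[float], config: ModelConfig,
                      seed: int = 0, uncertain_word: int = 2) -> dict:
    """Prior-violation difference waveforms under increasing noise.

    For one word of the sentence (by default the third), the simulated
    response is computed with and without its informative prior; the
    peak absolute difference waveform is the violation (mismatch/P300
    style) response.  Repeating the comparison at higher noise levels
    shows the attenuation of the surprise response: less precise
    evidence drives less belief updating.  Also reports the shrinkage
    of the recognised coefficients at each noise level.
    """
    from .segmentation import Interval, evaluate_interval
    audio, _ = ambiguous_stream(lexicon, script, config, gap=0.0,
                                seed=seed)
    informative = sentence_priors(lexicon, candidate_sets)
    clean = active_listen(audio, informative, lexicon, config,
                          noise=NoiseModel(0.0))
    if uncertain_word >= len(clean.parse.words):
        raise ValueError("utterance parsed into too few words")
    record = clean.parse.words[uncertain_word]
    iv = Interval(*record["interval"])
    with_prior = informative[min(uncertain_word, len(informative) - 1)]
    without_prior = CategoricalBelief.uniform(lexicon.labels)
    out = {"audio": audio, "per_gamma": {}}
    for gamma in gammas:
        noise = NoiseModel(gamma)
        ev = evaluate_interval(audio, iv, with_prior, lexicon, config,
                               noise=noise)
        dyn_with = word_dynamics(with_prior, ev.posterior,
                                 ev.result.logliks, config)
        ev0 = evaluate_interval(audio, iv, without_prior, lexicon, config,
                                noise=noise)
        dyn_without = word_dynamics(without_prior, ev0.posterior,
                                    ev0.result.logliks, config)
        diff = dyn_without.erp - dyn_with.erp
        out["per_gamma"][gamma] = {
            "with": dyn_with, "without": dyn_without,
            "difference_peak": float(np.max(np.abs(diff))),
            "coeff_norm": float(np.linalg.norm(
                ev0.result.params_hat.coeffs)),
        }
    return out
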