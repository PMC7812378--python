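"""Active segmentation: choosing word boundaries by free-energy minimisation.

Candidate boundaries come from the smoothed amplitude envelope: within a
fixed analysis epoch the onset is the last sub-to-supra threshold
crossing before the first supra-threshold envelope peak, and candidate
offsets are the internal envelope minima after that peak plus the last
supra-to-sub crossing.  Each candidate interval is scored by the
variational free energy of recognising a word inside it,

    F = complexity - accuracy
      = KL(posterior || prior) - E_posterior[log likelihood],

and the interval with the smallest F is selected — the covert action
that maximises the evidence for the listener's model of how single
words are generated.  The selected offset seeds the next search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import argrelextrema

from .config import ModelConfig
from .lexicon import AttributeModel, CategoricalBelief, Lexicon
from .recognition import (NoiseModel, RecognitionResult, UnvoicedEpochError,
                          recognize_word)
from .signals import smoothed_envelope
from .synthesis import AcousticEpoch

__all__ = [
    "Interval",
    "IntervalEvaluation",
    "ParseResult",
    "amplitude_envelope",
    "candidate_intervals",
    "evaluate_interval",
    "parse_sentence",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Interval:
    """Half-open sample interval [onset, offset)."""

    onset: int
    offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError("need 0 <= onset < offset")

    def duration(self, rate: float) -> float:
        return (self.offset - self.onset) / rate

    def __len__(self) -> int:
        return self.offset - self.onset


@dataclass
class IntervalEvaluation:
    """A candidate interval with its recognition result and free energy."""

    interval: Interval
    posterior: CategoricalBelief | None
    accuracy: float
    complexity: float
    free_energy: float
    result: RecognitionResult | None = None

    @property
    def voiced(self) -> bool:
        return np.isfinite(self.free_energy)


@dataclass
class ParseResult:
    """Selected word records plus regions left outside any boundary."""

    words: list[dict] = field(default_factory=list)
    unassigned: list[tuple[int, int]] = field(default_factory=list)
    rate: float = 22050.0

    @property
    def labels(self) -> list[str]:
        return [w["label"] for w in self.words]

    def to_json(self, path: str | Path | None = None) -> str:
        def serialisable(w: dict) -> dict:
            out = {
                "interval": list(w["interval"]),
                "onset_s": w["onset_s"], "offset_s": w["offset_s"],
                "label": w["label"],
                "posterior": {s: float(p) for s, p in zip(
                    w["posterior"].support, w["posterior"].probs)},
                "free_energy": w["free_energy"],
                "complexity": w["complexity"],
                "accuracy": w["accuracy"],
                "n_candidates": w["n_candidates"],
            }
            if w.get("params_hat") is not None:
                p = w["params_hat"]
                out["params_hat"] = {
                    "f0_mean": p.speaker.f0_mean,
                    "formant_scale": p.speaker.formant_scale,
                    "amplitude": p.prosody.amplitude,
                    "duration": p.prosody.duration,
                    "timbre": p.prosody.timbre,
                    "inflection": p.prosody.inflection.tolist(),
                }
            return out

        doc = {
            "rate": self.rate,
            "words": [serialisable(w) for w in self.words],
            "unassigned": [list(u) for u in self.unassigned],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_annotation(self, path: str | Path | None = None) -> str:
        """Tab-separated (onset_s, offset_s, label, posterior_max) lines."""
        lines = ["onset_s\toffset_s\tlabel\tposterior_max"]
        for w in self.words:
            lines.append(f"{w['onset_s']:.4f}\t{w['offset_s']:.4f}\t"
                         f"{w['label']}\t{w['posterior_max']:.4f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ----------------------------------------------------------------------
def amplitude_envelope(timeseries: AcousticEpoch,
                       config: ModelConfig | None = None) -> np.ndarray:
    """Smoothed amplitude envelope of the waveform (same length, >= 0)."""
    config = config or ModelConfig()
    return smoothed_envelope(timeseries.samples, timeseries.rate,
                             config.envelope_highpass, config.envelope_sigma)


def _crossings(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of sub->supra (up) and supra->sub (down) transitions."""
    d = np.diff(above.astype(int))
    return np.where(d == 1)[0] + 1, np.where(d == -1)[0] + 1


def candidate_intervals(envelope: np.ndarray, search_start: int,
                        config: ModelConfig) -> list[Interval]:
    """Enumerate candidate word intervals inside one analysis epoch.

    Within ``epoch_len`` seconds from ``search_start``: the first
    supra-threshold envelope peak anchors the word; the onset is the last
    upward threshold crossing before that peak (the threshold is the
    epoch maximum divided by 16); candidate offsets are the internal
    envelope minima between the peak and the final downward crossing,
    plus that final crossing itself.  Intervals outside the plausible
    duration range are dropped.  An epoch with no supra-threshold peak
    yields an empty list (end of speech).
    """
    n = len(envelope)
    if search_start >= n:
        return []
    stop = min(n, search_start + int(round(config.epoch_len * config.rate)))
    seg = envelope[search_start:stop]
    peak_level = seg.max(initial=0.0)
    if peak_level <= 0:
        return []
    threshold = peak_level * config.threshold_fraction
    above = seg > threshold
    if not above.any():
        return []

    # extrema on the scale of the envelope smoothing kernel
    order = max(1, int(config.envelope_sigma * config.rate / 2))

    # first supra-threshold local maximum (the first envelope peak)
    maxima = argrelextrema(seg, np.greater_equal, order=order)[0]
    maxima = maxima[above[maxima]]
    peak = int(maxima[0]) if len(maxima) else int(np.argmax(seg))

    ups, downs = _crossings(above)
    prior_ups = ups[ups <= peak]
    onset = int(prior_ups[-1]) if len(prior_ups) else \
        (0 if above[0] else int(np.argmax(above)))

    later_downs = [int(d) for d in downs[downs > peak]]
    tail = later_downs[-1] if later_downs else len(seg)

    interior = argrelextrema(seg[peak:], np.less_equal,
                             order=order)[0] + peak
    # deduplicate flat runs and keep only supra-threshold internal minima
    minima = []
    for m in interior:
        if m <= peak:
            continue
        if above[m] and (not minima or m - minima[-1] > order):
            minima.append(int(m))

    # candidate offsets: internal envelope minima after the peak plus
    # every supra-to-sub threshold crossing (each marks a possible word
    # end); when the envelope never falls below threshold again the
    # epoch end stands in for the final crossing
    offsets = sorted(set(minima + later_downs + [tail]))
    out = []
    for off in offsets:
        if off <= onset:
            continue
        iv = Interval(onset + search_start, off + search_start)
        if config.min_dur <= iv.duration(config.rate) <= config.max_dur:
            out.append(iv)
    return out


def evaluate_interval(timeseries: AcousticEpoch, interval: Interval,
                      priors: CategoricalBelief, lexicon: Lexicon,
                      config: ModelConfig,
                      noise: NoiseModel | None = None,
                      attribute_models: dict[str, AttributeModel] | None = None,
                      formant_scale: float | None = None,
                      ) -> IntervalEvaluation:
    """Free energy of explaining one candidate interval as a single word.

    Accuracy is the posterior-expected log likelihood; complexity is the
    KL divergence from the prior to the posterior; their difference is
    the variational free energy (equal to the negative log evidence when
    the posterior is the exact Bayes posterior).  Unvoiced intervals get
    an infinite free energy and are never selected.
    """
    epoch = timeseries.slice(interval.onset, interval.offset)
    try:
        result = recognize_word(epoch, priors, lexicon, config, noise=noise,
                                attribute_models=attribute_models,
                                formant_scale=formant_scale)
    except UnvoicedEpochError:
        return IntervalEvaluation(interval=interval, posterior=None,
                                  accuracy=-np.inf, complexity=np.inf,
                                  free_energy=np.inf)
    q = result.lexical_posterior.probs
    p = priors.probs
    logliks = np.array([result.logliks[label]
                        for label in priors.support])
    nz = q > 0
    accuracy = float(np.sum(q[nz] * logliks[nz]))
    with np.errstate(divide="ignore"):
        complexity = float(np.sum(q[nz] * (np.log(q[nz]) - np.log(p[nz]))))
    return IntervalEvaluation(interval=interval,
                              posterior=result.lexical_posterior,
                              accuracy=accuracy, complexity=complexity,
                              free_energy=complexity - accuracy,
                              result=result)


def parse_sentence(timeseries: AcousticEpoch,
                   prior_sequence: Sequence[CategoricalBelief] | str,
                   lexicon: Lexicon,
                   config: ModelConfig,
                   noise: NoiseModel | None = None,
                   attribute_models: dict[str, AttributeModel] | None = None,
                   ) -> ParseResult:
    """Greedy active parse of a continuous utterance.

    For each word position the candidate intervals from the current
    search point are evaluated and the one with the smallest free energy
    selected (ties break towards the shortest interval); its offset
    becomes the next search point.  Word ``k`` uses the ``k``-th prior in
    the sequence, reusing the last prior when the sentence outruns it;
    the string ``"uniform"`` requests uniform priors over the lexicon.
    The formant scale is estimated once, on the first voiced word, and
    held fixed for the rest of the utterance.
    """
    envelope = amplitude_envelope(timeseries, config)
    result = ParseResult(rate=timeseries.rate)
    search = 0
    word_index = 0
    formant_scale: float | None = None

    def prior_for(k: int) -> CategoricalBelief:
        if prior_sequence == "uniform":
            return CategoricalBelief.uniform(lexicon.labels)
        return prior_sequence[min(k, len(prior_sequence) - 1)]

    eval_cache: dict[tuple[int, int], list[IntervalEvaluation]] = {}

    def evals_from(start: int, k: int) -> list[IntervalEvaluation]:
        key = (start, min(k, 0 if prior_sequence == "uniform"
                          else len(prior_sequence) - 1))
        if key not in eval_cache:
            prior = prior_for(k)
            eval_cache[key] = [
                evaluate_interval(timeseries, iv, prior, lexicon, config,
                                  noise=noise,
                                  attribute_models=attribute_models,
                                  formant_scale=formant_scale)
                for iv in candidate_intervals(envelope, start, config)]
        return eval_cache[key]

    def residual_cost(start: int, k: int) -> float:
        """Price of leaving supra-threshold signal after ``start`` unparsed.

        A leftover stretch of speech too short to be a candidate word is
        still an observation the parse must account for; it is scored as
        a (bad) single-word interval so that truncating a word is never
        cheaper than explaining it whole.
        """
        tail = envelope[start:]
        if tail.size == 0 or tail.max() <= 0:
            return 0.0
        above = tail > tail.max() * config.threshold_fraction
        idx = np.where(above)[0]
        extent = (idx[-1] - idx[0]) if len(idx) else 0
        if extent < int(0.05 * config.rate):
            return 0.0
        iv = Interval(start + int(idx[0]), start + int(idx[-1]) + 1)
        ev = evaluate_interval(timeseries, iv, prior_for(k), lexicon,
                               config, noise=noise,
                               attribute_models=attribute_models,
                               formant_scale=formant_scale)
        return ev.free_energy if ev.voiced else 0.0

    def continuation_cost(start: int, k: int) -> float:
        """Free energy of the best next word from ``start`` (0 at end)."""
        finite = [ev.free_energy for ev in evals_from(start, k)
                  if ev.voiced]
        return min(finite) if finite else residual_cost(start, k)

    while True:
        evals = evals_from(search, word_index)
        if not evals:
            break
        finite = [ev for ev in evals if ev.voiced]
        if not finite:
            # skip past this epoch: nothing voiced here
            search += int(round(config.epoch_len * config.rate))
            continue
        # one-word lookahead: a myopic argmin F can prefer a sub-word
        # fragment that matches some short word, leaving the remainder
        # to be explained badly; scoring each candidate together with
        # the best continuation from its offset compares hypotheses on
        # the evidence for the stream, not just the current interval
        best = min(finite, key=lambda ev: (
            ev.free_energy + continuation_cost(ev.interval.offset,
                                               word_index + 1),
            len(ev.interval)))
        prior = prior_for(word_index)
        if formant_scale is None and best.result is not None:
            formant_scale = best.result.params_hat.speaker.formant_scale
        iv = best.interval
        if iv.onset > search:
            result.unassigned.append((search, iv.onset))
        result.words.append({
            "interval": (iv.onset, iv.offset),
            "onset_s": iv.onset / timeseries.rate,
            "offset_s": iv.offset / timeseries.rate,
            "label": best.posterior.map_label(),
            "posterior_max": float(best.posterior.probs.max()),
            "posterior": best.posterior,
            "prior": prior,
            "params_hat": (best.result.params_hat
                           if best.result is not None else None),
            "logliks": (best.result.logliks
                        if best.result is not None else None),
            "free_energy": best.free_energy,
            "complexity": best.complexity,
            "accuracy": best.accuracy,
            "n_candidates": len(evals),
            "evaluation": evals,
        })
        word_index += 1
        search = iv.offset
    if search < len(timeseries.samples):
        tail = envelope[search:]
        if tail.size and tail.max() > 0:
            result.unassigned.append((search, len(timeseries.samples)))
    return result
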