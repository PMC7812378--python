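"""Synthetic data generation: demo lexicons and scripted utterance streams.

Every stage of the pipeline is testable without external recordings:
words are model-native templates (random, mutually orthogonalised
coefficient matrices with a syllable-like temporal envelope imposed on
the level contour), exemplar sets are jittered re-syntheses of those
templates passed through the recognition front end, and utterance
streams are scripted concatenations with ground-truth boundaries.

The word models are trained on *recovered* coefficients — each exemplar
is synthesised and pushed through the same analysis used at recognition
time — so the Gaussian statistics live in the space the recogniser
actually measures, exactly as a lexicon trained from recorded exemplars
would.

Syllable structure matters for segmentation: a word with ``n`` syllables
has ``n`` envelope humps separated by level dips, so zero-gap streams
stay above the envelope threshold at word boundaries and the boundary
candidates multiply — the regime in which active selection of the
free-energy-minimising interval does real work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ModelConfig
from .lexicon import Lexicon, train_lexical_entry
from .recognition import NoiseModel, epoch_to_trajectory, \
    estimate_fundamental, map_parameters
from .signals import dct_basis, smoothed_envelope
from .synthesis import (AcousticEpoch, ProsodyState, SpeakerState,
                        WordParameters, synthesize_utterance, synthesize_word)

__all__ = [
    "DemoSpec",
    "DEMO_WORDS",
    "random_probe_template",
    "build_demo_lexicon",
    "ambiguous_stream",
    "homophone_lexicon",
]

#: the 14-word demo vocabulary with syllable counts
DEMO_WORDS: dict[str, int] = {
    "triangle": 3, "square": 2, "is": 1, "there": 1, "a": 1,
    "above": 2, "below": 2, "red": 1, "green": 1, "blue": 1,
    "no": 1, "not": 1, "yes": 1, "round": 1,
}

#: typical word duration (s) by syllable count
SYLLABLE_DURATIONS = {1: 0.32, 2: 0.45, 3: 0.65}

#: depth of the inter-syllable level dip, in log-amplitude units; deep
#: enough to carve clear envelope minima, shallow enough that dips stay
#: above the 1/16 segmentation threshold (so zero-gap word boundaries
#: become competing internal-minimum candidates, not hard crossings)
SYLLABLE_DIP = 1.6

#: standard deviation of each coefficient row's contribution to the log
#: trajectory.  Row 0 (the temporal level contour) is kept small so the
#: random identity component does not swamp the syllable envelope —
#: hump heights stay within ~30% of each other and inter-syllable dips
#: stay above the segmentation threshold; the frequency-direction rows
#: are modest so the log-spectral structure stays in the quasi-linear
#: regime of the analysis window.
ROW_CONTRAST = (0.25, 0.35)  # (row 0, rows >= 1)


@dataclass
class DemoSpec:
    """Reproducible recipe for a demo lexicon and its utterance scripts."""

    labels: tuple[str, ...] = tuple(DEMO_WORDS)
    syllables: dict[str, int] = field(
        default_factory=lambda: dict(DEMO_WORDS))
    n_exemplars: int = 10
    jitter: float = 0.05
    seed: int = 0
    scripts: dict[str, list[str]] = field(default_factory=dict)


# ----------------------------------------------------------------------
def _syllable_profile(n_syllables: int, k: int,
                      depth: float = SYLLABLE_DIP) -> np.ndarray:
    """Log-level contour with ``n_syllables`` humps over ``k`` time points.

    Dips of the given depth sit at the syllable boundaries (including the
    word edges); the contour is zero at hump centres.
    """
    u = (np.arange(k) + 0.5) / k
    return -0.5 * depth * (1.0 + np.cos(2.0 * np.pi * n_syllables * u))


def _shape_template(raw: np.ndarray, n_syllables: int,
                    config: ModelConfig) -> np.ndarray:
    """Impose the row-contrast convention and syllable contour on a draw.

    Each row of the raw coefficient matrix is rescaled so its
    contribution to the log trajectory has the configured standard
    deviation, and the syllable-envelope contour is added to the
    frequency-constant row (whose coefficients set the temporal level
    profile of the word).
    """
    k0 = config.nf
    q = np.array(raw, dtype=float)
    q[0, 0] = 0.0
    for r in range(config.nq_f):
        target = ROW_CONTRAST[0] if r == 0 else ROW_CONTRAST[1]
        norm = np.linalg.norm(q[r, :])
        q[r, :] *= target * np.sqrt(config.nf * k0) / max(norm, 1e-12)
    u_t = dct_basis(k0, config.nq_t)
    contour = _syllable_profile(n_syllables, k0)
    q[0, :] += np.sqrt(config.nf) * (u_t.T @ contour)
    q[0, 0] = 0.0
    return q


def random_probe_template(rng: np.random.Generator, n_syllables: int,
                          config: ModelConfig) -> np.ndarray:
    """One random word template from the fixture distribution.

    Used both for demo words and for the recogniser's gain calibration,
    so calibration probes match the statistics of the words the package
    synthesises.
    """
    raw = rng.standard_normal((config.nq_f, config.nq_t))
    return _shape_template(raw, n_syllables, config)


def _seed_templates(labels: Sequence[str], syllables: dict[str, int],
                    rng: np.random.Generator,
                    config: ModelConfig) -> dict[str, np.ndarray]:
    """Random per-word coefficient templates, orthogonalised across words.

    The raw draws are orthogonalised across labels (QR) before shaping,
    which guarantees separability of the lexicon in coefficient space.
    """
    n = len(labels)
    dim = config.nq_f * config.nq_t
    if n > dim:
        raise ValueError("more labels than coefficient dimensions")
    flat = rng.standard_normal((dim, n))
    ortho, _ = np.linalg.qr(flat)
    templates = {}
    for i, label in enumerate(labels):
        raw = ortho[:, i].reshape(config.nq_f, config.nq_t)
        templates[label] = _shape_template(raw, syllables.get(label, 1),
                                           config)
    return templates


def _compound_template(parts: Sequence[np.ndarray],
                       config: ModelConfig) -> np.ndarray:
    """Template whose trajectory is the temporal concatenation of parts."""
    k0 = config.nf
    k_part = max(k0 // len(parts), config.nq_t)
    u_f = dct_basis(config.nf, config.nq_f)
    u_part = dct_basis(k_part, config.nq_t)
    g = np.concatenate([u_f @ q @ u_part.T for q in parts], axis=1)
    u_full = dct_basis(g.shape[1], config.nq_t)
    q = u_f.T @ g @ u_full
    q[0, 0] = 0.0
    return q


def _excise_from_context(word: AcousticEpoch,
                         left: AcousticEpoch, right: AcousticEpoch,
                         config: ModelConfig) -> AcousticEpoch:
    """Embed a word between two neighbours and excise it at envelope minima.

    Connected speech reaches the recogniser excised at smoothed-envelope
    minima, with the neighbouring words' edge material leaking into the
    epoch; training exemplars are cut out of exactly such a zero-gap
    context so the word models live on the distribution the parser
    produces.
    """
    from scipy.signal import argrelextrema
    samples = np.concatenate([left.samples, word.samples, right.samples])
    env = smoothed_envelope(samples, config.rate,
                            config.envelope_highpass, config.envelope_sigma)
    j1 = len(left.samples)
    j2 = j1 + len(word.samples)
    order = max(1, int(config.envelope_sigma * config.rate / 2))
    minima = argrelextrema(env, np.less_equal, order=order)[0]
    window = int(0.06 * config.rate)

    def nearest(j: int) -> int:
        near = minima[np.abs(minima - j) <= window]
        return int(near[np.argmin(np.abs(near - j))]) if len(near) else j

    return AcousticEpoch(samples[nearest(j1):nearest(j2)], config.rate)


def _recover_params(epoch: AcousticEpoch, config: ModelConfig
                    ) -> WordParameters:
    """Recognition front end at the reference formant scale (training path)."""
    fundamental = estimate_fundamental(epoch, config.f0_prior,
                                       config.f0_min, config.f0_max)
    traj = epoch_to_trajectory(epoch, fundamental, config.f1_reference,
                               config)
    env = smoothed_envelope(epoch.samples, epoch.rate,
                            config.envelope_highpass, config.envelope_sigma)
    return map_parameters(traj, fundamental, float(env.max()),
                          NoiseModel(0.0), config, formant_scale=1.0)


def _recover_coeffs(epoch: AcousticEpoch, config: ModelConfig) -> np.ndarray:
    return _recover_params(epoch, config).coeffs


def _exemplar_parameters(template: np.ndarray, duration: float,
                         jitter: float, rng: np.random.Generator,
                         config: ModelConfig) -> WordParameters:
    scale = jitter * np.sqrt(np.mean(template ** 2))
    coeffs = template + rng.standard_normal(template.shape) * scale
    prosody = ProsodyState(
        amplitude=float(np.exp(rng.normal(0.0, 0.05))),
        duration=float(np.clip(duration * np.exp(rng.normal(0.0, 0.03)),
                               config.min_dur, config.max_dur)),
        timbre=1.0,
        inflection=rng.normal(0.0, [0.01, 0.02, 0.02]),
    )
    speaker = SpeakerState(f0_mean=float(
        config.f0_prior * np.exp(rng.normal(0.0, 0.03))), formant_scale=1.0)
    return WordParameters(coeffs=coeffs, prosody=prosody, speaker=speaker)


def build_demo_lexicon(labels: Sequence[str] | None = None,
                       n_exemplars: int = 10,
                       jitter: float = 0.05,
                       seed: int = 0,
                       config: ModelConfig | None = None,
                       syllables: dict[str, int] | None = None,
                       durations: dict[str, float] | None = None,
                       compounds: dict[str, tuple[str, ...]] | None = None,
                       ) -> Lexicon:
    """Build and train a demo lexicon, deterministically per seed.

    Draws one orthogonalised random template per label, synthesises
    ``n_exemplars`` jittered tokens of each, recovers their coefficients
    with the recognition front end, and fits the Gaussian word models
    from those recovered exemplars.  ``compounds`` maps a label to the
    sequence of other labels whose trajectories it concatenates (the
    near-homophone construction).
    """
    config = config or ModelConfig()
    labels = tuple(labels if labels is not None else DEMO_WORDS)
    if len(labels) < 2:
        raise ValueError("a recognition lexicon needs at least two words")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in lexicon specification")
    syllables = dict(syllables if syllables is not None else DEMO_WORDS)
    compounds = compounds or {}
    rng = np.random.default_rng(seed)
    base_labels = [lb for lb in labels if lb not in compounds]
    templates = _seed_templates(base_labels, syllables, rng, config)
    for label, parts in compounds.items():
        templates[label] = _compound_template(
            [templates[p] for p in parts], config)

    # canonical per-word durations: the syllable-count typical value with
    # a per-word (seeded) spread, since real words of equal syllable
    # count still differ in typical length
    word_durations = {}
    for label in labels:
        if durations and label in durations:
            word_durations[label] = durations[label]
            continue
        if label in compounds:
            base = sum(SYLLABLE_DURATIONS.get(syllables.get(p, 1), 0.45)
                       for p in compounds[label])
        else:
            base = SYLLABLE_DURATIONS.get(syllables.get(label, 1), 0.45)
        word_durations[label] = float(np.clip(
            base * np.exp(rng.uniform(-0.12, 0.12)),
            config.min_dur, config.max_dur))

    def flank(exclude: str) -> AcousticEpoch:
        """A clipped edge of a random other word, for zero-gap context."""
        other = labels[rng.integers(len(labels))]
        params = _exemplar_parameters(templates[other],
                                      word_durations[other],
                                      jitter, rng, config)
        epoch = synthesize_word(params, config)
        k = min(len(epoch.samples), int(0.12 * config.rate))
        return AcousticEpoch(epoch.samples[:k] if rng.random() < 0.5
                             else epoch.samples[-k:], config.rate)

    def word_audio(label: str) -> AcousticEpoch:
        """One spoken token: plain word, or concatenated parts (compound).

        A compound (near-homophone) is trained on genuine run-together
        productions of its parts, so an utterance of the parts with no
        gap is acoustically indistinguishable from the compound — the
        ambiguity only priors can resolve.
        """
        if label in compounds:
            parts = [synthesize_word(
                _exemplar_parameters(templates[p],
                                     word_durations.get(
                                         p, SYLLABLE_DURATIONS.get(
                                             syllables.get(p, 1), 0.45)),
                                     jitter, rng, config), config).samples
                for p in compounds[label]]
            return AcousticEpoch(np.concatenate(parts), config.rate)
        params = _exemplar_parameters(templates[label],
                                      word_durations[label],
                                      jitter, rng, config)
        return synthesize_word(params, config)

    entries = []
    for label in labels:
        recovered = []
        spans = []
        for _ in range(n_exemplars):
            epoch = _excise_from_context(word_audio(label),
                                         flank(label), flank(label), config)
            first_gen = _recover_params(epoch, config)
            recovered.append(first_gen.coeffs)
            spans.append(first_gen.prosody.duration)
            # second generation: re-synthesise from the recovered
            # coefficients and recognise again, so the word model covers
            # both freshly spoken and internally regenerated tokens (the
            # generate-recognise loop is then self-consistent)
            regen = WordParameters(
                coeffs=first_gen.coeffs,
                prosody=ProsodyState(duration=word_durations[label]),
                speaker=SpeakerState(f0_mean=config.f0_prior))
            second_gen = _recover_params(
                _excise_from_context(synthesize_word(regen, config),
                                     flank(label), flank(label), config),
                config)
            recovered.append(second_gen.coeffs)
            spans.append(second_gen.prosody.duration)
        entries.append(train_lexical_entry(label, recovered,
                                           durations=spans))
    return Lexicon(entries=entries,
                   metadata={"durations": word_durations,
                             "seed": seed, "jitter": jitter,
                             "n_exemplars": n_exemplars})


def ambiguous_stream(lexicon: Lexicon, script: Sequence[str],
                     config: ModelConfig | None = None,
                     gap: float = 0.0, seed: int = 0,
                     ) -> tuple[AcousticEpoch, list[dict]]:
    """Synthesise a scripted utterance with ground-truth boundaries.

    With zero or small gaps the envelope stays above threshold across
    word boundaries, so the internal minima inside multisyllabic words
    compete with the true boundaries — the segmentation problem the
    active parser is built to resolve.
    """
    config = config or ModelConfig()
    for label in script:
        if label not in lexicon:
            raise KeyError(f"script word {label!r} not in lexicon")
    return synthesize_utterance(list(script), lexicon, config, gap=gap,
                                rng_seed=seed)


def homophone_lexicon(seed: int = 0,
                      config: ModelConfig | None = None,
                      n_exemplars: int = 10,
                      jitter: float = 0.05) -> Lexicon:
    """A small lexicon with a near-homophone compound.

    ``greyday`` is constructed so its trajectory is the concatenation of
    ``grey`` and ``day`` — the classic segmentation ambiguity in which
    only prior beliefs can decide between one word and two.
    """
    config = config or ModelConfig()
    labels = ("grey", "day", "greyday", "grade", "night")
    syllables = {"grey": 1, "day": 1, "grade": 1, "night": 1, "greyday": 2}
    return build_demo_lexicon(labels, n_exemplars=n_exemplars, jitter=jitter,
                              seed=seed, config=config, syllables=syllables,
                              compounds={"greyday": ("grey", "day")})
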