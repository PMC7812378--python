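"""Word-level probabilistic knowledge.

Each word in the lexicon carries a Gaussian likelihood model over its
lexical coefficients — the DCT coefficients of the (standardised) log
time-frequency trajectory — summarised by an elementwise mean and
precision (inverse variance).  A diagonal precision is used throughout:
with a handful of exemplars per word a full covariance would be rank
deficient, and only relative likelihoods matter for the categorical
posterior over words.

Discrete prosody and speaker attributes (amplitude, duration, timbre,
inflection; fundamental frequency, formant scaling) use the same
machinery via :class:`AttributeModel`: a Gaussian likelihood per level
combined with a categorical prior.  The default models have a single
uninformative level each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.special import logsumexp

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthesis import WordParameters

__all__ = [
    "CategoricalBelief",
    "LexicalEntry",
    "Lexicon",
    "AttributeModel",
    "train_lexical_entry",
    "log_likelihood",
    "posterior_from_likelihoods",
]

#: relative variance floor: this fraction of the mean squared coefficient
#: magnitude bounds the precision from above (duplicate exemplars would
#: otherwise imply an infinitely precise word model)
DEFAULT_VARIANCE_FLOOR_FRACTION = 1e-4

ATTRIBUTE_FACTORS = (
    "amplitude", "duration", "timbre", "inflection", "f0_speaker",
    "formant_scale",
)


# ----------------------------------------------------------------------
@dataclass
class CategoricalBelief:
    """A normalised categorical distribution over labelled alternatives."""

    support: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = tuple(self.support)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.support),):
            raise ValueError("probs must align with support")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probs.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-12:
            if total <= 0 or not np.isfinite(total):
                raise ValueError("belief has no mass")
            self.probs = self.probs / total

    @classmethod
    def uniform(cls, support: Sequence[str]) -> "CategoricalBelief":
        n = len(support)
        return cls(tuple(support), np.full(n, 1.0 / n))

    @classmethod
    def from_mapping(cls, support: Sequence[str],
                     weights: dict[str, float]) -> "CategoricalBelief":
        """Belief placing the given (unnormalised) weights, zero elsewhere."""
        unknown = set(weights) - set(support)
        if unknown:
            raise KeyError(f"labels not in support: {sorted(unknown)}")
        probs = np.array([weights.get(label, 0.0) for label in support], float)
        return cls(tuple(support), probs / probs.sum())

    def map_label(self) -> str:
        return self.support[int(np.argmax(self.probs))]

    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.support.index(label)])


# ----------------------------------------------------------------------
@dataclass
class LexicalEntry:
    """Gaussian sufficient statistics of one word's lexical coefficients.

    Entries may additionally carry Gaussian duration statistics (words
    have characteristic lengths); when present they contribute to the
    word likelihood, which penalises explaining a word fragment — or a
    run of several words — as a single lexical item.
    """

    label: str
    coeff_mean: np.ndarray
    coeff_precision: np.ndarray
    n_exemplars: int = 1
    duration_mean: float | None = None
    duration_precision: float | None = None

    def __post_init__(self) -> None:
        if (self.duration_precision is not None
                and self.duration_precision <= 0):
            raise ValueError("duration precision must be positive")
        self.coeff_mean = np.asarray(self.coeff_mean, dtype=float)
        self.coeff_precision = np.asarray(self.coeff_precision, dtype=float)
        if self.coeff_mean.shape != self.coeff_precision.shape:
            raise ValueError("mean and precision must share a shape")
        if not np.all(np.isfinite(self.coeff_mean)):
            raise ValueError(f"non-finite coefficient mean for {self.label!r}")
        if not (np.all(self.coeff_precision > 0)
                and np.all(np.isfinite(self.coeff_precision))):
            raise ValueError(
                f"precisions must be strictly positive and finite "
                f"for {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeff_mean.shape


@dataclass
class Lexicon:
    """An ordered collection of lexical entries with unique labels.

    ``metadata`` carries generator-side conveniences (typical per-word
    durations, coefficient shape) that travel with the serialised lexicon.
    """

    entries: list[LexicalEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("lexicon labels must be unique")
        shapes = {e.shape for e in self.entries}
        if len(shapes) > 1:
            raise ValueError("all entries must share one coefficient shape")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> LexicalEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(f"unknown word {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def duration_of(self, label: str, default: float = 0.5) -> float:
        return float(self.metadata.get("durations", {}).get(label, default))

    # ambient (pre-lexical) coefficient statistics ----------------------
    def prior_variance(self) -> np.ndarray:
        """Per-coefficient variance pooled over the lexicon.

        This is the variance of a coefficient before the word identity is
        known (between-word scatter of the means plus mean within-word
        variance); it defines the ambient prior precision used by the
        speech-in-noise model.
        """
        means = np.stack([e.coeff_mean for e in self.entries])
        within = np.stack([1.0 / e.coeff_precision for e in self.entries])
        var = means.var(axis=0) + within.mean(axis=0)
        return np.maximum(var, 1e-12)

    def prior_duration_variance(self) -> float | None:
        """Pooled duration variance (the pre-lexical duration prior)."""
        stats = [(e.duration_mean, 1.0 / e.duration_precision)
                 for e in self.entries if e.duration_mean is not None]
        if not stats:
            return None
        means = np.array([m for m, _ in stats])
        within = np.array([v for _, v in stats])
        return float(max(means.var() + within.mean(), 1e-12))

    # serialisation -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "config": {
                "coeff_shape": list(self.entries[0].shape) if self.entries
                else None,
            },
            "metadata": self.metadata,
            "entries": [
                {
                    "label": e.label,
                    "coeff_mean": e.coeff_mean.tolist(),
                    "coeff_precision": e.coeff_precision.tolist(),
                    "n_exemplars": e.n_exemplars,
                    "duration_mean": e.duration_mean,
                    "duration_precision": e.duration_precision,
                }
                for e in self.entries
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Lexicon":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            s = str(source)
            text = s if s.lstrip().startswith("{") else Path(s).read_text()
        doc = json.loads(text)
        entries = [
            LexicalEntry(
                label=d["label"],
                coeff_mean=np.array(d["coeff_mean"], float),
                coeff_precision=np.array(d["coeff_precision"], float),
                n_exemplars=int(d.get("n_exemplars", 1)),
                duration_mean=d.get("duration_mean"),
                duration_precision=d.get("duration_precision"),
            )
            for d in doc["entries"]
        ]
        return cls(entries=entries, metadata=doc.get("metadata", {}))


@dataclass
class AttributeModel:
    """Gaussian level models for one prosody or speaker factor."""

    factor_name: str
    levels: list[tuple[str, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if self.factor_name not in ATTRIBUTE_FACTORS:
            raise ValueError(f"unknown factor {self.factor_name!r}")
        if not self.levels:
            raise ValueError("an attribute model needs at least one level")
        checked = []
        for name, mean, prec in self.levels:
            mean = np.atleast_1d(np.asarray(mean, float))
            prec = np.atleast_1d(np.asarray(prec, float))
            if np.any(prec <= 0):
                raise ValueError("level precisions must be positive")
            checked.append((name, mean, prec))
        self.levels = checked

    def posterior(self, value: np.ndarray,
                  prior: CategoricalBelief | None = None) -> CategoricalBelief:
        """Categorical posterior over levels given a MAP attribute value."""
        value = np.atleast_1d(np.asarray(value, float))
        logliks = np.array([
            float(0.5 * np.sum(np.log(prec)) - 0.5 * np.sum(
                prec * (value - mean) ** 2))
            for _, mean, prec in self.levels
        ])
        if prior is None:
            prior = CategoricalBelief.uniform([n for n, _, _ in self.levels])
        return posterior_from_likelihoods(logliks, prior)

    @classmethod
    def uninformative(cls, factor_name: str,
                      dim: int = 1) -> "AttributeModel":
        """A single broad level: carries no information about the factor."""
        return cls(factor_name,
                   [("any", np.zeros(dim), np.full(dim, 1e-6))])


def default_attribute_models() -> dict[str, AttributeModel]:
    dims = {"inflection": 3}
    return {name: AttributeModel.uninformative(name, dims.get(name, 1))
            for name in ATTRIBUTE_FACTORS}


# ----------------------------------------------------------------------
def train_lexical_entry(label: str,
                        exemplars: Sequence[np.ndarray],
                        variance_floor: float | None = None,
                        durations: Sequence[float] | None = None,
                        duration_sd_floor: float = 0.02) -> LexicalEntry:
    """Fit a word model from exemplar coefficient matrices.

    The mean is the elementwise sample mean and the precision the
    reciprocal of the elementwise *population* variance (``ddof=0``),
    floored at ``variance_floor`` so duplicate exemplars cannot yield an
    infinitely precise model.  When ``variance_floor`` is None it defaults
    to ``1e-4`` of the mean squared coefficient magnitude.  Optional
    exemplar ``durations`` (seconds) train the word's duration model,
    with the standard deviation floored at ``duration_sd_floor``.
    """
    if len(exemplars) == 0:
        raise ValueError(f"no exemplars supplied for {label!r}")
    mats = [np.asarray(m, dtype=float) for m in exemplars]
    shape = mats[0].shape
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(
                f"exemplar {k} for {label!r} has shape {m.shape}, "
                f"expected {shape}")
    stack = np.stack(mats)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=0)
    if variance_floor is None:
        variance_floor = (DEFAULT_VARIANCE_FLOOR_FRACTION
                          * max(float(np.mean(mean ** 2)), 1e-12))
    if variance_floor <= 0:
        raise ValueError("variance_floor must be positive")
    precision = 1.0 / np.maximum(var, variance_floor)
    dur_mean = dur_prec = None
    if durations is not None and len(durations) > 0:
        durations = np.asarray(durations, dtype=float)
        dur_mean = float(durations.mean())
        dur_sd = max(float(durations.std(ddof=0)), duration_sd_floor)
        dur_prec = 1.0 / dur_sd ** 2
    return LexicalEntry(label=label, coeff_mean=mean,
                        coeff_precision=precision,
                        n_exemplars=len(mats),
                        duration_mean=dur_mean,
                        duration_precision=dur_prec)


def log_likelihood(params: "WordParameters | np.ndarray",
                   entry: LexicalEntry,
                   extra_variance: np.ndarray | float | None = None,
                   extra_duration_variance: float | None = None) -> float:
    """Gaussian log density of estimated coefficients under a word model.

    Returned up to the ``-n/2 log(2 pi)`` constant shared by every entry.
    ``extra_variance`` adds observation noise to the entry's own variance
    (the speech-in-noise manipulation: less precise sensory evidence).
    """
    coeffs = getattr(params, "coeffs", params)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != entry.shape:
        raise ValueError(
            f"coefficient shape {coeffs.shape} does not match entry "
            f"{entry.label!r} shape {entry.shape}")
    variance = 1.0 / entry.coeff_precision
    if extra_variance is not None:
        variance = variance + extra_variance
    precision = 1.0 / variance
    resid = coeffs - entry.coeff_mean
    total = float(0.5 * np.sum(np.log(precision))
                  - 0.5 * np.sum(precision * resid ** 2))
    prosody = getattr(params, "prosody", None)
    if entry.duration_mean is not None and prosody is not None:
        dur_var = 1.0 / entry.duration_precision
        if extra_duration_variance is not None:
            dur_var = dur_var + extra_duration_variance
        d = prosody.duration - entry.duration_mean
        total += float(-0.5 * np.log(dur_var) - 0.5 * d ** 2 / dur_var)
    return total


def posterior_from_likelihoods(logliks: Sequence[float] | np.ndarray,
                               prior: CategoricalBelief) -> CategoricalBelief:
    """Combine per-label log likelihoods with a categorical prior.

    Computed in log space (max subtracted before exponentiation), so the
    result is invariant under adding any constant to all log likelihoods.
    """
    logliks = np.asarray(logliks, dtype=float)
    if logliks.shape != (len(prior.support),):
        raise ValueError("log-likelihoods must align with the prior support")
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior.probs)
    log_post = log_prior + logliks
    if np.all(np.isneginf(log_post)):
        raise ValueError("prior places no mass on any supported label")
    log_post = log_post - logsumexp(log_post[np.isfinite(log_post)])
    probs = np.exp(log_post)
    probs[~np.isfinite(log_post)] = 0.0
    return CategoricalBelief(prior.support, probs / probs.sum())
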