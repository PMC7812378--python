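"""Belief updating as neuronal dynamics.

Recognising a word moves a categorical belief from its prior to its
posterior.  Simulated neuronal populations — one per word in the
lexicon — perform this movement by a gradient flow on free energy: the
log-expectation ``v`` of each population (a proxy for depolarisation)
relaxes towards the optimal log posterior, driven by the prediction
error between the two, while firing rates encode the softmax
expectations themselves.  ERP-like traces are the band-pass filtered
temporal derivative of ``v``; their variance across populations is the
evoked power, and the KL divergence from prior to posterior (Bayesian
surprise, the complexity of the update) is the information-theoretic
quantity those responses track.

Beliefs are floored at ``exp(-8)`` before taking logs so that
depolarisations saturate rather than diverge for words assigned zero
prior probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.special import logsumexp, softmax

from .lexicon import CategoricalBelief

__all__ = [
    "BeliefTrajectory",
    "SurpriseRecord",
    "floored_log",
    "belief_gradient_flow",
    "simulated_erp",
    "bayesian_surprise",
    "evoked_power",
]


# ----------------------------------------------------------------------
@dataclass
class BeliefTrajectory:
    """Time-stepped log-expectations and expectations over words.

    ``v`` has one row per update step (row 0 is the prior state) and one
    column per word; ``s`` is the row-wise softmax of ``v``.
    """

    v: np.ndarray
    s: np.ndarray
    dt: float = 0.016
    support: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        self.s = np.asarray(self.s, float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("log-expectations must be finite")
        if not np.allclose(self.s.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("expectations must normalise per step")

    @property
    def n_steps(self) -> int:
        return self.v.shape[0]

    @property
    def terminal_belief(self) -> np.ndarray:
        return self.s[-1]


@dataclass
class SurpriseRecord:
    """Belief-updating summary for one word."""

    kl: float
    erp: np.ndarray
    evoked_power: np.ndarray
    peak_power: float

    def __post_init__(self) -> None:
        if self.kl < 0:
            raise ValueError("KL divergence cannot be negative")


# ----------------------------------------------------------------------
def floored_log(probs: np.ndarray, floor: float) -> np.ndarray:
    """Log of a belief floored at ``floor`` and renormalised."""
    p = np.maximum(np.asarray(probs, float), floor)
    return np.log(p / p.sum())


def belief_gradient_flow(log_prior: np.ndarray, logliks: np.ndarray,
                         n_steps: int = 32, kappa: float = 0.25,
                         dt: float = 0.016,
                         support: tuple[str, ...] = (),
                         floor: float | None = None) -> BeliefTrajectory:
    """Gradient flow of log-expectations towards the Bayes log posterior.

    The prediction error is the difference between the optimal log
    posterior — ``log_prior + logliks`` normalised — and the current
    log-expectation; each of the ``n_steps`` updates moves ``v`` a
    fraction ``kappa`` of the way along it.  The fixed point satisfies
    ``softmax(v) == exact Bayes posterior``, and the convergence is
    geometric with ratio ``1 - kappa``.

    With ``floor`` set, both the starting state and the target are
    floored beliefs: depolarisations saturate at ``log(floor)`` instead
    of diverging for words the evidence rules out entirely (the fixed
    point is then the floored posterior).
    """
    log_prior = np.asarray(log_prior, float)
    logliks = np.asarray(logliks, float)
    if log_prior.shape != logliks.shape:
        raise ValueError("prior and likelihood vectors must align")
    if not (np.all(np.isfinite(log_prior)) and np.all(np.isfinite(logliks))):
        raise ValueError("inputs must be finite")
    if not 0.0 < kappa <= 1.0:
        raise ValueError("kappa must lie in (0, 1]")
    v0 = log_prior - logsumexp(log_prior)
    target = log_prior + logliks
    target = target - logsumexp(target)
    if floor is not None:
        v0 = floored_log(np.exp(v0), floor)
        target = floored_log(np.exp(target), floor)
    v = np.empty((n_steps, len(v0)))
    v[0] = v0
    for t in range(1, n_steps):
        error = target - v[t - 1]
        v[t] = v[t - 1] + kappa * error
    s = softmax(v, axis=1)
    return BeliefTrajectory(v=v, s=s, dt=dt, support=tuple(support))


def simulated_erp(trajectory: BeliefTrajectory,
                  band: tuple[float, float] = (1.0, 16.0)) -> np.ndarray:
    """Band-passed temporal derivative of the log-expectations.

    One trace per population, zero-phase filtered so the output length
    equals the trajectory length; the first difference is padded with a
    leading zero.  Units are arbitrary (a single global scale relates
    them to microvolts).
    """
    t = trajectory.n_steps
    if t < 8:
        raise ValueError("need at least 8 steps to filter an ERP")
    fs = 1.0 / trajectory.dt
    if band[1] >= fs / 2:
        raise ValueError("band upper edge must lie below the Nyquist "
                         "frequency of the update rate")
    deriv = np.diff(trajectory.v, axis=0) / trajectory.dt
    deriv = np.vstack([np.zeros((1, deriv.shape[1])), deriv])
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    padlen = min(3 * 6, t - 1)
    return sps.sosfiltfilt(sos, deriv, axis=0, padlen=padlen)


def bayesian_surprise(prior: CategoricalBelief,
                      posterior: CategoricalBelief) -> float:
    """KL divergence from prior to posterior beliefs, in nats."""
    if prior.support != posterior.support:
        raise ValueError("supports must match")
    q = posterior.probs
    p = prior.probs
    if np.any((q > 0) & (p == 0)):
        warnings.warn("posterior places mass where the prior has none; "
                      "surprise is infinite", RuntimeWarning, stacklevel=2)
        return float(np.inf)
    nz = q > 0
    return float(np.sum(q[nz] * (np.log(q[nz]) - np.log(p[nz]))))


def evoked_power(erp: np.ndarray, dt: float = 0.016,
                 window: tuple[int, int] | None = None,
                 ) -> tuple[np.ndarray, float]:
    """Variance of ERP traces across populations, and its window peak.

    ``erp`` is (steps x populations).  When no window is given, the peak
    is taken over a peristimulus span of 500 ms from the start of the
    traces (about 31 bins at 16 ms).
    """
    erp = np.asarray(erp, float)
    if erp.ndim != 2 or erp.shape[1] < 2:
        raise ValueError("need at least two populations")
    power = erp.var(axis=1)
    if window is None:
        window = (0, min(len(power), int(round(0.5 / dt))))
    lo, hi = window
    peak = float(power[lo:hi].max()) if hi > lo else 0.0
    return power, peak
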