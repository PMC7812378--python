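# Methods

`activelisten` implements a generative model of spoken words, its
amortised Bayesian inversion, an active (free-energy minimising)
segmentation of continuous utterances, and a belief-updating simulator
that yields ERP-like neuronal response predictions. This note records
the model, the numerical choices, and what the synthetic test world
does and does not establish.

## The generative model of a word

A word is caused by three families of discrete states — *lexical*
(which word), *prosody* (amplitude, duration, timbre, inflection) and
*speaker* (mean fundamental frequency F0, formant scaling) — mapped to
continuous parameters and then to a waveform:

1. **Fundamental contour.** Instantaneous F0 over normalised time
   u ∈ [0,1] is
   `F0(u) = f0_mean · (1 + i₁ + i₂(u−½) + i₃((u−½)² − 1/12))`,
   an orthogonalised quadratic basis for offset, slope and curvature,
   clipped to [50, 500] Hz. Glottal transients are spaced by the
   reciprocal instantaneous F0, accumulated from t = 0 until the word
   duration is exceeded.
2. **Spectral trajectory.** The lexical coefficients Q (Nq_f × Nq_t
   DCT coefficients of the log time–frequency image; default 3 × 8)
   are expanded on orthonormal DCT bases to the formant grid — Nf = 64
   frequencies at multiples F1·(1 + j/8), F1 = 500 Hz × formant
   scale — and to one column per transient (a duration-normalised
   temporal resampling), then scaled by the timbre parameter and
   exponentiated: `W = exp(timbre · U_f Q U_tᵀ) > 0`.
3. **Transients.** Each column is rendered as a time-symmetric
   raised-cosine-windowed sum of cosines at the grid frequencies,
   phase-aligned at the segment midpoint, with duration one period of
   F1 (`round(rate/F1)` samples — the longest formant wavelength).
4. **Assembly.** Transients are overlap-added at the contour centre
   times; the buffer is scaled so the peak of its smoothed amplitude
   envelope equals the prosodic amplitude. The same envelope
   definition is used at recognition, which makes the gain a
   round-trippable parameter.

Default sample rate 22 050 Hz (the 64-bin grid tops out at ≈4.4 kHz at
scale 1, well below Nyquist).

## Inversion (recognition)

Recognition mirrors generation: a frequency-domain Gaussian band-pass
(half-octave half-width) around the prior speaker F0, peak picking
(minimum separation half the prior period) to recover glottal pulse
times; per-pulse segments one F1-period long projected onto cosines at
the formant grid (the cosine transform of their autocovariance, i.e.
the power spectrum at the grid) to recover the trajectory; then MAP
parameters: the standardised log trajectory is projected back onto the
DCT bases, the timbre estimate being its dispersion. Because the
trajectory is *measured* as power but *generated* as amplitude, the
standardisation absorbs the factor of two; timbre is therefore a
relative attribute, and regeneration uses the reference timbre 1.

**Resolution limit and calibration.** A 44-sample analysis window
cannot resolve 64 grid bins: the windowed-cosine smearing spans about
one formant interval, so only the slowest ~3 frequency DCT components
of the trajectory survive the synthesis→analysis loop. The lexical
code is therefore kept in that invertible subspace (Nq_f = 3), and the
residual per-row attenuation of the loop is measured once per
configuration by regressing recovered probe-word coefficients on their
generative values (24 probes, fixed internal seed) and divided out.
This amortisation calibration makes the generate→recognise loop
approximately idempotent, which the recursive round-trip simulation
requires.

**Formant scale** is selected by Bayesian model selection: each
candidate scale implies a different grid and segment length; the scale
whose analysis yields the highest lexicon evidence (log-sum-exp of
word likelihoods under a flat word prior) is chosen, ties towards 1.0.
A lexicon-free spectral fallback (mean log power at the candidate
grid) exists for bare epochs and flags low-confidence decisions.

**Word likelihoods.** Each lexicon entry holds elementwise Gaussian
mean/precision over coefficients (diagonal: with few exemplars a full
covariance is rank-deficient, and only relative likelihoods matter)
plus Gaussian duration statistics — words have characteristic lengths,
and the duration term is what stops a fragment of a long word from
masquerading as a short word, or two words as one. Precisions are
floored (variance floor 1e-4 of the mean squared coefficient) so
duplicate exemplars cannot become infinitely precise.

**Speech in noise.** A single multiplier γ on the observation-noise
variance: MAP coefficients shrink towards the zero prior mean by
λ = 1/(1+γ) (evidence precision ∝ 1/γ against the ambient prior
precision), and the categorical likelihood is evaluated with variances
inflated by γ times the pooled (pre-lexical) coefficient — and
duration — variance. Both inflations are needed: leaving duration
noiseless lets it discriminate at any γ and the posterior never
flattens.

## Active segmentation

The smoothed amplitude envelope (high-pass 100 Hz, rectify, Gaussian
σ = 16 ms, minimum subtracted) proposes boundaries inside a 1250 ms
analysis epoch: the onset is the last upward crossing of the threshold
(epoch max / 16) before the first supra-threshold envelope peak;
candidate offsets are the supra-threshold internal minima after the
peak, every downward crossing, and the epoch end when the envelope
never falls below threshold again (continuous speech), filtered to
plausible word durations (0.2–1.0 s). Each candidate interval is
scored by its variational free energy

    F = complexity − accuracy
      = KL(posterior ‖ prior) − E_posterior[log likelihood],

which equals the negative log evidence when the posterior is exact.
The selected interval minimises F *plus the best continuation F from
its offset* (one-word lookahead, with leftover supra-threshold signal
too short to be a word priced as a single bad pseudo-word): a myopic
argmin can prefer a fragment because the duration-normalised
likelihood makes every word cost roughly the same regardless of
length, so abandoning the remainder of a word would otherwise be free.
Ties break towards the shorter interval. The selected offset seeds the
next search; the formant scale is estimated on the first voiced word
and held for the utterance.

## Belief updating and simulated responses

Recognising a word moves a categorical belief from prior to posterior.
One population per word holds a log-expectation v (depolarisation
proxy); the prediction error is the difference between the optimal log
posterior and v, and v moves a fraction κ = 0.25 of the way along it
per 16 ms bin for 32 bins (≈500 ms). The fixed point is the exact
Bayes posterior (convergence ratio 1−κ; the oracle tests use 128 steps
where the residual is ≈1e-16). Firing rates are the softmax of v.
Beliefs are floored at exp(−8) and renormalised, so depolarisations
saturate rather than diverge for words the evidence excludes; the
floor was fixed a priori as a baseline-rate convention. ERPs are the
1–16 Hz band-passed (zero-phase, 2nd-order Butterworth) temporal
derivative of v, in arbitrary units with a single global scale.
Bayesian surprise is KL(posterior ‖ prior) of the floored beliefs;
evoked power is the variance of the ERP traces across populations,
with per-word peaks taken over a 500 ms peristimulus window.

## The synthetic test world

No external recordings are used. Demo words are random coefficient
templates, orthogonalised across labels, with a syllable-like level
contour (n humps, log-dips of 1.6) written into the frequency-constant
coefficient row; the temporal contour transmits exactly through the
analysis while the frequency rows are kept modest (row contrasts
0.25/0.35) so the log-spectral structure stays in the quasi-linear
regime of the analysis window. Typical durations are 0.32/0.45/0.65 s
for 1/2/3 syllables with a seeded ±12% per-word spread; exemplar
jitter is 5% rms; 10 exemplars per word are trained in two generations
(fresh synthesis, then a regenerated token) and excised from zero-gap
flanked context at envelope minima — i.e. the word models are trained
on the distribution the parser actually produces. A near-homophone
lexicon (grey / day / greyday, the compound trained on genuine
run-together productions of its parts) provides the classic
segmentation ambiguity that only priors can resolve.

What this world does *not* emulate: unvoiced phonemes and fricatives,
natural voice quality, coarticulation, multi-speaker babble, and —
importantly — the graded acoustic overlap between real words. Clean
synthesis plus orthogonalised templates gives likelihood margins of
tens to hundreds of nats, so lexical posteriors are numerically
one-hot for clean speech. Consequences worth knowing:

- Parsing and round-trip recursion are near-deterministic successes
  (that is what the margins buy).
- The no-prior increase in simulated ERP amplitude is floor-dominated:
  every losing population saturates at log-floor, and the measured
  increase (≈89%) exceeds the ≈50% seen with graded evidence. The
  direction of the effect is robust; its magnitude is a property of
  the saturated regime, not of the update equations.
- Across-population evoked power can transiently *rise* at small γ as
  updates de-synchronise before the noise suppresses them; the strict
  attenuation of surprise and power is assessed at γ ∈ (1, 4, 16),
  the regime where noise perceptibly degrades the posterior. The
  speech-in-noise comparisons use baseline γ = 4 (winner posterior
  ≈0.8) doubled to 8, where coefficient shrinkage (λ ratio ≈ 0.55)
  and the ≈2× attenuation of the prior-violation difference waveform
  both emerge from the model.

## Problem sizes

The shipped simulations use the 14-word lexicon, five-word sentences,
six-word alternating streams, 100-word recovery batches, 1000-instance
inference oracles, and 10 synthesis seeds for averaged effect sizes.

## Known limitations

- Greedy-with-lookahead segmentation is not global inference over the
  boundary lattice; pathological streams could defeat it.
- The formant-scale estimator needs a lexicon to be reliable; the
  spectral fallback is weak by construction.
- Attribute models for prosody/speaker levels default to single
  uninformative levels; posteriors over those factors are reported but
  carry no information until level inventories are supplied.
- ERP units are arbitrary; only comparisons within a simulation are
  meaningful.
- Random vocabularies are not all equally separable: for some lexicon
  seeds a pair of one-syllable words lands close together in the
  band-limited measurement space, and connected-speech recognition of
  those words becomes systematically unreliable even though isolated
  recognition still succeeds. The shipped demonstrations use a lexicon
  seed verified to be well-separated.
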