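# activelisten

Active listening: a generative model of spoken words, its Bayesian
inversion for word recognition, free-energy based segmentation of
continuous utterances, and a belief-updating simulator that produces
ERP-like neuronal response predictions — including the effects of
prior beliefs and of speech in noise.

The package is aimed at computational-neuroscience and
speech-modelling work: it is not a production speech recogniser, but a
fully inspectable simulation laboratory in which synthesis, inference,
segmentation and simulated electrophysiology share one probabilistic
model.

## The model in brief

A spoken word is caused by discrete **lexical**, **prosody**
(amplitude, duration, timbre, F0 inflection) and **speaker** (mean F0,
formant scale) states. The lexical state indexes a matrix of DCT
coefficients `Q` of the log time–frequency trajectory; after scaling
by the timbre parameter and exponentiation, `W = exp(τ · U_f Q U_tᵀ)`
gives one strictly positive spectral column per glottal pulse.
Each column is rendered as a time-symmetric transient (one first-formant
period long) at cosines on the formant grid `f_j = F1 (1 + j/8)`, and
the transients are overlap-added at intervals given by the reciprocal
instantaneous fundamental frequency.

Recognition inverts this chain with amortised MAP estimation:
band-pass filtering and peak picking recover the fundamental
intervals; per-pulse segments projected onto the formant grid recover
the trajectory; the standardised log trajectory projected back onto
the DCT basis gives the lexical coefficients, which are scored under
each word's Gaussian model and combined with a categorical prior.

Segmentation is a *covert action*: candidate word boundaries are
enumerated from the smoothed amplitude envelope (threshold crossings
and internal minima), and the interval minimising the variational free
energy

    F = KL(posterior ‖ prior) − E_posterior[log p(observations | word)]

is selected per word — the segmentation maximising the evidence for
the listener's model of how words are generated. Belief updating is
simulated as a gradient flow of log-expectations on free energy
(κ = 0.25, 16 ms bins); its band-passed temporal derivative is the
simulated ERP, the KL divergence from prior to posterior is the
Bayesian surprise it tracks, and the variance of the traces across
word populations is the evoked power.

No external data are needed: a synthetic 14-word lexicon (random,
orthogonalised coefficient templates with syllable-like envelope
contours) provides all stimuli, and the generate→recognise loop is the
validation path.

## Worked example

```
active-listen synth --script "is there a square above" --seed 0 -o sent.wav
active-listen parse sent.wav --seed 0 -o parse.json
```

prints `is there a square above`, and the parse records per word:

```
0.00-0.29  is       p=1.000 F=36.8
0.30-0.58  there    p=1.000 F=35.3
0.62-0.95  a        p=1.000 F=53.5
0.95-1.39  square   p=1.000 F=44.3
1.39-1.79  above    p=1.000 F=29.5
```

Each line is a selected word boundary (seconds), the maximum of the
lexical posterior, and the variational free energy of the chosen
interval (nats; the minimum among its candidate boundaries — smaller
means more evidence for that segmentation).

The canonical simulations are exposed as scenarios, e.g. the recursive
generate→recognise loop,

```
active-listen simulate --scenario round-trip --seed 0
# ... "first": ["is","there","a","square","above"],
#     "second": ["is","there","a","square","above"], "match": true
```

and the speech-in-noise violation-response analysis,

```
active-listen simulate --scenario speech-in-noise --seed 0
# ... "attenuation_factor": 1.967, "shrinkage_factor": 0.556
```

which shows that doubling the noise variance multiplier from the
moderate-noise baseline shrinks the recognised coefficients by about
half and attenuates the prior-violation (mismatch-style) difference
waveform by about a factor of two. Other scenarios:
`alternating-priors` (prior-dependent segmentation of a zero-gap
"triangle square ..." stream), `sentence-priors` (informative vs
uniform priors and the amplitude of simulated evoked responses), and
`surprise-power` (Bayesian surprise vs evoked power across words with
graded prior sharpness).

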