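"""Model inversion: pitch tracking, formant scale, trajectories, MAP."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from activelisten.config import ModelConfig
from activelisten.fixtures import random_probe_template
from activelisten.lexicon import CategoricalBelief
from activelisten.recognition import (FundamentalEstimate, NoiseModel,
                                      UnvoicedEpochError,
                                      epoch_to_trajectory,
                                      estimate_formant_scale,
                                      estimate_fundamental, map_parameters,
                                      recognize_word)
from activelisten.synthesis import (AcousticEpoch, ProsodyState,
                                    SpeakerState, WordParameters,
                                    sample_word_parameters,
                                    synthesize_word)


def pulse_train(f0: float, duration: float, rate: float) -> AcousticEpoch:
    """Synthetic glottal-pulse oracle signal with known rate."""
    n = int(duration * rate)
    x = np.zeros(n)
    t = 0.0
    while t < duration:
        idx = int(round(t * rate))
        if idx < n:
            x[idx] = 1.0
        t += 1.0 / f0
    return AcousticEpoch(x, rate)


class TestEstimateFundamental:
    def test_pulse_train_at_109_hz_with_96_hz_prior(self):
        epoch = pulse_train(109.0, 1.0, 22050.0)
        est = estimate_fundamental(epoch, f0_prior=96.0)
        assert est.f0_mean == pytest.approx(109.0, abs=1.0)

    def test_synthesised_word_f0_within_two_percent(self, rng, config):
        for f0 in (90.0, 120.0):
            params = WordParameters(
                random_probe_template(rng, 2, config),
                ProsodyState(duration=0.5),
                SpeakerState(f0_mean=f0))
            epoch = synthesize_word(params, config)
            est = estimate_fundamental(epoch, config.f0_prior)
            assert abs(est.f0_mean - f0) / f0 < 0.02

    def test_silent_epoch_raises_unvoiced(self, config):
        with pytest.raises(UnvoicedEpochError):
            estimate_fundamental(AcousticEpoch(np.zeros(22050), 22050.0),
                                 config.f0_prior)

    def test_too_short_epoch_raises(self, config):
        with pytest.raises(UnvoicedEpochError):
            estimate_fundamental(AcousticEpoch(np.ones(100), 22050.0),
                                 config.f0_prior)

    def test_inflection_recovered_for_rising_contour(self, rng, config):
        params = WordParameters(
            random_probe_template(rng, 1, config),
            ProsodyState(duration=0.5,
                         inflection=np.array([0.0, 0.15, 0.0])),
            SpeakerState(f0_mean=100.0))
        epoch = synthesize_word(params, config)
        est = estimate_fundamental(epoch, config.f0_prior)
        assert est.inflection_hat[1] > 0.05


class TestFormantScale:
    @pytest.mark.parametrize("true_scale", [1.0, 1.2])
    def test_round_trip_scale_selection(self, true_scale, demo_lexicon,
                                        config, rng):
        params = sample_word_parameters("square", demo_lexicon, config, rng)
        params.speaker.formant_scale = true_scale
        epoch = synthesize_word(params, config)
        scale, low_conf = estimate_formant_scale(epoch, config,
                                                 lexicon=demo_lexicon)
        assert scale == true_scale
        assert not low_conf

    def test_white_noise_returns_member_flagged(self, rng, config):
        epoch = AcousticEpoch(rng.standard_normal(22050), 22050.0)
        scale, low_conf = estimate_formant_scale(epoch, config)
        assert scale in config.scale_grid
        assert low_conf

    def test_empty_grid_rejected(self, config, rng):
        epoch = AcousticEpoch(rng.standard_normal(2048), 22050.0)
        with pytest.raises(ValueError):
            estimate_formant_scale(epoch, config, scale_grid=())


class TestEpochToTrajectory:
    def _fundamental(self, times):
        times = np.asarray(times)
        f0 = 1.0 / np.diff(times)
        return FundamentalEstimate(times, f0, float(f0.mean()), np.zeros(3))

    def test_pure_cosine_peaks_near_its_bin(self, config):
        grid = config.formant_grid()
        j = 24
        rate = config.rate
        t = np.arange(int(0.3 * rate)) / rate
        epoch = AcousticEpoch(np.cos(2 * np.pi * grid[j] * t), rate)
        fund = self._fundamental(np.arange(0.02, 0.28, 0.01))
        traj = epoch_to_trajectory(epoch, fund, config.f1_reference, config)
        peak_bins = traj.W.argmax(axis=0)
        # window smearing spans about one formant interval (8 bins)
        assert np.all(np.abs(peak_bins - j) <= 8)

    def test_silent_epoch_floored(self, config):
        epoch = AcousticEpoch(np.zeros(22050), 22050.0)
        fund = self._fundamental(np.arange(0.02, 0.9, 0.01))
        traj = epoch_to_trajectory(epoch, fund, config.f1_reference, config)
        assert np.all(traj.W > 0)
        assert traj.W.max() == pytest.approx(traj.W.min())

    def test_recovered_trajectory_tracks_analysis_prediction(self, rng,
                                                             config):
        """The measured trajectory correlates with the forward prediction.

        The analysis window (one F1 period) cannot resolve all 64 bins
        independently, so fidelity is assessed against the generative
        trajectory pushed through the same band-limited analysis: for a
        synthesised word the two log trajectories must correlate > 0.9.
        """
        from activelisten.recognition import _power_at
        from activelisten.signals import round_half_away
        from activelisten.synthesis import render_transient, \
            spectral_trajectory

        coeffs = random_probe_template(rng, 2, config)
        params = WordParameters(coeffs, ProsodyState(duration=0.5),
                                SpeakerState(f0_mean=100.0))
        epoch = synthesize_word(params, config)
        fund = estimate_fundamental(epoch, config.f0_prior)
        traj = epoch_to_trajectory(epoch, fund, config.f1_reference, config)

        grid = config.formant_grid()
        fine = spectral_trajectory(coeffs, 1.0, 256, grid)
        predicted = []
        for t_peak in fund.peak_times:
            u = min(t_peak / params.prosody.duration, 1.0 - 1e-9)
            col = fine.W[:, int(u * 256)]
            seg = render_transient(col, grid, config.f1_reference,
                                   config.rate)
            predicted.append(_power_at(grid, seg, config.rate))
        predicted = np.maximum(np.stack(predicted, axis=1), 1e-30)
        measured = np.log(traj.W)
        floored = np.isclose(measured, measured.min(axis=0), atol=1e-6).all(
            axis=0)
        keep = ~floored
        r = np.corrcoef(measured[:, keep].ravel(),
                        np.log(predicted)[:, keep].ravel())[0, 1]
        assert r > 0.9


class TestMapParameters:
    def _setup(self, rng, config):
        coeffs = random_probe_template(rng, 2, config)
        params = WordParameters(coeffs, ProsodyState(duration=0.45),
                                SpeakerState(f0_mean=100.0))
        epoch = synthesize_word(params, config)
        fund = estimate_fundamental(epoch, config.f0_prior)
        traj = epoch_to_trajectory(epoch, fund, config.f1_reference, config)
        return traj, fund

    def test_noiseless_limit_no_shrinkage(self, rng, config):
        traj, fund = self._setup(rng, config)
        clean = map_parameters(traj, fund, 1.0, NoiseModel(0.0), config)
        assert NoiseModel(0.0).shrinkage == 1.0
        noisy = map_parameters(traj, fund, 1.0, NoiseModel(1.0), config)
        assert np.allclose(noisy.coeffs, 0.5 * clean.coeffs)

    def test_infinite_noise_shrinks_to_prior_mean(self, rng, config):
        traj, fund = self._setup(rng, config)
        est = map_parameters(traj, fund, 1.0, NoiseModel(1e12), config)
        assert np.max(np.abs(est.coeffs)) < 1e-6

    def test_shrinkage_ratio_two_thirds(self):
        """Matched evidence/prior precision, then doubled noise."""
        lam1 = NoiseModel(1.0).shrinkage   # evidence precision == prior
        lam2 = NoiseModel(2.0).shrinkage
        assert lam1 == pytest.approx(0.5)
        assert lam2 / lam1 == pytest.approx(2.0 / 3.0)

    @given(st.floats(0.0, 100.0), st.floats(0.01, 100.0))
    def test_shrinkage_monotone_decreasing(self, g, dg):
        assert NoiseModel(g + dg).shrinkage < NoiseModel(g).shrinkage
        assert NoiseModel(0.0).shrinkage == 1.0

    def test_duration_and_timbre_estimates(self, rng, config):
        traj, fund = self._setup(rng, config)
        est = map_parameters(traj, fund, 0.7, NoiseModel(0.0), config)
        assert est.prosody.duration == pytest.approx(0.45, abs=0.03)
        assert est.prosody.timbre > 0
        assert est.prosody.amplitude == pytest.approx(0.7)


class TestRecognizeWord:
    def test_round_trip_map_label(self, demo_lexicon, config, rng):
        uniform = CategoricalBelief.uniform(demo_lexicon.labels)
        for label in ("square", "triangle", "is"):
            params = sample_word_parameters(label, demo_lexicon, config,
                                            rng)
            epoch = synthesize_word(params, config)
            result = recognize_word(epoch, uniform, demo_lexicon, config)
            assert result.map_label == label

    def test_delta_prior_absorbs_likelihood(self, demo_lexicon, config,
                                            rng):
        params = sample_word_parameters("square", demo_lexicon, config, rng)
        epoch = synthesize_word(params, config)
        delta = CategoricalBelief.from_mapping(demo_lexicon.labels,
                                               {"triangle": 1.0})
        result = recognize_word(epoch, delta, demo_lexicon, config)
        assert result.map_label == "triangle"
        assert result.lexical_posterior["triangle"] == pytest.approx(1.0)

    def test_duplicate_entries_return_prior(self, demo_lexicon, config,
                                            rng):
        from activelisten.lexicon import LexicalEntry, Lexicon
        e = demo_lexicon["square"]
        twins = Lexicon([
            LexicalEntry("w1", e.coeff_mean, e.coeff_precision,
                         duration_mean=e.duration_mean,
                         duration_precision=e.duration_precision),
            LexicalEntry("w2", e.coeff_mean, e.coeff_precision,
                         duration_mean=e.duration_mean,
                         duration_precision=e.duration_precision),
        ], metadata=demo_lexicon.metadata)
        prior = CategoricalBelief(("w1", "w2"), [0.8, 0.2])
        params = sample_word_parameters("square", demo_lexicon, config, rng)
        epoch = synthesize_word(params, config)
        result = recognize_word(epoch, prior, twins, config,
                                formant_scale=1.0)
        assert np.allclose(result.lexical_posterior.probs, [0.8, 0.2])

    def test_unvoiced_epoch_propagates(self, demo_lexicon, config):
        uniform = CategoricalBelief.uniform(demo_lexicon.labels)
        with pytest.raises(UnvoicedEpochError):
            recognize_word(AcousticEpoch(np.zeros(11025), 22050.0),
                           uniform, demo_lexicon, config)

    def test_attribute_posteriors_normalised(self, demo_lexicon, config,
                                             rng):
        params = sample_word_parameters("red", demo_lexicon, config, rng)
        epoch = synthesize_word(params, config)
        uniform = CategoricalBelief.uniform(demo_lexicon.labels)
        result = recognize_word(epoch, uniform, demo_lexicon, config)
        for post in {**result.prosody_posteriors,
                     **result.speaker_posteriors}.values():
            assert post.probs.sum() == pytest.approx(1.0)
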