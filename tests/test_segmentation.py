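"""Active segmentation: envelopes, candidates, free energy, parsing."""

import numpy as np
import pytest
from scipy.special import logsumexp

from activelisten.fixtures import ambiguous_stream, homophone_lexicon
from activelisten.lexicon import CategoricalBelief
from activelisten.segmentation import (Interval, amplitude_envelope,
                                       candidate_intervals,
                                       evaluate_interval, parse_sentence)
from activelisten.synthesis import (AcousticEpoch, sample_word_parameters,
                                    synthesize_word)


class TestAmplitudeEnvelope:
    def test_silence_gives_zero_envelope(self, config):
        env = amplitude_envelope(AcousticEpoch(np.zeros(22050), 22050.0),
                                 config)
        assert np.allclose(env, 0.0)
        assert len(env) == 22050

    def test_sign_flip_invariance(self, config, rng):
        x = rng.standard_normal(22050)
        a = amplitude_envelope(AcousticEpoch(x, 22050.0), config)
        b = amplitude_envelope(AcousticEpoch(-x, 22050.0), config)
        assert np.allclose(a, b)

    def test_word_in_silence_single_dominant_hump(self, demo_lexicon,
                                                  config, rng):
        params = sample_word_parameters("red", demo_lexicon, config, rng)
        word = synthesize_word(params, config)
        pad = np.zeros(int(0.25 * config.rate))
        audio = AcousticEpoch(np.concatenate([pad, word.samples, pad]),
                              config.rate)
        env = amplitude_envelope(audio, config)
        peak = np.argmax(env)
        assert len(pad) <= peak <= len(pad) + len(word.samples)
        assert env[:len(pad) // 2].max() < 0.25 * env.max()


class TestCandidateIntervals:
    def test_all_zero_envelope_empty(self, config):
        assert candidate_intervals(np.zeros(44100), 0, config) == []

    def test_search_start_beyond_signal_empty(self, config):
        assert candidate_intervals(np.ones(100), 200, config) == []

    def test_single_hump_single_candidate(self, config):
        n = int(0.6 * config.rate)
        t = np.linspace(0, 1, n)
        env = np.concatenate([np.zeros(1000),
                              np.sin(np.pi * t) ** 2,
                              np.zeros(1000)])
        cands = candidate_intervals(env, 0, config)
        assert len(cands) == 1
        assert cands[0].onset < 1000 + n // 4
        assert cands[0].offset > 1000 + 3 * n // 4

    def test_paused_two_word_stream_yields_three_candidates(
            self, demo_lexicon, config):
        """A three-syllable word before a pause: two internal minima plus
        the final threshold crossing give three boundary hypotheses."""
        stream, _ = ambiguous_stream(demo_lexicon, ["triangle", "square"],
                                     config, gap=0.2, seed=0)
        env = amplitude_envelope(stream, config)
        cands = candidate_intervals(env, 0, config)
        assert len(cands) == 3
        assert all(c.onset == cands[0].onset for c in cands)

    def test_durations_respect_configured_range(self, demo_lexicon,
                                                config):
        stream, _ = ambiguous_stream(demo_lexicon,
                                     ["triangle", "square"] * 2,
                                     config, gap=0.0, seed=1)
        env = amplitude_envelope(stream, config)
        for c in candidate_intervals(env, 0, config):
            assert config.min_dur <= c.duration(config.rate) <= \
                config.max_dur


class TestEvaluateInterval:
    def test_uniform_prior_equal_likelihoods(self, demo_lexicon, config,
                                             rng):
        """Duplicate-entry lexicon: complexity 0 and F = -L exactly."""
        from activelisten.lexicon import LexicalEntry, Lexicon
        e = demo_lexicon["square"]
        twins = Lexicon([
            LexicalEntry(f"w{i}", e.coeff_mean, e.coeff_precision,
                         duration_mean=e.duration_mean,
                         duration_precision=e.duration_precision)
            for i in range(3)])
        params = sample_word_parameters("square", demo_lexicon, config, rng)
        epoch = synthesize_word(params, config)
        iv = Interval(0, len(epoch.samples))
        prior = CategoricalBelief.uniform(twins.labels)
        ev = evaluate_interval(epoch, iv, prior, twins, config,
                               formant_scale=1.0)
        assert ev.complexity == pytest.approx(0.0, abs=1e-9)
        level = next(iter(ev.result.logliks.values()))
        assert ev.free_energy == pytest.approx(-level, abs=1e-6)

    def test_free_energy_equals_negative_log_evidence(self, demo_lexicon,
                                                      config, rng):
        """Brute-force evidence oracle: F = -log sum_w p_w exp(ll_w)."""
        params = sample_word_parameters("above", demo_lexicon, config, rng)
        epoch = synthesize_word(params, config)
        iv = Interval(0, len(epoch.samples))
        prior = CategoricalBelief.uniform(demo_lexicon.labels)
        ev = evaluate_interval(epoch, iv, prior, demo_lexicon, config)
        lls = np.array([ev.result.logliks[lb] for lb in prior.support])
        log_evidence = logsumexp(lls + np.log(prior.probs))
        assert ev.free_energy + log_evidence == pytest.approx(0.0,
                                                              abs=1e-9)
        assert ev.complexity >= 0.0

    def test_unvoiced_interval_infinite_free_energy(self, demo_lexicon,
                                                    config):
        silent = AcousticEpoch(np.zeros(22050), 22050.0)
        ev = evaluate_interval(silent, Interval(0, 11025),
                               CategoricalBelief.uniform(
                                   demo_lexicon.labels),
                               demo_lexicon, config)
        assert np.isinf(ev.free_energy)
        assert not ev.voiced


class TestParseSentence:
    def test_single_word_uniform_prior(self, demo_lexicon, config):
        audio, truth = ambiguous_stream(demo_lexicon, ["square"], config,
                                        seed=6)
        parse = parse_sentence(audio, "uniform", demo_lexicon, config)
        assert parse.labels == ["square"]

    def test_silence_parses_empty(self, demo_lexicon, config):
        silent = AcousticEpoch(np.zeros(2 * 22050), 22050.0)
        parse = parse_sentence(silent, "uniform", demo_lexicon, config)
        assert parse.labels == []

    def test_selected_interval_minimises_free_energy(self, demo_lexicon,
                                                     config):
        audio, _ = ambiguous_stream(demo_lexicon, ["triangle", "square"],
                                    config, gap=0.0, seed=2)
        parse = parse_sentence(audio, "uniform", demo_lexicon, config)
        for word in parse.words:
            finite = [ev.free_energy for ev in word["evaluation"]
                      if ev.voiced]
            # selection includes a continuation term, but the chosen
            # interval's own F can never undercut the candidate minimum
            assert word["free_energy"] >= min(finite) - 1e-9

    def test_selected_intervals_ordered_non_overlapping(self, demo_lexicon,
                                                        config):
        audio, _ = ambiguous_stream(demo_lexicon,
                                    ["triangle", "square"] * 3,
                                    config, gap=0.0, seed=3)
        parse = parse_sentence(audio, "uniform", demo_lexicon, config)
        bounds = [w["interval"] for w in parse.words]
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            assert a1 <= b0

    def test_prior_sequence_reuses_last_prior(self, demo_lexicon, config):
        audio, _ = ambiguous_stream(demo_lexicon, ["red", "red", "red"],
                                    config, gap=0.0, seed=4)
        prior = [CategoricalBelief.from_mapping(demo_lexicon.labels,
                                                {"red": 1.0})]
        parse = parse_sentence(audio, prior, demo_lexicon, config)
        assert parse.labels == ["red"] * 3

    def test_annotation_export(self, demo_lexicon, config, tmp_path):
        audio, _ = ambiguous_stream(demo_lexicon, ["square"], config,
                                    seed=6)
        parse = parse_sentence(audio, "uniform", demo_lexicon, config)
        out = tmp_path / "annot.tsv"
        parse.to_annotation(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].startswith("onset_s")
        assert len(lines) == 2
        parse.to_json(tmp_path / "parse.json")


class TestPriorSensitivity:
    def test_homophone_stream_disambiguated_only_by_priors(self, config):
        """Spoken 'grey day' merges into the compound under uniform
        priors; only the informative two-word prior recovers the truth."""
        lex = homophone_lexicon(seed=0, config=config)
        stream, truth = ambiguous_stream(lex, ["grey", "day"], config,
                                         gap=0.0, seed=2)
        uniform = parse_sentence(stream, "uniform", lex, config)
        informative = parse_sentence(
            stream,
            [CategoricalBelief.from_mapping(lex.labels, {"grey": 1.0}),
             CategoricalBelief.from_mapping(lex.labels, {"day": 1.0})],
            lex, config)
        assert informative.labels == ["grey", "day"]
        assert uniform.labels != informative.labels
        assert uniform.labels == ["greyday"]
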