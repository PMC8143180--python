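import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from guidedreading.assessment import TrialCondition
from guidedreading.guidance import TextMaterial, build_script
from guidedreading.protocols import ideal_profile, miscalibrated
from guidedreading.simulator import (
    SimReaderParams,
    corrupt_word,
    recognition_probability,
    simulate_free_reading,
    simulate_guided_reading,
    simulate_pseudoword_trial,
)

SUB_ONLY = {"omission": 0.0, "substitution": 1.0, "transposition": 0.0, "addition": 0.0}


class TestRecognitionProbability:
    def test_step_reader_at_threshold(self, step_reader):
        assert recognition_probability(3, 350, step_reader) == 1.0
        assert recognition_probability(3, 349, step_reader) == 0.0

    def test_one_letter_beyond_span_unreachable_on_grid(self, step_reader):
        # extra letter cost 300 ms pushes the threshold past 500 ms
        assert recognition_probability(4, 500, step_reader) == 0.0

    def test_shorter_strings_need_less_time_with_floor(self):
        p = SimReaderParams(true_span=5, threshold_time_ms=500.0)
        assert recognition_probability(4, 250, p) == 1.0  # 500-300=200 -> floor 150... passes at 200+
        assert recognition_probability(3, 149, p) == 0.0  # floor at 150 ms

    @pytest.mark.parametrize("slope", [math.inf, 0.5, 0.05])
    def test_monotone_in_time_and_length(self, slope):
        p = SimReaderParams(true_span=4, threshold_time_ms=350.0, slope=slope)
        grid_t = range(150, 601, 25)
        for n in range(2, 9):
            vals = [recognition_probability(n, t, p) for t in grid_t]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for t in grid_t:
            vals = [recognition_probability(n, t, p) for n in range(2, 9)]
            assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_finite_slope_near_certain_at_threshold(self):
        p = SimReaderParams(true_span=4, threshold_time_ms=350.0, slope=0.5)
        assert recognition_probability(4, 350, p) >= 0.95

    def test_invalid_inputs(self, step_reader):
        with pytest.raises(ValueError):
            recognition_probability(0, 300, step_reader)
        with pytest.raises(ValueError):
            recognition_probability(3, 0, step_reader)


class TestCorruptWord:
    def test_omission_only_shortens(self, rng):
        p = SimReaderParams(error_mixture={"omission": 1.0, "substitution": 0.0, "transposition": 0.0, "addition": 0.0})
        for _ in range(50):
            out = corrupt_word("bodan", p, rng)
            assert len(out) < 5 and out != "bodan"

    def test_response_always_differs(self, rng):
        p = SimReaderParams()
        for target in ["bo", "mul", "raket", "bodana"]:
            for _ in range(200):
                assert corrupt_word(target, p, rng) != target

    def test_zero_gradient_victims_uniform(self):
        p = SimReaderParams(position_gradient=0.0, error_mixture=SUB_ONLY)
        rng = np.random.default_rng(7)
        counts = np.zeros(5)
        for _ in range(10_000):
            out = corrupt_word("bodan", p, rng)
            (i,) = [k for k in range(5) if out[k] != "bodan"[k]]
            counts[i] += 1
        assert sps.chisquare(counts).pvalue > 0.01

    def test_positive_gradient_victims_increase(self):
        p = SimReaderParams(position_gradient=2.0, error_mixture=SUB_ONLY)
        rng = np.random.default_rng(7)
        counts = np.zeros(5)
        for _ in range(10_000):
            out = corrupt_word("bodan", p, rng)
            (i,) = [k for k in range(5) if out[k] != "bodan"[k]]
            counts[i] += 1
        assert all(b > a for a, b in zip(counts, counts[1:]))


class TestPseudowordTrial:
    def test_below_threshold_always_incorrect(self, step_reader, rng):
        cond = TrialCondition(4, 500)  # needs 650 ms -> unreachable
        for _ in range(50):
            t = simulate_pseudoword_trial(cond, "belo", step_reader, rng)
            assert not t.correct and t.response != "belo"

    def test_speech_onset_respects_tone(self, step_reader, rng):
        cond = TrialCondition(3, 350)
        onsets = [
            simulate_pseudoword_trial(cond, "mul", step_reader, rng).speech_onset_ms
            for _ in range(200)
        ]
        assert min(onsets) >= 700.0

    def test_list_pass_rate_within_binomial_ci(self):
        p = SimReaderParams(true_span=4, threshold_time_ms=350.0, slope=0.05)
        cond = TrialCondition(4, 300)
        prob = recognition_probability(4, 300, p)
        rng = np.random.default_rng(5)
        n = 2000
        k = sum(
            simulate_pseudoword_trial(cond, "belo", p, rng).correct for _ in range(n)
        )
        lo, hi = sps.binom.interval(0.999, n, prob)
        assert lo <= k <= hi


class TestFreeReading:
    def test_calibrated_reader_makes_no_errors(self, texts):
        p = SimReaderParams(
            true_span=4,
            threshold_time_ms=350.0,
            free_duration_scale=1.5,
            free_duration_sigma=0.0,
            premature_speech_p=0.0,
            regression_rate=0.0,
        )
        log = simulate_free_reading(texts[0].part(0), p, 3)
        assert log.n_errors == 0
        assert log.n_words == 29

    def test_overreaching_without_guessing_fails_long_words(self, texts):
        p = SimReaderParams(
            true_span=3,
            threshold_time_ms=250.0,
            attempted_span=7,
            guess_p=0.0,
            free_duration_scale=2.0,
            free_duration_sigma=0.0,
            premature_speech_p=0.0,
            regression_rate=0.0,
        )
        part = texts[0].part(0)
        log = simulate_free_reading(part, p, 3)
        for word, outcome in zip(part.words, log.outcomes):
            if len(word) > 3:
                assert not outcome.correct

    def test_regression_rate_matches_negative_saccade_fraction(self):
        p = SimReaderParams(true_span=3, attempted_span=3, regression_rate=0.3)
        text = TextMaterial.from_text(" ".join(["bodana"] * 600))
        log = simulate_free_reading(text, p, 11)
        sacc = np.asarray(log.saccades)
        assert sacc.size > 1000
        frac = (sacc < 0).mean()
        assert frac == pytest.approx(0.3, abs=0.03)

    def test_total_time_covers_fixations(self, texts, step_reader):
        log = simulate_free_reading(texts[0].part(0), step_reader, 1)
        assert log.total_time_s >= sum(f.duration_ms for f in log.fixations) / 1000 - 1e-9
        assert log.mode == "free"


class TestGuidedReading:
    def _guided(self, texts, params, seed=5):
        profile = ideal_profile(params)
        part = texts[0].part(0)
        script = build_script(part, profile)
        return simulate_guided_reading(script, part, params, seed), part

    def test_compliant_threshold_reader_reads_perfectly(self, texts, step_reader):
        log, part = self._guided(texts, step_reader)
        assert log.n_errors == 0
        assert log.n_words == len(part.words)

    def test_no_regressions_without_lapses(self, texts, step_reader):
        log, _ = self._guided(texts, step_reader)
        assert all(a > 0 for a in log.saccades)

    def test_lapses_produce_backward_saccades(self, texts, step_reader):
        p = replace(step_reader, compliance_lapse_p=0.3)
        log, _ = self._guided(texts, p, seed=8)
        assert any(a < 0 for a in log.saccades)
        assert log.n_errors == 0  # lapses do not unread segments

    def test_speech_onsets_after_tone_plus_reaction(self, texts, step_reader):
        log, _ = self._guided(texts, step_reader)
        starts = [f.t_start_ms for f in log.fixations]
        for onset, t0 in zip(log.speech_onsets_ms, starts):
            assert onset >= t0 + 1000 + 250

    def test_guided_slower_but_cleaner_than_free(self, texts):
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            base = SimReaderParams(true_span=3, threshold_time_ms=400.0, seed=seed)
            p = miscalibrated(base)
            part = texts[2].part(0)
            free = simulate_free_reading(part, p, seed)
            script = build_script(part, ideal_profile(p))
            guided = simulate_guided_reading(script, part, p, seed + 1)
            assert guided.total_time_s > free.total_time_s
            wins += guided.n_errors < free.n_errors
        assert wins >= 0.9 * n_seeds
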