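"""Synthetic readers standing in for human subjects.

A reader is parameterized by a true recognition span s* (letters
recognizable in one fixation) and a threshold fixation time T*.
Recognition follows temporal summation: the probability of recognizing
an n-letter string after fixating it for t ms is monotone nondecreasing
in t and nonincreasing in n.  The time needed for a string is

    tau(n) = T* + kappa * (n - s*)          for n >= s*
    tau(n) = max(150, T* - kappa * (s* - n)) for n < s*

with kappa the extra-letter time cost.  An infinite psychometric slope
gives the deterministic step reader (recognize iff t >= tau(n)); a
finite slope gives a logistic curve anchored so that recognition at the
threshold point is near-certain (p = 0.995), consistent with a reader
who passes a 19-of-20 criterion at threshold.

Failed recognitions produce letter errors (omission, substitution,
transposition, addition) with victims drawn with a left-to-right
position gradient, reproducing the empirical increase of misreading
rates toward word endings.  Free reading is modelled as fixation chunks
of the reader's attempted span (which may exceed s*, leaving guessed
gap letters), with premature fixations and regressions; guided reading
follows a guidance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assessment import TrialCondition, TrialResult
from .guidance import GuidanceScript, TextMaterial
from .scoring import WordOutcome, classify_response
from .stimuli import CONSONANTS, VOWELS

__all__ = [
    "SimReaderParams",
    "FixationRecord",
    "SessionLog",
    "recognition_probability",
    "corrupt_word",
    "simulate_pseudoword_trial",
    "simulate_free_reading",
    "simulate_guided_reading",
]

_ALPHABET = VOWELS + CONSONANTS
#: Logit anchor: a finite-slope reader recognizes at threshold with p=0.995.
_ANCHOR = math.log(0.995 / 0.005)
#: Temporal summation is ineffective below this floor.
_TAU_FLOOR_MS = 150.0


def _default_mixture() -> dict[str, float]:
    return {"omission": 0.35, "substitution": 0.40, "transposition": 0.15, "addition": 0.10}


@dataclass(frozen=True)
class SimReaderParams:
    """Generative parameters of one synthetic reader."""

    true_span: int = 4                   # s*, letters
    threshold_time_ms: float = 350.0     # T*, ms
    slope: float = math.inf              # per ms; inf = deterministic step
    extra_letter_cost_ms: float = 300.0  # kappa
    attempted_span: int | None = None    # letters used in free reading (default s*)
    premature_speech_p: float = 0.0      # prob. of a cut-short free fixation
    regression_rate: float = 0.0         # per-saccade backward probability
    position_gradient: float = 1.0       # >=0; error weight rise left->right
    error_mixture: dict[str, float] = field(default_factory=_default_mixture)
    guess_p: float = 0.25                # prob. a gap letter is guessed right
    seed: int | None = None
    # latency model (speech onset = max(retrieval, tone) + reaction)
    retrieval_mean_ms: float = 1250.0
    retrieval_sd_ms: float = 300.0
    reaction_mean_ms: float = 150.0
    reaction_sd_ms: float = 50.0
    # free reading: fixation duration ~ free_duration_scale * T* * lognormal
    free_duration_scale: float = 0.75
    free_duration_sigma: float = 0.25
    compliance_lapse_p: float = 0.0      # guided-mode regression probability
    age_months: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.true_span <= 8:
            raise ValueError("true_span must be in [1, 8]")
        if self.attempted_span is not None and not 1 <= self.attempted_span <= 8:
            raise ValueError("attempted_span must be in [1, 8]")
        for name in ("premature_speech_p", "regression_rate", "guess_p", "compliance_lapse_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.position_gradient < 0:
            raise ValueError("position_gradient must be >= 0")
        total = sum(self.error_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error mixture must sum to 1, sums to {total}")

    @property
    def span_used(self) -> int:
        return self.attempted_span if self.attempted_span is not None else self.true_span


@dataclass(frozen=True)
class FixationRecord:
    t_start_ms: float
    duration_ms: float
    offset: int

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass(frozen=True)
class SessionLog:
    outcomes: tuple[WordOutcome, ...]
    fixations: tuple[FixationRecord, ...]
    saccades: tuple[int, ...]
    speech_onsets_ms: tuple[float, ...]
    total_time_s: float
    mode: str  # "free" | "guided"
    seed: int | None = None

    @property
    def n_words(self) -> int:
        return len(self.outcomes)

    @property
    def n_errors(self) -> int:
        return sum(not o.correct for o in self.outcomes)


def _tau(n: int, params: SimReaderParams) -> float:
    s, t_star, kappa = params.true_span, params.threshold_time_ms, params.extra_letter_cost_ms
    if n >= s:
        return t_star + kappa * (n - s)
    return max(_TAU_FLOOR_MS, t_star - kappa * (s - n))


def recognition_probability(n: int, t: float, params: SimReaderParams) -> float:
    """Probability of recognizing an n-letter string fixated for t ms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if t <= 0:
        raise ValueError("t must be positive")
    tau = _tau(n, params)
    if math.isinf(params.slope):
        return 1.0 if t >= tau else 0.0
    x = params.slope * (t - tau) + _ANCHOR
    return 1.0 / (1.0 + math.exp(-x))


def _victim_position(length: int, params: SimReaderParams, rng: np.random.Generator) -> int:
    if length == 1:
        return 0
    w = 1.0 + params.position_gradient * np.arange(length) / (length - 1)
    return int(rng.choice(length, p=w / w.sum()))


def corrupt_word(target: str, params: SimReaderParams, rng: np.random.Generator) -> str:
    """Produce a misreading of ``target`` (guaranteed to differ).

    One letter-error event is drawn from the reader's error-type
    mixture; the victim position is drawn with weights rising from left
    to right according to ``position_gradient``.
    """
    kinds = sorted(params.error_mixture)
    probs = np.array([params.error_mixture[k] for k in kinds])
    for _ in range(100):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        i = _victim_position(len(target), params, rng)
        if kind == "omission":
            out = target[:i] + target[i + 1 :]
        elif kind == "substitution":
            pool = [c for c in _ALPHABET if c != target[i]]
            out = target[:i] + pool[rng.integers(len(pool))] + target[i + 1 :]
        elif kind == "addition":
            out = target[:i] + _ALPHABET[rng.integers(len(_ALPHABET))] + target[i:]
        else:  # transposition: swap with the right neighbour (left at word end)
            j = i + 1 if i + 1 < len(target) else i - 1
            if j < 0:
                continue
            i, j = min(i, j), max(i, j)
            out = target[:i] + target[j] + target[i + 1 : j] + target[i] + target[j + 1 :]
        if out != target:
            return out
    # degenerate targets (e.g. "aa" with a transposition-only mixture)
    return target[:-1] if len(target) > 1 else target + target


def _speech_onset(params: SimReaderParams, rng: np.random.Generator, tone_ms: float) -> float:
    retrieval = max(0.0, rng.normal(params.retrieval_mean_ms, params.retrieval_sd_ms))
    reaction = max(0.0, rng.normal(params.reaction_mean_ms, params.reaction_sd_ms))
    return max(retrieval, tone_ms) + reaction


def simulate_pseudoword_trial(
    condition: TrialCondition,
    target: str,
    params: SimReaderParams,
    rng: np.random.Generator,
    tone_ms: float = 700.0,
) -> TrialResult:
    """One assessment trial: recognize-or-corrupt plus a speech latency.

    The guard tone at ``tone_ms`` forbids earlier pronunciation, so the
    speech onset is max(retrieval time, tone) plus a reaction time.
    """
    p = recognition_probability(condition.length, condition.presentation_ms, params)
    correct = bool(rng.random() < p)
    response = target if correct else corrupt_word(target, params, rng)
    return TrialResult(
        target=target,
        response=response,
        correct=correct,
        speech_onset_ms=_speech_onset(params, rng, tone_ms),
    )


def _free_fixation_duration(params: SimReaderParams, rng: np.random.Generator) -> float:
    sigma = params.free_duration_sigma
    base = params.free_duration_scale * params.threshold_time_ms
    dur = base * math.exp(rng.normal(-0.5 * sigma**2, sigma))
    if params.premature_speech_p and rng.random() < params.premature_speech_p:
        dur *= 0.5
    return max(50.0, dur)


def _read_chunk(chunk: str, duration: float, params: SimReaderParams, rng: np.random.Generator) -> str:
    """Response letters produced for one free-reading fixation chunk.

    Only the first min(s*, attempted span) letters fall inside the
    recognizable window; the remaining gap letters are guessed.
    """
    prefix_len = min(params.true_span, len(chunk))
    prefix = chunk[:prefix_len]
    p = recognition_probability(prefix_len, duration, params)
    got = prefix if rng.random() < p else corrupt_word(prefix, params, rng)
    gap = []
    for ch in chunk[prefix_len:]:
        if rng.random() < params.guess_p:
            gap.append(ch)
        else:
            pool = [c for c in _ALPHABET if c != ch]
            gap.append(pool[rng.integers(len(pool))])
    return got + "".join(gap)


def simulate_free_reading(
    text: TextMaterial,
    params: SimReaderParams,
    rng: np.random.Generator | int | None = None,
) -> SessionLog:
    """Unguided reading: self-chosen chunks, durations, and regressions.

    The reader advances in chunks of the attempted span.  Each planned
    forward saccade is replaced, with probability ``regression_rate``,
    by a regression to the previous chunk (a refixation without
    re-scoring), so the fraction of negative saccades equals the
    regression rate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    span = params.span_used
    # chunk geometry over the rendered line
    chunks: list[tuple[int, str, int]] = []  # (word_idx, letters, abs fixation offset)
    word_start = 0
    for w_idx, word in enumerate(text.words):
        for start in range(0, len(word), span):
            piece = word[start : start + span]
            fix = word_start + start + math.ceil(len(piece) / 2) - 1
            chunks.append((w_idx, piece, fix))
        word_start += len(word) + 1
    responses: dict[int, list[str]] = {i: [] for i in range(len(text.words))}
    fixations: list[FixationRecord] = []
    saccades: list[int] = []
    speech_onsets: list[float] = []
    t = 0.0
    idx = 0
    prev_fix: int | None = None

    def visit(i: int, score: bool) -> None:
        nonlocal t, prev_fix
        dur = _free_fixation_duration(params, rng)
        fix = chunks[i][2]
        fixations.append(FixationRecord(t, dur, fix))
        if prev_fix is not None:
            saccades.append(fix - prev_fix)
        prev_fix = fix
        t += dur
        if score:
            responses[chunks[i][0]].append(_read_chunk(chunks[i][1], dur, params, rng))

    visit(0, True)
    pos = 0  # current chunk; idx is the scored frontier
    while idx < len(chunks) - 1:
        if pos > 0 and params.regression_rate and rng.random() < params.regression_rate:
            pos -= 1
            visit(pos, False)  # regression: refixate, no rescoring
        else:
            idx += 1
            pos = idx
            visit(pos, True)
    # one speech onset per word, clocked from that word's first fixation
    for w_idx in range(len(text.words)):
        speech_onsets.append(max(0.0, rng.normal(params.retrieval_mean_ms, params.retrieval_sd_ms)))
    outcomes = tuple(
        classify_response(word, "".join(responses[w_idx]))
        for w_idx, word in enumerate(text.words)
    )
    total_s = t / 1000.0
    return SessionLog(
        outcomes=outcomes,
        fixations=tuple(fixations),
        saccades=tuple(saccades),
        speech_onsets_ms=tuple(speech_onsets),
        total_time_s=total_s,
        mode="free",
    )


def simulate_guided_reading(
    script: GuidanceScript,
    text: TextMaterial,
    params: SimReaderParams,
    rng: np.random.Generator | int | None = None,
) -> SessionLog:
    """Computer-guided reading along a guidance script.

    Fixations follow the scripted offsets; each segment is fixated for
    the interval from cursor move to tone (>= the planned fixation
    duration), recognition is evaluated on the segment length, and
    pronunciation starts no earlier than tone + reaction window.  A
    misrecognized segment is retried once, then the script advances.
    Regressions occur only through compliance lapses (default off).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cfg = script.config
    duration = float(max(cfg.tone_delay_ms, script.planned_fixation_ms))
    responses: dict[int, list[str]] = {i: [] for i in range(len(text.words))}
    fixations: list[FixationRecord] = []
    saccades: list[int] = []
    speech_onsets: list[float] = []
    t = 0.0
    prev_fix: int | None = None
    for seg in script.segments:
        letters = text.words[seg.word_index][seg.start_letter : seg.end_letter + 1]
        attempts = 0
        while True:
            attempts += 1
            if (
                prev_fix is not None
                and params.compliance_lapse_p
                and rng.random() < params.compliance_lapse_p
            ):
                # lapse: regress toward already-read text, then return
                back = max(0, prev_fix - script.span)
                fixations.append(FixationRecord(t, 120.0, back))
                saccades.append(back - prev_fix)
                prev_fix = back
                t += 120.0
            fix = seg.fixation_offset
            fixations.append(FixationRecord(t, duration, fix))
            if prev_fix is not None:
                saccades.append(fix - prev_fix)
            prev_fix = fix
            p = recognition_probability(seg.length, duration, params)
            ok = rng.random() < p
            onset = t + cfg.tone_delay_ms + cfg.reaction_ms + max(
                0.0, rng.normal(params.reaction_mean_ms, params.reaction_sd_ms)
            )
            t += duration + cfg.reaction_ms + cfg.pronounce_ms + cfg.saccade_ms
            if ok or attempts >= 2:
                speech_onsets.append(onset)
                responses[seg.word_index].append(
                    letters if ok else corrupt_word(letters, params, rng)
                )
                break
    outcomes = tuple(
        classify_response(word, "".join(responses[w_idx]))
        for w_idx, word in enumerate(text.words)
    )
    return SessionLog(
        outcomes=outcomes,
        fixations=tuple(fixations),
        saccades=tuple(saccades),
        speech_onsets_ms=tuple(speech_onsets),
        total_time_s=t / 1000.0,
        mode="guided",
    )
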