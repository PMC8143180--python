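"""Adaptive staircase estimating recognition span and required fixation time.

The procedure presents lists of 20 same-length pseudowords, starting at
4 letters / 250 ms.  A list is passed when at least 19 of 20 items
(95%) are read correctly.  On failure the presentation time is raised in
50 ms steps up to 500 ms; if the longest time still fails, word length
is reduced by one and the time sweep restarts at 250 ms.  A pass at the
shortest time before any demotion promotes to the next word length;
any other pass terminates and defines the reader's profile: the longest
word length readable at criterion and the shortest sufficient
presentation (fixation) time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import fmean
from typing import TYPE_CHECKING

import numpy as np

from .stimuli import generate_list

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import SimReaderParams

__all__ = [
    "TrialCondition",
    "TrialResult",
    "StaircaseState",
    "ReaderProfile",
    "AssessmentConfig",
    "initial_state",
    "update_state",
    "run_assessment",
    "estimate_speech_onset",
]

TIME_GRID = (250, 300, 350, 400, 450, 500)


@dataclass(frozen=True)
class TrialCondition:
    """One list's difficulty: word length (letters) and presentation time."""

    length: int
    presentation_ms: int

    def __post_init__(self) -> None:
        if not 2 <= self.length <= 6:
            raise ValueError(f"length {self.length} outside [2, 6]")
        if self.presentation_ms not in TIME_GRID:
            raise ValueError(
                f"presentation time {self.presentation_ms} not on grid {TIME_GRID}"
            )


@dataclass(frozen=True)
class TrialResult:
    target: str
    response: str
    correct: bool
    speech_onset_ms: float

    def __post_init__(self) -> None:
        if self.speech_onset_ms < 0:
            raise ValueError("speech onset must be nonnegative")


@dataclass(frozen=True)
class AssessmentConfig:
    list_size: int = 20
    pass_threshold: int = 19
    time_step_ms: int = 50
    time_min_ms: int = 250
    time_max_ms: int = 500
    length_min: int = 2
    length_max: int = 6
    tone_ms: int = 700          # early-pronunciation guard tone
    max_lists: int = 30         # session budget (~45 min)
    inter_trial_s: tuple[float, float] = (5.0, 10.0)  # metadata only

    def __post_init__(self) -> None:
        if self.pass_threshold > self.list_size:
            raise ValueError("pass_threshold cannot exceed list_size")


@dataclass(frozen=True)
class StaircaseState:
    condition: TrialCondition
    demoted_once: bool = False
    lists_used: int = 0
    history: tuple[tuple[TrialCondition, int], ...] = ()
    terminated: bool = False
    at_floor: bool = False

    @property
    def terminal_condition(self) -> TrialCondition:
        if not self.terminated:
            raise ValueError("staircase has not terminated")
        return self.condition


@dataclass(frozen=True)
class ReaderProfile:
    """Assessment outcome: the span/fixation-time pair a reader needs."""

    span: int
    fixation_time_ms: int
    speech_onset_mean_ms: float = float("nan")
    at_floor: bool = False
    at_ceiling: bool = False
    budget_exhausted: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.span <= 6:
            raise ValueError("span must be in [2, 6]")
        if self.fixation_time_ms not in TIME_GRID:
            raise ValueError("fixation time must lie on the 250-500 ms grid")


def initial_state(config: AssessmentConfig | None = None) -> StaircaseState:
    """Fixed start: 4-letter pseudowords shown for 250 ms."""
    _ = config or AssessmentConfig()
    return StaircaseState(condition=TrialCondition(4, 250))


def update_state(
    state: StaircaseState, n_correct: int, config: AssessmentConfig | None = None
) -> StaircaseState:
    """Advance the staircase after one list.

    Pass (>= 19/20): at the minimum time before any demotion and below
    the maximum length -> promote one letter (time stays minimal);
    otherwise terminate at the current condition.  Fail: raise time one
    step if possible, else demote one letter and restart the time sweep;
    failing at the floor (2 letters, 500 ms) terminates at the floor.
    """
    cfg = config or AssessmentConfig()
    if state.terminated:
        raise RuntimeError("cannot update a terminated staircase")
    if not 0 <= n_correct <= cfg.list_size:
        raise ValueError(f"n_correct {n_correct} outside [0, {cfg.list_size}]")
    cond = state.condition
    passed = n_correct >= cfg.pass_threshold
    hist = state.history + ((cond, n_correct),)
    base = replace(state, history=hist, lists_used=state.lists_used + 1)
    if passed:
        promotable = (
            cond.presentation_ms == cfg.time_min_ms
            and not state.demoted_once
            and cond.length < cfg.length_max
        )
        if promotable:
            return replace(
                base, condition=TrialCondition(cond.length + 1, cfg.time_min_ms)
            )
        return replace(base, terminated=True)
    if cond.presentation_ms < cfg.time_max_ms:
        return replace(
            base,
            condition=TrialCondition(cond.length, cond.presentation_ms + cfg.time_step_ms),
        )
    if cond.length > cfg.length_min:
        return replace(
            base,
            condition=TrialCondition(cond.length - 1, cfg.time_min_ms),
            demoted_once=True,
        )
    return replace(
        base,
        condition=TrialCondition(cfg.length_min, cfg.time_max_ms),
        terminated=True,
        at_floor=True,
    )


def profile_from_state(
    state: StaircaseState,
    speech_onset_mean_ms: float = float("nan"),
    *,
    config: AssessmentConfig | None = None,
    budget_exhausted: bool = False,
    seed: int | None = None,
) -> ReaderProfile:
    cfg = config or AssessmentConfig()
    cond = state.condition
    return ReaderProfile(
        span=cond.length,
        fixation_time_ms=cond.presentation_ms,
        speech_onset_mean_ms=speech_onset_mean_ms,
        at_floor=state.at_floor,
        at_ceiling=(
            cond.length == cfg.length_max and cond.presentation_ms == cfg.time_min_ms
        ),
        budget_exhausted=budget_exhausted,
        seed=seed,
    )


def estimate_speech_onset(trials: list[TrialResult]) -> float:
    """Arithmetic mean speech-onset latency (ms) over trials."""
    if not trials:
        raise ValueError("no trials to average")
    return fmean(t.speech_onset_ms for t in trials)


def run_assessment(
    reader: "SimReaderParams",
    config: AssessmentConfig | None = None,
    seed: int | None = None,
) -> tuple[ReaderProfile, list[dict]]:
    """Run the full staircase against a synthetic reader.

    Returns the profile and a flat trial log (one dict per pseudoword
    trial).  The profile's speech-onset mean is taken over the trials of
    the terminal (criterion-defining) list.
    """
    from .simulator import simulate_pseudoword_trial  # local import: cycle

    cfg = config or AssessmentConfig()
    rng = np.random.default_rng(seed)
    state = initial_state(cfg)
    log: list[dict] = []
    last_list: list[TrialResult] = []
    best_pass: TrialCondition | None = None
    while not state.terminated and state.lists_used < cfg.max_lists:
        cond = state.condition
        stim = generate_list(
            cond.length, cfg.list_size, rng, seed=int(rng.integers(2**31))
        )
        results = [
            simulate_pseudoword_trial(cond, w.letters, reader, rng, tone_ms=cfg.tone_ms)
            for w in stim
        ]
        n_correct = sum(t.correct for t in results)
        for t in results:
            log.append(
                {
                    "list_index": state.lists_used,
                    "length": cond.length,
                    "presentation_ms": cond.presentation_ms,
                    "target": t.target,
                    "response": t.response,
                    "correct": t.correct,
                    "speech_onset_ms": t.speech_onset_ms,
                }
            )
        if n_correct >= cfg.pass_threshold:
            best_pass = cond
        last_list = results
        state = update_state(state, n_correct, cfg)
    exhausted = not state.terminated
    if exhausted and best_pass is not None:
        state = replace(state, condition=best_pass, terminated=True)
    elif exhausted:
        state = replace(
            state,
            condition=TrialCondition(cfg.length_min, cfg.time_max_ms),
            terminated=True,
            at_floor=True,
        )
    onset = estimate_speech_onset(last_list) if last_list else float("nan")
    profile = profile_from_state(
        state, onset, config=cfg, budget_exhausted=exhausted, seed=seed
    )
    return profile, log
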