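"""In-silico reproduction of the two-experiment study design.

Builds the 60-child cohort whose span x fixation-time cross-tabulation
matches the published table, assigns matched therapy/control groups,
plans the crossover (each therapy child reads one half of the texts
unaided and the other half computer-guided; controls read both halves
unaided), runs the simulated sessions, and summarizes errors, reading
times and effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assessment import (
    TIME_GRID,
    AssessmentConfig,
    ReaderProfile,
    run_assessment,
)
from .guidance import GuidanceConfig, TextMaterial, build_script
from .materials import default_texts
from .simulator import SimReaderParams, simulate_free_reading, simulate_guided_reading
from .stats import (
    EffectSize,
    GroupSummary,
    TestResult,
    cohens_d,
    d_contrast,
    percent_of_total,
    wilcoxon_signed_rank,
)

__all__ = [
    "TABLE1_CELLS",
    "TABLE1_SPEECH_ONSET",
    "COHORT_MEAN_AGE_MONTHS",
    "COHORT_SD_AGE_MONTHS",
    "CohortAssignment",
    "CrossoverPlan",
    "ExperimentResult",
    "table1_cohort",
    "miscalibrated",
    "ideal_profile",
    "match_groups",
    "crossover_assign",
    "run_experiment1_cohort",
    "run_experiment2",
]

#: (span, fixation time ms) -> (therapy count, control count) of the
#: published 60-child cross-tabulation.
TABLE1_CELLS: dict[tuple[int, int], tuple[int, int]] = {
    (3, 250): (3, 3), (3, 300): (2, 3), (3, 350): (1, 2),
    (3, 400): (1, 1), (3, 450): (1, 0), (3, 500): (1, 1),
    (4, 250): (2, 3), (4, 300): (1, 1), (4, 350): (3, 2),
    (4, 400): (1, 1), (4, 450): (0, 1), (4, 500): (2, 1),
    (5, 250): (3, 4), (5, 300): (3, 2), (5, 350): (1, 1),
    (5, 400): (1, 0), (5, 500): (1, 2),
    (6, 250): (2, 1), (6, 400): (1, 1),
}

#: Bottom-row speech-onset latency summaries per span column:
#: span -> (mean ms, SD ms, n subjects).
TABLE1_SPEECH_ONSET: dict[int, tuple[float, float, int]] = {
    3: (1456.45, 473.08, 19),
    4: (1404.84, 705.60, 18),
    5: (1466.39, 562.96, 18),
    6: (1393.86, 484.52, 5),
}

COHORT_MEAN_AGE_MONTHS = 122.4
COHORT_SD_AGE_MONTHS = 19.3


@dataclass(frozen=True)
class CohortAssignment:
    therapy: tuple[int, ...]
    control: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.therapy) & set(self.control):
            raise ValueError("therapy and control groups overlap")

    def group_of(self, reader_id: int) -> str:
        if reader_id in self.therapy:
            return "therapy"
        if reader_id in self.control:
            return "control"
        raise KeyError(reader_id)


@dataclass(frozen=True)
class CrossoverPlan:
    """Per-reader ordered (part index, aided?) conditions."""

    conditions: dict[int, tuple[tuple[int, bool], tuple[int, bool]]]


@dataclass(frozen=True)
class ExperimentResult:
    sessions: pd.DataFrame
    therapy_effect: EffectSize
    control_effect: EffectSize
    contrast: float
    therapy_test: TestResult
    control_test: TestResult
    summaries: dict[str, GroupSummary]
    percentages: dict[str, float]


def table1_cohort(seed: int | None = None, **overrides) -> list[SimReaderParams]:
    """Synthesize the 60-reader cohort matching the published table.

    Each cell (span, fixation time) yields its published number of
    threshold readers with that true span and threshold time; memory
    retrieval times are drawn so each span column's speech-onset
    latencies match the published column means within sampling error.
    Extra keyword arguments override simulator parameters cohort-wide.
    """
    rng = np.random.default_rng(seed)
    cohort: list[SimReaderParams] = []
    for (span, time_ms), (tg, cg) in sorted(TABLE1_CELLS.items()):
        mean_ms, sd_ms, _ = TABLE1_SPEECH_ONSET[span]
        for _ in range(tg + cg):
            retrieval = float(
                np.clip(rng.normal(mean_ms - 150.0, sd_ms), 400.0, 4000.0)
            )
            age = float(
                np.clip(
                    rng.normal(COHORT_MEAN_AGE_MONTHS, COHORT_SD_AGE_MONTHS), 96, 180
                )
            )
            cohort.append(
                SimReaderParams(
                    true_span=span,
                    threshold_time_ms=float(time_ms),
                    retrieval_mean_ms=retrieval,
                    age_months=age,
                    seed=int(rng.integers(2**31)),
                    **overrides,
                )
            )
    return cohort


def miscalibrated(params: SimReaderParams, extra_span: int = 2) -> SimReaderParams:
    """A reader attempting more letters than they can recognize, with
    premature fixations and regressions -- the untreated reading style."""
    return replace(
        params,
        attempted_span=min(8, params.true_span + extra_span),
        premature_speech_p=0.3,
        regression_rate=0.15,
        guess_p=0.9,  # real words, unlike pseudowords, are guessable
        free_duration_scale=0.85,
    )


def ideal_profile(params: SimReaderParams) -> ReaderProfile:
    """The profile a noise-free assessment of this reader would yield."""
    span = int(np.clip(params.true_span, 2, 6))
    grid = np.asarray(TIME_GRID)
    above = grid[grid >= params.threshold_time_ms]
    time_ms = int(above[0]) if above.size else int(grid[-1])
    return ReaderProfile(span=span, fixation_time_ms=time_ms)


def _reader_key(r) -> tuple[int, int, float]:
    span = getattr(r, "span", None) or getattr(r, "true_span")
    time_ms = getattr(r, "fixation_time_ms", None) or getattr(r, "threshold_time_ms")
    age = getattr(r, "age_months", None) or 0.0
    return int(span), int(time_ms), float(age)


def match_groups(readers, seed: int | None = None) -> CohortAssignment:
    """Stratified matched assignment into therapy and control groups.

    Readers are stratified by span, then fixation time; within each
    stratum they are sorted by age and assigned alternately, starting
    each stratum with whichever group is currently smaller (seeded coin
    flip on ties).  Group sizes therefore differ by at most one per
    stratum and overall.
    """
    readers = list(readers)
    if len(readers) < 2:
        raise ValueError("need at least two readers to form groups")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[int, int], list[int]] = {}
    for idx, r in enumerate(readers):
        span, time_ms, _ = _reader_key(r)
        strata.setdefault((span, time_ms), []).append(idx)
    counts = {"therapy": 0, "control": 0}
    groups: dict[str, list[int]] = {"therapy": [], "control": []}
    for key in sorted(strata):
        members = sorted(strata[key], key=lambda i: _reader_key(readers[i])[2])
        if counts["therapy"] < counts["control"]:
            order = ["therapy", "control"]
        elif counts["control"] < counts["therapy"]:
            order = ["control", "therapy"]
        else:
            order = ["therapy", "control"] if rng.random() < 0.5 else ["control", "therapy"]
        for pos, idx in enumerate(members):
            g = order[pos % 2]
            groups[g].append(idx)
            counts[g] += 1
    return CohortAssignment(
        therapy=tuple(groups["therapy"]), control=tuple(groups["control"])
    )


def crossover_assign(
    assignment: CohortAssignment, seed: int | None = None
) -> CrossoverPlan:
    """Counterbalanced part order; therapy readers' second read is aided."""
    rng = np.random.default_rng(seed)
    conditions: dict[int, tuple[tuple[int, bool], tuple[int, bool]]] = {}
    for group, aided_second in (("therapy", True), ("control", False)):
        ids = list(getattr(assignment, group))
        rng.shuffle(ids)
        half = len(ids) // 2 + (len(ids) % 2 and rng.random() < 0.5)
        for pos, rid in enumerate(ids):
            first_part = 0 if pos < half else 1
            conditions[rid] = (
                (first_part, False),
                (1 - first_part, aided_second),
            )
    return CrossoverPlan(conditions=conditions)


def run_experiment1_cohort(
    cohort: list[SimReaderParams],
    seed: int | None = None,
    config: AssessmentConfig | None = None,
) -> tuple[list[ReaderProfile], pd.DataFrame]:
    """Assess every reader; cross-tabulate recovered span x fixation time."""
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    profiles = [
        run_assessment(params, config, seed=int(rng.integers(2**31)))[0]
        for params in cohort
    ]
    table = pd.crosstab(
        pd.Series([p.fixation_time_ms for p in profiles], name="fixation_ms"),
        pd.Series([p.span for p in profiles], name="span"),
    )
    return profiles, table


def _session(reader, profile, text_part, aided, rng, guidance_config):
    if aided:
        script = build_script(text_part, profile, guidance_config)
        return simulate_guided_reading(script, text_part, reader, rng)
    return simulate_free_reading(text_part, reader, rng)


def run_experiment2(
    cohort: list[SimReaderParams],
    texts: list[TextMaterial] | None = None,
    seed: int | None = None,
    profiles: list[ReaderProfile] | None = None,
    guidance_config: GuidanceConfig | None = None,
) -> ExperimentResult:
    """Simulate the full crossover protocol and summarize it.

    Therapy readers read one half of each of the four texts unaided and
    the other half computer-guided (scripted from their profile);
    controls read both halves unaided.  Effect sizes are computed on
    misread-word counts: the therapy contrast is unaided minus aided,
    the control contrast first minus second read, each divided by the
    pooled SD, so an error decrease gives a positive d.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    texts = texts if texts is not None else default_texts(int(rng.integers(2**31)))
    if profiles is None:
        profiles = [ideal_profile(p) for p in cohort]
    if len(profiles) != len(cohort):
        raise ValueError("profiles and cohort lengths differ")
    assignment = match_groups(cohort, seed=int(rng.integers(2**31)))
    plan = crossover_assign(assignment, seed=int(rng.integers(2**31)))
    rows = []
    for rid, conds in plan.conditions.items():
        reader, profile = cohort[rid], profiles[rid]
        group = assignment.group_of(rid)
        for phase, (part_idx, aided) in enumerate(conds, start=1):
            errors = words = 0
            time_s = 0.0
            for text in texts:
                part = text.part(part_idx)
                log = _session(reader, profile, part, aided, rng, guidance_config)
                errors += log.n_errors
                words += log.n_words
                time_s += log.total_time_s
            rows.append(
                {
                    "reader_id": rid,
                    "group": group,
                    "phase": phase,
                    "part": part_idx,
                    "aided": aided,
                    "errors": errors,
                    "words": words,
                    "time_s": time_s,
                }
            )
    sessions = pd.DataFrame(rows).sort_values(["reader_id", "phase"]).reset_index(drop=True)

    def _cond(group: str, **mask) -> pd.DataFrame:
        df = sessions[sessions.group == group]
        for k, v in mask.items():
            df = df[df[k] == v]
        return df.sort_values("reader_id")

    th_un = _cond("therapy", aided=False)
    th_ai = _cond("therapy", aided=True)
    co_1 = _cond("control", phase=1)
    co_2 = _cond("control", phase=2)
    summaries = {
        "therapy_unaided": GroupSummary.from_sample(th_un.errors),
        "therapy_aided": GroupSummary.from_sample(th_ai.errors),
        "control_first": GroupSummary.from_sample(co_1.errors),
        "control_second": GroupSummary.from_sample(co_2.errors),
    }
    therapy_effect = cohens_d(summaries["therapy_unaided"], summaries["therapy_aided"])
    control_effect = cohens_d(summaries["control_first"], summaries["control_second"])
    word_counts = [len(t.words) for t in texts]
    percentages = {
        name: percent_of_total(s.mean, word_counts) for name, s in summaries.items()
    }
    return ExperimentResult(
        sessions=sessions,
        therapy_effect=therapy_effect,
        control_effect=control_effect,
        contrast=d_contrast(therapy_effect.d, control_effect.d),
        therapy_test=wilcoxon_signed_rank(th_un.errors.to_numpy(), th_ai.errors.to_numpy()),
        control_test=wilcoxon_signed_rank(co_1.errors.to_numpy(), co_2.errors.to_numpy()),
        summaries=summaries,
        percentages=percentages,
    )
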