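"""Plain-text serialization for profiles, scripts, logs and configs.

Structured documents use YAML (human-readable, diff-friendly); tabular
logs use CSV with headers.  Every stochastic artifact records the seed
it was produced with.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .assessment import ReaderProfile
from .guidance import GuidanceConfig, GuidanceEvent, GuidanceScript, Segment
from .simulator import SessionLog, SimReaderParams

__all__ = [
    "write_profile",
    "read_profile",
    "write_reader_params",
    "read_reader_params",
    "write_script",
    "read_script",
    "write_trial_log",
    "read_trial_log",
    "write_session_log",
]


def _dump(doc: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def _load(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping document")
    return doc


def write_profile(profile: ReaderProfile, path: str | Path) -> None:
    _dump(asdict(profile), path)


def read_profile(path: str | Path) -> ReaderProfile:
    return ReaderProfile(**_load(path))


def write_reader_params(params: SimReaderParams, path: str | Path) -> None:
    _dump(asdict(params), path)


def read_reader_params(path: str | Path) -> SimReaderParams:
    return SimReaderParams(**_load(path))


def write_script(script: GuidanceScript, path: str | Path) -> None:
    doc = {
        "span": script.span,
        "planned_fixation_ms": script.planned_fixation_ms,
        "config": asdict(script.config),
        "segments": [
            {
                "word_index": s.word_index,
                "start": s.start_letter,
                "end": s.end_letter,
                "absolute_start": s.absolute_start,
                "fixation_offset": s.fixation_offset,
            }
            for s in script.segments
        ],
        "events": [
            {"t_ms": e.t_ms, "kind": e.kind, "segment_index": e.segment_index}
            for e in script.events
        ],
        "display_start_per_segment": list(script.display_start_per_segment),
    }
    _dump(doc, path)


def read_script(path: str | Path) -> GuidanceScript:
    doc = _load(path)
    segments = tuple(
        Segment(
            word_index=s["word_index"],
            start_letter=s["start"],
            end_letter=s["end"],
            absolute_start=s["absolute_start"],
        )
        for s in doc["segments"]
    )
    events = tuple(
        GuidanceEvent(t_ms=e["t_ms"], kind=e["kind"], segment_index=e["segment_index"])
        for e in doc["events"]
    )
    return GuidanceScript(
        segments=segments,
        events=events,
        display_start_per_segment=tuple(doc["display_start_per_segment"]),
        planned_fixation_ms=doc["planned_fixation_ms"],
        span=doc["span"],
        config=GuidanceConfig(**doc["config"]),
    )


def write_trial_log(log: list[dict], path: str | Path) -> None:
    pd.DataFrame(log).to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_session_log(log: SessionLog, stem: str | Path) -> tuple[Path, Path]:
    """Write a session as two CSVs: word outcomes and fixations."""
    stem = Path(stem)
    words = pd.DataFrame(
        {
            "target": [o.target for o in log.outcomes],
            "response": [o.response for o in log.outcomes],
            "correct": [o.correct for o in log.outcomes],
            "error_kinds": ["|".join(sorted(k.value for k in o.error_kinds)) for o in log.outcomes],
        }
    )
    fix = pd.DataFrame(
        {
            "t_start_ms": [f.t_start_ms for f in log.fixations],
            "duration_ms": [f.duration_ms for f in log.fixations],
            "offset": [f.offset for f in log.fixations],
        }
    )
    w_path = stem.with_suffix(".words.csv")
    f_path = stem.with_suffix(".fixations.csv")
    words.to_csv(w_path, index=False)
    fix.to_csv(f_path, index=False)
    return w_path, f_path
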