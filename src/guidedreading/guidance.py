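"""Timed gaze-guidance scripts for text reading.

Given a reader profile (recognition span in letters, required fixation
time), a text is split into word segments no longer than the span.  For
each segment the script schedules: a cursor move marking the segment
and its fixation point (the middle letter, left-of-middle for even
lengths), a tone 1 s later releasing pronunciation, and a speech window
opening 250 ms after the tone (a minimal reaction time).  Text left of
the current segment is hidden so regressions are impossible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TextMaterial",
    "Segment",
    "GuidanceEvent",
    "GuidanceScript",
    "GuidanceConfig",
    "segment_word",
    "fixation_offset",
    "build_script",
    "saccade_plan",
]


@dataclass(frozen=True)
class TextMaterial:
    """A text as an ordered word sequence with a two-part split."""

    words: tuple[str, ...]
    part_boundary: int

    def __post_init__(self) -> None:
        if not 0 <= self.part_boundary <= len(self.words):
            raise ValueError("part boundary outside the text")

    @classmethod
    def from_text(cls, text: str, part_boundary: int | None = None) -> "TextMaterial":
        """Tokenize on whitespace; punctuation stays attached to its word."""
        words = tuple(text.split())
        if not words:
            raise ValueError("empty text")
        return cls(words=words, part_boundary=part_boundary if part_boundary is not None else len(words))

    @classmethod
    def from_file(cls, path: str | Path, part_boundary: int | None = None) -> "TextMaterial":
        return cls.from_text(Path(path).read_text(encoding="utf-8"), part_boundary)

    @property
    def parts(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return self.words[: self.part_boundary], self.words[self.part_boundary :]

    def part(self, index: int) -> "TextMaterial":
        words = self.parts[index]
        if not words:
            raise ValueError(f"part {index} is empty")
        return TextMaterial(words=words, part_boundary=len(words))

    @property
    def word_counts(self) -> tuple[int, int]:
        return tuple(len(p) for p in self.parts)  # type: ignore[return-value]

    @property
    def letter_counts(self) -> tuple[int, int]:
        return tuple(sum(len(w) for w in p) for p in self.parts)  # type: ignore[return-value]


@dataclass(frozen=True)
class Segment:
    word_index: int
    start_letter: int       # inclusive, 0-based within the word
    end_letter: int         # inclusive
    absolute_start: int     # character offset in the rendered line

    def __post_init__(self) -> None:
        if self.end_letter < self.start_letter:
            raise ValueError("segment end before start")

    @property
    def length(self) -> int:
        return self.end_letter - self.start_letter + 1

    @property
    def fixation_offset(self) -> int:
        return fixation_offset(self)


@dataclass(frozen=True)
class GuidanceEvent:
    t_ms: float
    kind: str  # cursor_move | tone | speech_window_open | segment_advance
    segment_index: int


@dataclass(frozen=True)
class GuidanceConfig:
    tone_delay_ms: int = 1000     # cursor move -> tone
    reaction_ms: int = 250        # tone -> speech window
    pronounce_ms: int = 500       # speech window -> segment advance
    saccade_ms: int = 50          # advance -> next cursor move
    min_fixation_ms: int = 250


@dataclass(frozen=True)
class GuidanceScript:
    segments: tuple[Segment, ...]
    events: tuple[GuidanceEvent, ...]
    display_start_per_segment: tuple[int, ...]
    planned_fixation_ms: int
    span: int
    config: GuidanceConfig = field(default_factory=GuidanceConfig)


def segment_word(word: str, span: int, word_index: int = 0, absolute_word_start: int = 0) -> tuple[Segment, ...]:
    """Greedy left-to-right split into span-sized pieces, remainder last."""
    if span < 1:
        raise ValueError("span must be >= 1")
    if not word:
        raise ValueError("cannot segment an empty word")
    out = []
    for start in range(0, len(word), span):
        end = min(start + span, len(word)) - 1
        out.append(
            Segment(
                word_index=word_index,
                start_letter=start,
                end_letter=end,
                absolute_start=absolute_word_start + start,
            )
        )
    return tuple(out)


def fixation_offset(segment: Segment) -> int:
    """Absolute index of the fixated letter: the middle one, or the
    letter left of middle for even segment lengths."""
    k = segment.length
    return segment.absolute_start + math.ceil(k / 2) - 1


def build_script(
    text: TextMaterial,
    profile,
    config: GuidanceConfig | None = None,
) -> GuidanceScript:
    """Compile a text plus a reader profile into a timed guidance script.

    ``profile`` needs ``span`` and ``fixation_time_ms`` attributes.  The
    planned fixation duration is max(profile fixation time, 250 ms); the
    tone always fires 1 s after the cursor move, so the planned duration
    is honored for every profile on the 250-500 ms grid.
    """
    cfg = config or GuidanceConfig()
    if not text.words:
        raise ValueError("empty text")
    span = int(profile.span)
    planned = max(int(profile.fixation_time_ms), cfg.min_fixation_ms)
    segments: list[Segment] = []
    word_start = 0
    for w_idx, word in enumerate(text.words):
        segments.extend(segment_word(word, span, w_idx, word_start))
        word_start += len(word) + 1  # single inter-word space
    events: list[GuidanceEvent] = []
    t = 0.0
    for s_idx in range(len(segments)):
        events.append(GuidanceEvent(t, "cursor_move", s_idx))
        events.append(GuidanceEvent(t + cfg.tone_delay_ms, "tone", s_idx))
        events.append(
            GuidanceEvent(t + cfg.tone_delay_ms + cfg.reaction_ms, "speech_window_open", s_idx)
        )
        adv = t + cfg.tone_delay_ms + cfg.reaction_ms + cfg.pronounce_ms
        events.append(GuidanceEvent(adv, "segment_advance", s_idx))
        t = adv + cfg.saccade_ms
    return GuidanceScript(
        segments=tuple(segments),
        events=tuple(events),
        display_start_per_segment=tuple(s.absolute_start for s in segments),
        planned_fixation_ms=planned,
        span=span,
        config=cfg,
    )


def saccade_plan(script: GuidanceScript) -> tuple[int, ...]:
    """Signed character amplitudes between consecutive fixation offsets."""
    if len(script.segments) < 2:
        raise ValueError("need at least two segments for a saccade plan")
    offs = [s.fixation_offset for s in script.segments]
    return tuple(b - a for a, b in zip(offs, offs[1:]))
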