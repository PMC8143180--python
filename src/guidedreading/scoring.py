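"""Letter-level scoring of spoken responses against target words.

A word counts as misread when at least one letter was omitted, replaced
by a letter not present at that position, shifted to a wrong position
(transposition), or incorrectly added.  Errors are attributed to target
letter positions through a minimal edit alignment so that per-position
misreading rates can be tabulated by word length.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ErrorKind",
    "EditOp",
    "LetterAlignment",
    "WordOutcome",
    "PositionErrorProfile",
    "align_letters",
    "classify_response",
    "position_error_flags",
    "position_error_profile",
]


class ErrorKind(str, Enum):
    OMISSION = "omission"
    SUBSTITUTION = "substitution"
    TRANSPOSITION = "transposition"
    ADDITION = "addition"


@dataclass(frozen=True)
class EditOp:
    """One step of an alignment.

    ``kind`` is 'match', 'substitute', 'delete' (target letter dropped)
    or 'insert' (extra response letter).  ``i``/``j`` are the 0-based
    target/response indices consumed; -1 when the side is not consumed.
    """

    kind: str
    i: int
    j: int


@dataclass(frozen=True)
class LetterAlignment:
    ops: tuple[EditOp, ...]
    cost: int

    def apply(self, target: str, response: str) -> str:
        """Rebuild the response from the target via the ops (invariant check)."""
        out = []
        for op in self.ops:
            if op.kind == "match":
                out.append(target[op.i])
            elif op.kind in ("substitute", "insert"):
                out.append(response[op.j])
        return "".join(out)


@dataclass(frozen=True)
class WordOutcome:
    target: str
    response: str
    correct: bool
    error_kinds: frozenset[ErrorKind]

    def __post_init__(self) -> None:
        if self.correct and self.error_kinds:
            raise ValueError("a correct outcome cannot carry error kinds")


@dataclass(frozen=True)
class PositionErrorProfile:
    length: int
    rate_by_position: tuple[float, ...]
    n_words: int


def _normalize(s: str) -> str:
    return s.strip().lower()


def align_letters(target: str, response: str) -> LetterAlignment:
    """Minimal-cost edit alignment (unit costs) from target to response.

    Ties are broken by preferring match > substitute > delete > insert,
    resolved leftmost-first via forward dynamic programming and a
    priority-ordered traceback.
    """
    t, r = target, response
    n, m = len(t), len(r)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1, j - 1] + (t[i - 1] != r[j - 1])
            dp[i, j] = min(sub, dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    ops: list[EditOp] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] and t[i - 1] == r[j - 1]:
            ops.append(EditOp("match", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + 1:
            ops.append(EditOp("substitute", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            ops.append(EditOp("delete", i - 1, -1))
            i -= 1
        else:
            ops.append(EditOp("insert", -1, j - 1))
            j -= 1
    ops.reverse()
    return LetterAlignment(ops=tuple(ops), cost=int(dp[n, m]))


def _transposed_pairs(
    target: str, response: str, ops: Sequence[EditOp]
) -> set[int]:
    """Target indices whose substitution is part of a letter swap.

    Two substitutions (i1,j1), (i2,j2) no more than two target positions
    apart form a transposition when each target letter reappears at the
    other's response position.
    """
    subs = [op for op in ops if op.kind == "substitute"]
    hit: set[int] = set()
    for a in range(len(subs)):
        for b in range(a + 1, len(subs)):
            o1, o2 = subs[a], subs[b]
            if abs(o1.i - o2.i) > 2:
                continue
            if target[o1.i] == response[o2.j] and target[o2.i] == response[o1.j]:
                hit.add(o1.i)
                hit.add(o2.i)
    return hit


def classify_response(target: str, response: str) -> WordOutcome:
    """Score one response; comparison is case-insensitive after trimming."""
    if not target:
        raise ValueError("target must be nonempty")
    t, r = _normalize(target), _normalize(response)
    if t == r:
        return WordOutcome(t, r, True, frozenset())
    aln = align_letters(t, r)
    swapped = _transposed_pairs(t, r, aln.ops)
    kinds: set[ErrorKind] = set()
    for op in aln.ops:
        if op.kind == "delete":
            kinds.add(ErrorKind.OMISSION)
        elif op.kind == "insert":
            kinds.add(ErrorKind.ADDITION)
        elif op.kind == "substitute":
            kinds.add(
                ErrorKind.TRANSPOSITION if op.i in swapped else ErrorKind.SUBSTITUTION
            )
    return WordOutcome(t, r, False, frozenset(kinds))


def position_error_flags(target: str, response: str) -> tuple[bool, ...]:
    """Per-target-position misreading flags.

    A position is flagged when the minimal alignment deletes or
    substitutes it (including transposition participation).  Insertions
    are charged to the nearest following target position so the flag
    vector keeps the target's length; insertions past the last letter
    charge the last position.
    """
    t, r = _normalize(target), _normalize(response)
    n = len(t)
    flags = [False] * n
    if t == r or n == 0:
        return tuple(flags)
    aln = align_letters(t, r)
    # target index that each op precedes, for insertion attribution
    for idx, op in enumerate(aln.ops):
        if op.kind in ("delete", "substitute"):
            flags[op.i] = True
        elif op.kind == "insert":
            nxt = next(
                (o.i for o in aln.ops[idx + 1 :] if o.kind in ("match", "substitute", "delete")),
                None,
            )
            flags[nxt if nxt is not None else n - 1] = True
    return tuple(flags)


def position_error_profile(
    outcomes: Iterable[WordOutcome],
) -> PositionErrorProfile:
    """Per-position misread fraction over same-length word outcomes."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to profile")
    lengths = {len(o.target) for o in outcomes}
    if len(lengths) != 1:
        raise ValueError(f"outcomes mix several target lengths: {sorted(lengths)}")
    (length,) = lengths
    counts = np.zeros(length)
    for o in outcomes:
        if not o.correct:
            counts += np.asarray(position_error_flags(o.target, o.response), dtype=float)
    rates = counts / len(outcomes)
    return PositionErrorProfile(
        length=length,
        rate_by_position=tuple(float(x) for x in rates),
        n_words=len(outcomes),
    )
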