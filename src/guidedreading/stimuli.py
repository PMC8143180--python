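"""Pseudoword stimulus generation.

Pseudowords are pronounceable non-words used in span assessment: because
they carry no lexical meaning, every letter must actually be recognized,
so misreadings expose the reader's simultaneous-recognition limit rather
than guessing skill.  All items in a list share one consonant/vowel
template (e.g. every 4-letter item is CVCV), and adjacent letter pairs
are restricted to a permitted-bigram table as a reproducible proxy for
phonotactic plausibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VOWELS",
    "CONSONANTS",
    "PERMITTED_BIGRAMS",
    "Pseudoword",
    "StimulusList",
    "canonical_pattern",
    "generate_pseudoword",
    "generate_list",
    "write_list",
    "read_list",
]

#: Default alphabet: German lowercase without umlauts or rare/ambiguous
#: letters (c, q, v, x, y do not start common German grapheme-phoneme
#: correspondences on their own).
VOWELS = "aeiou"
CONSONANTS = "bdfghklmnprstwz"

#: Consonant clusters that occur word-internally in colloquial German.
_CC_CLUSTERS = (
    "st nd nt ch ck rt rn rl rm rb rg rs lt ld lm ls mp mm nn ll ss tt tz pf"
).split()


def _default_bigrams() -> frozenset[str]:
    pairs = set()
    for c in CONSONANTS:
        for v in VOWELS:
            pairs.add(c + v)
            pairs.add(v + c)
    pairs.update(cc for cc in _CC_CLUSTERS if len(cc) == 2)
    return frozenset(pairs)


#: Permitted adjacent letter pairs.  Every generated word's bigrams are
#: members of this table; it is configurable per call.
PERMITTED_BIGRAMS: frozenset[str] = _default_bigrams()

_PATTERNS = {2: "CV", 3: "CVC", 4: "CVCV", 5: "CVCVC", 6: "CVCCVC"}


@dataclass(frozen=True)
class Pseudoword:
    """A single pronounceable non-word and its consonant/vowel template."""

    letters: str
    cv_pattern: str

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.cv_pattern):
            raise ValueError("letters and cv_pattern must have equal length")
        for ch, cls in zip(self.letters, self.cv_pattern):
            if cls == "V" and ch not in VOWELS:
                raise ValueError(f"{self.letters!r}: {ch!r} is not a vowel")
            if cls == "C" and ch in VOWELS:
                raise ValueError(f"{self.letters!r}: {ch!r} is not a consonant")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters


@dataclass(frozen=True)
class StimulusList:
    """An ordered list of unique same-template pseudowords."""

    length: int
    items: tuple[Pseudoword, ...]
    seed: int

    def __post_init__(self) -> None:
        words = [w.letters for w in self.items]
        if len(set(words)) != len(words):
            raise ValueError("stimulus list items must be unique")
        if any(len(w) != self.length for w in self.items):
            raise ValueError("all items must have the configured length")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


def canonical_pattern(length: int) -> str:
    """Fixed consonant/vowel template for a word length.

    Lengths 2-6 use the shipped templates (CV, CVC, CVCV, CVCVC, CVCCVC);
    text materials may need longer words, for which a strict CV
    alternation is extended (7 -> CVCVCVC, ...).
    """
    if not isinstance(length, (int, np.integer)) or isinstance(length, bool):
        raise TypeError("length must be an integer")
    if length in _PATTERNS:
        return _PATTERNS[length]
    if 2 <= length <= 6:  # pragma: no cover - table covers 2..6
        raise ValueError(f"no template for length {length}")
    raise ValueError(f"pseudoword length must be in [2, 6], got {length}")


def _extended_pattern(length: int) -> str:
    """Template for arbitrary lengths >= 1 (used for text materials)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if length in _PATTERNS:
        return _PATTERNS[length]
    return ("CV" * length)[:length]


def _letters_for(cls: str) -> str:
    return VOWELS if cls == "V" else CONSONANTS


def _generate_from_pattern(
    pattern: str, rng: np.random.Generator, bigrams: frozenset[str]
) -> str:
    """Sample letters left to right subject to the bigram table.

    Backtracks (by restart) if a prefix admits no permitted successor,
    which is rare with the default table.
    """
    if not bigrams:
        raise ValueError("permitted-bigram table is empty")
    for _ in range(200):
        word = ""
        ok = True
        for cls in pattern:
            pool = _letters_for(cls)
            if word:
                pool = [ch for ch in pool if word[-1] + ch in bigrams]
                if not pool:
                    ok = False
                    break
            word += pool[rng.integers(len(pool))]
        if ok:
            return word
    raise RuntimeError(f"could not realize pattern {pattern!r} under bigram table")


def generate_pseudoword(
    length: int,
    rng: np.random.Generator | int | None = None,
    *,
    bigrams: frozenset[str] = PERMITTED_BIGRAMS,
) -> Pseudoword:
    """Draw one pseudoword of the canonical template for ``length``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pattern = canonical_pattern(length)
    return Pseudoword(_generate_from_pattern(pattern, rng, bigrams), pattern)


def generate_list(
    length: int,
    n: int = 20,
    rng: np.random.Generator | int | None = None,
    *,
    seed: int | None = None,
    bigrams: frozenset[str] = PERMITTED_BIGRAMS,
) -> StimulusList:
    """Generate ``n`` unique pseudowords of one length (default list size 20)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        seed = rng if seed is None and rng is not None else (seed or 0)
        rng = np.random.default_rng(seed)
    seen: dict[str, Pseudoword] = {}
    attempts = 0
    while len(seen) < n:
        w = generate_pseudoword(length, rng, bigrams=bigrams)
        seen.setdefault(w.letters, w)
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                f"could not draw {n} unique length-{length} pseudowords"
            )
    return StimulusList(length=length, items=tuple(seen.values()), seed=seed or 0)


def write_list(stim: StimulusList, path: str | Path) -> None:
    """Serialize a list as plain text, one word per line, with a header."""
    path = Path(path)
    header = f"#length={stim.length} seed={stim.seed} pattern={stim.items[0].cv_pattern}"
    path.write_text("\n".join([header, *(w.letters for w in stim.items)]) + "\n")


def read_list(path: str | Path) -> StimulusList:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing stimulus-list header line")
    meta = dict(kv.split("=") for kv in lines[0].lstrip("#").split())
    length, seed = int(meta["length"]), int(meta["seed"])
    pattern = meta["pattern"]
    items = tuple(Pseudoword(w, pattern) for w in lines[1:] if w)
    return StimulusList(length=length, items=items, seed=seed)
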