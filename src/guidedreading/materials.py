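"""Synthetic reading texts matching the study materials' bookkeeping.

The crossover experiment used four texts, each split into two parts
with fixed word and letter counts (e.g. text 1: 29 words/142 letters
then 30 words/139 letters; 216 words over all eight parts).  Those
counts are the denominators of every error percentage, so the package
ships a generator that produces pronounceable synthetic texts with
exactly these counts.  The generated words are pseudo-German letter
strings, not real prose; they are labelled synthetic throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .guidance import TextMaterial
from .stimuli import PERMITTED_BIGRAMS, _extended_pattern, _generate_from_pattern

__all__ = ["TEXT_PART_COUNTS", "TOTAL_WORDS", "default_texts", "write_texts"]

#: (words, letters) for (part 1, part 2) of each of the four texts.
TEXT_PART_COUNTS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((29, 142), (30, 139)),
    ((33, 156), (34, 161)),
    ((26, 129), (25, 130)),
    ((20, 131), (19, 127)),
)

#: Total words over all four texts (both parts) -- the percentage denominator.
TOTAL_WORDS: int = sum(w for text in TEXT_PART_COUNTS for (w, _) in text)


def _word_lengths(n_words: int, n_letters: int, rng: np.random.Generator) -> list[int]:
    """Split a letter budget into word lengths, shuffled for variety."""
    base, extra = divmod(n_letters, n_words)
    if base < 2 or base + 1 > 8:
        raise ValueError("letter/word ratio outside realistic word lengths")
    lengths = [base + 1] * extra + [base] * (n_words - extra)
    rng.shuffle(lengths)
    return lengths


def _part_words(n_words: int, n_letters: int, rng: np.random.Generator) -> list[str]:
    return [
        _generate_from_pattern(_extended_pattern(k), rng, PERMITTED_BIGRAMS)
        for k in _word_lengths(n_words, n_letters, rng)
    ]


def default_texts(seed: int = 0) -> list[TextMaterial]:
    """Generate the four two-part texts with the canonical counts."""
    rng = np.random.default_rng(seed)
    texts = []
    for (w1, l1), (w2, l2) in TEXT_PART_COUNTS:
        part1 = _part_words(w1, l1, rng)
        part2 = _part_words(w2, l2, rng)
        texts.append(TextMaterial(words=tuple(part1 + part2), part_boundary=w1))
    return texts


def write_texts(texts: list[TextMaterial], out_dir: str | Path) -> list[Path]:
    """Write texts as UTF-8 files, one line per part."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, text in enumerate(texts, start=1):
        p1, p2 = text.parts
        path = out / f"text{i}.txt"
        path.write_text(" ".join(p1) + "\n" + " ".join(p2) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
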