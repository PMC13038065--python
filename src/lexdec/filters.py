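"""Real-word pool filtering and the typo-proximity test.

Candidate real words for a lexical-decision test must be genuine
dictionary words (not corpus misspellings), not proper nouns, not
transparent compounds of frequent words, and must fall in the target
rarity band.  Pseudoword candidates, conversely, must not sit within one
typo of a real dictionary word, or participants may read them as
misspelled real words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DictionaryResource",
    "CasingStats",
    "FilterReport",
    "filter_misspellings",
    "proper_noun_fraction",
    "filter_proper_nouns",
    "damerau_levenshtein",
    "is_typo_of_dictionary",
    "compound_filter",
    "select_rare_words",
]

logger = logging.getLogger(__name__)

REASON_MISSPELLING = "misspelling"
REASON_PROPER_NOUN = "proper_noun"
REASON_COMPOUND = "compound"
REASON_OUT_OF_BAND = "out_of_band"
_REASONS = (REASON_MISSPELLING, REASON_PROPER_NOUN, REASON_COMPOUND, REASON_OUT_OF_BAND)


@dataclass
class DictionaryResource:
    """A set of known-good word forms, casefolded on construction."""

    entries: frozenset[str]
    name: str = "dictionary"

    def __post_init__(self) -> None:
        self.entries = frozenset(w.casefold() for w in self.entries)
        if not self.entries:
            raise ValueError("dictionary resource must be non-empty")
        # Length buckets accelerate bounded-distance scans.
        buckets: dict[int, list[str]] = {}
        for w in self.entries:
            buckets.setdefault(len(w), []).append(w)
        self._by_length = buckets

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "DictionaryResource":
        """Load a dictionary: UTF-8 text, one entry per line."""
        words = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                w = line.strip()
                if w:
                    words.add(w.casefold())
        return cls(entries=frozenset(words), name=name or str(path))

    def __contains__(self, word: str) -> bool:
        return word.casefold() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def entries_with_length(self, lo: int, hi: int) -> Iterable[str]:
        for length in range(lo, hi + 1):
            yield from self._by_length.get(length, ())


@dataclass
class CasingStats:
    """Per-word counts of capitalized-initial vs. total occurrences.

    Collected from the corpus *before* casefolding; stands in for a
    part-of-speech tagger when deciding which words are proper nouns.
    """

    counts: dict[str, tuple[int, int]]  # word -> (n_capitalized, n_total)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "CasingStats":
        counts: dict[str, list[int]] = {}
        for tok in tokens:
            word = tok.casefold()
            cell = counts.setdefault(word, [0, 0])
            if tok[:1].isupper():
                cell[0] += 1
            cell[1] += 1
        return cls(counts={w: (c[0], c[1]) for w, c in counts.items()})

    def fraction(self, word: str) -> float:
        if word not in self.counts:
            raise KeyError(f"no casing statistics for {word!r}")
        n_cap, n_tot = self.counts[word]
        return n_cap / n_tot


@dataclass
class FilterReport:
    """Removed words with the single reason each was removed for."""

    removed: dict[str, str] = field(default_factory=dict)

    def add(self, word: str, reason: str) -> None:
        if reason not in _REASONS:
            raise ValueError(f"unknown reason {reason!r}")
        if word in self.removed:
            raise ValueError(f"{word!r} already removed ({self.removed[word]})")
        self.removed[word] = reason

    def merge(self, other: "FilterReport") -> None:
        for word, reason in other.removed.items():
            self.add(word, reason)

    def words_with_reason(self, reason: str) -> set[str]:
        return {w for w, r in self.removed.items() if r == reason}

    def write_tsv(self, destination: str | Path) -> None:
        with open(destination, "w", encoding="utf-8") as fh:
            for word in sorted(self.removed):
                fh.write(f"{word}\t{self.removed[word]}\n")


def filter_misspellings(
    words: Iterable[str], dictionary: DictionaryResource | None
) -> tuple[list[str], FilterReport]:
    """Keep only words attested in *dictionary*; identity if none supplied."""
    words = list(words)
    report = FilterReport()
    if dictionary is None:
        return words, report
    kept = []
    for w in words:
        if w in dictionary:
            kept.append(w)
        else:
            report.add(w, REASON_MISSPELLING)
    return kept, report


def proper_noun_fraction(word: str, stats: CasingStats) -> float:
    """Fraction of corpus occurrences of *word* with an uppercase initial."""
    return stats.fraction(word)


def filter_proper_nouns(
    words: Iterable[str],
    stats: CasingStats,
    threshold: float = 0.5,
    is_proper_noun: Callable[[str], bool] | None = None,
) -> tuple[list[str], FilterReport]:
    """Drop words capitalized in more than *threshold* of their occurrences.

    ``is_proper_noun`` is an optional external predicate (e.g. a
    part-of-speech tagger) that overrides the capitalization heuristic —
    needed for languages such as German where every noun is capitalized.
    """
    kept, report = [], FilterReport()
    for w in words:
        if is_proper_noun is not None:
            proper = is_proper_noun(w)
        else:
            proper = stats.fraction(w) > threshold
        if proper:
            report.add(w, REASON_PROPER_NOUN)
        else:
            kept.append(w)
    return kept, report


def damerau_levenshtein(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein distance between two strings.

    Insertions, deletions, substitutions, and transpositions of adjacent
    characters each cost 1.  The unrestricted variant (transposed
    characters may be edited further) is a true metric, unlike the
    optimal-string-alignment shortcut.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # Lowrance–Wagner dynamic programme with a per-character last-seen row.
    inf = la + lb
    da: dict[str, int] = {}
    # H has an extra border row/column at index 0 holding `inf`.
    H = [[inf] * (lb + 2) for _ in range(la + 2)]
    for i in range(la + 1):
        H[i + 1][1] = i
    for j in range(lb + 1):
        H[1][j + 1] = j
    for i in range(1, la + 1):
        db = 0
        ai = a[i - 1]
        Hi, Hi1 = H[i + 1], H[i]
        for j in range(1, lb + 1):
            bj = b[j - 1]
            i1 = da.get(bj, 0)
            j1 = db
            if ai == bj:
                cost = 0
                db = j
            else:
                cost = 1
            Hi[j + 1] = min(
                Hi1[j] + cost,            # substitution / match
                Hi[j] + 1,                # insertion
                Hi1[j + 1] + 1,           # deletion
                H[i1][j1] + (i - i1 - 1) + 1 + (j - j1 - 1),  # transposition
            )
        da[ai] = i
    return H[la + 1][lb + 1]


def _within_one_edit(a: str, b: str) -> bool:
    """True iff damerau_levenshtein(a, b) <= 1, in O(len) time."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        # one substitution, or one adjacent transposition
        diffs = [i for i in range(la) if a[i] != b[i]]
        if len(diffs) == 1:
            return True
        if len(diffs) == 2:
            i, j = diffs
            return j == i + 1 and a[i] == b[j] and a[j] == b[i]
        return False
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    # b is one longer: one deletion from b must yield a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def is_typo_of_dictionary(
    word: str,
    dictionary: DictionaryResource | None,
    max_distance: int = 1,
) -> bool:
    """Is *word* within *max_distance* edits of any dictionary entry?

    Equivalent to a brute-force Damerau–Levenshtein scan over all
    entries; entries whose length differs by more than *max_distance*
    are pruned (the distance is bounded below by the length difference),
    and the common ``max_distance=1`` case uses a closed-form
    neighbour test.
    """
    if dictionary is None:
        logger.warning("typo check skipped: no dictionary supplied")
        return False
    word = word.casefold()
    lo, hi = max(0, len(word) - max_distance), len(word) + max_distance
    if max_distance == 1:
        return any(
            _within_one_edit(word, entry)
            for entry in dictionary.entries_with_length(lo, hi)
        )
    return any(
        damerau_levenshtein(word, entry) <= max_distance
        for entry in dictionary.entries_with_length(lo, hi)
    )


def compound_filter(
    words: Iterable[str],
    table,
    enabled: bool = False,
    min_part_len: int = 4,
    min_part_pm: float = 50.0,
) -> tuple[list[str], FilterReport]:
    """Optionally drop transparent two-part compounds.

    A word is removed when it splits into two parts, each at least
    *min_part_len* characters and each with per-million frequency at
    least *min_part_pm* in *table*.  Off by default: compounding rules
    are highly language-specific and this rule is a generic stand-in.
    """
    words = list(words)
    report = FilterReport()
    if not enabled:
        return words, report
    kept = []
    for w in words:
        if _is_transparent_compound(w, table, min_part_len, min_part_pm):
            report.add(w, REASON_COMPOUND)
        else:
            kept.append(w)
    return kept, report


def _is_transparent_compound(word, table, min_part_len, min_part_pm) -> bool:
    for cut in range(min_part_len, len(word) - min_part_len + 1):
        left, right = word[:cut], word[cut:]
        if table.per_million(left) >= min_part_pm and table.per_million(right) >= min_part_pm:
            return True
    return False


def select_rare_words(
    table,
    band_pm: tuple[float, float] = (5.0, 20.0),
    n: int = 60,
    seed: int | np.random.Generator = 0,
    target_mean_pm: float = 10.0,
    mean_tolerance: float = 0.3,
    max_resamples: int = 1000,
    exclude: Iterable[str] = (),
) -> tuple[list[str], float]:
    """Sample *n* rare words from the target frequency band.

    Words whose per-million frequency lies in ``band_pm`` (and that are
    not in *exclude*, e.g. filter-removed words) form the pool; *n* are
    drawn uniformly without replacement, redrawing (up to
    *max_resamples* attempts) until the sample's mean per-million
    frequency is within ``mean_tolerance`` (default ±30%) of
    *target_mean_pm*.  The printed target of 10 per million pitches the
    test at proficient speakers; lowering it makes the test harder.

    Returns the selected words and the achieved mean per-million.
    """
    lo, hi = band_pm
    if lo >= hi:
        raise ValueError("band_pm must be (low, high) with low < high")
    excluded = set(exclude)
    pool = [w for w in table.entries if w not in excluded and lo <= table.per_million(w) <= hi]
    if len(pool) < n:
        raise ValueError(
            f"in-band pool has {len(pool)} words, fewer than the requested {n}"
        )
    pool.sort()  # decouple sampling from dict iteration order
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pm = np.array([table.per_million(w) for w in pool])
    lo_mean = target_mean_pm * (1 - mean_tolerance)
    hi_mean = target_mean_pm * (1 + mean_tolerance)
    for _ in range(max_resamples):
        idx = rng.choice(len(pool), size=n, replace=False)
        mean_pm = float(pm[idx].mean())
        if lo_mean <= mean_pm <= hi_mean:
            return [pool[i] for i in idx], mean_pm
    raise RuntimeError(
        f"could not reach mean per-million in [{lo_mean:.3g}, {hi_mean:.3g}] "
        f"within {max_resamples} resamples (band {band_pm}, n={n})"
    )
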