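"""Corpus ingestion: tokenization, cleaning, and word-frequency tables.

The vocabulary-test pipeline starts from a plain-text corpus (UTF-8, one
document per line).  This module turns raw text into a
:class:`FrequencyTable` mapping casefolded word types to corpus counts,
from which per-million frequencies — the difficulty dial of the test —
are computed.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "CorpusMeta",
    "FrequencyTable",
    "tokenize",
    "clean_tokens",
    "build_frequency_table",
    "frequency_table_from_lines",
    "write_frequency_tsv",
    "read_frequency_tsv",
]

# Maximal runs of Unicode letters, optionally joined by internal
# apostrophes (ASCII or typographic) or hyphens.  ``[^\W\d_]`` is the
# re-module idiom for "Unicode letter".
_TOKEN_RE = re.compile(r"[^\W\d_]+(?:['’\-][^\W\d_]+)*")

DEFAULT_MIN_LEN = 2
DEFAULT_MAX_LEN = 20

# Characters allowed inside tokens that carry no script of their own.
_SCRIPT_NEUTRAL = {"'", "’", "-"}


@dataclass(frozen=True)
class CorpusMeta:
    """Provenance of a corpus: language code, script, and source label."""

    language: str
    script: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.language:
            raise ValueError("language code must be non-empty")


@dataclass
class FrequencyTable:
    """Word-type counts with per-million normalization.

    Invariants: counts are positive integers summing to ``total_tokens``;
    stored words are casefolded and contain no digits or whitespace.
    """

    entries: dict[str, int]
    total_tokens: int
    meta: CorpusMeta = field(default_factory=lambda: CorpusMeta(language="und"))

    def __post_init__(self) -> None:
        if self.total_tokens <= 0:
            raise ValueError("total_tokens must be positive")
        for word, count in self.entries.items():
            if count <= 0:
                raise ValueError(f"non-positive count for {word!r}")
            if any(ch.isdigit() or ch.isspace() for ch in word):
                raise ValueError(f"invalid stored word {word!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def count(self, word: str) -> int:
        return self.entries.get(word, 0)

    def per_million(self, word: str) -> float:
        """Occurrences of *word* per one million corpus tokens."""
        return self.entries.get(word, 0) / self.total_tokens * 1_000_000

    def sorted_items(self) -> list[tuple[str, int]]:
        """Entries ordered by descending count, ties broken lexicographically."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))


def tokenize(text: str, meta: CorpusMeta | None = None) -> list[str]:
    """Split *text* into word tokens, preserving original casing.

    Tokens are maximal runs of Unicode letters, optionally containing
    internal apostrophes or hyphens; surrounding punctuation is dropped.
    """
    if isinstance(text, bytes):  # decoding is the caller's job, but fail loudly
        text = text.decode("utf-8")
    return _TOKEN_RE.findall(text)


@lru_cache(maxsize=None)
def _char_script(ch: str) -> str | None:
    """Coarse Unicode script of a character, None if neutral/unknown.

    Derived from the leading word of the character's Unicode name
    (LATIN, CYRILLIC, CJK, ...), which is a sufficient proxy for the
    mixed-script guard below.
    """
    if ch in _SCRIPT_NEUTRAL:
        return None
    try:
        name = unicodedata.name(ch)
    except ValueError:
        return None
    return name.split(" ", 1)[0]


def _is_single_script(word: str) -> bool:
    scripts = {s for ch in word if (s := _char_script(ch)) is not None}
    return len(scripts) <= 1


_ASCII_LOWER_RE = re.compile(r"[a-z'\-]+\Z")


def _clean_one(
    token: str, min_len: int, max_len: int
) -> str | None:
    """Casefold *token* and apply the cleaning filters; None if rejected."""
    word = token.casefold()
    if not (min_len <= len(word) <= max_len):
        return None
    # Fast path: all-ASCII lowercase words are single-script and digit-free.
    if _ASCII_LOWER_RE.match(word):
        return word
    if any(ch.isdigit() for ch in word):
        return None
    if not _is_single_script(word):
        return None
    return word


def clean_tokens(
    tokens: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Casefold tokens and drop unusable ones.

    Removes tokens containing digits, tokens outside the configured
    length bounds (applied to the casefolded form), and tokens mixing
    characters from more than one Unicode script — a cheap,
    language-agnostic guard against boilerplate in multilingual corpora.
    Idempotent.
    """
    out = []
    for tok in tokens:
        word = _clean_one(tok, min_len, max_len)
        if word is not None:
            out.append(word)
    return out


def build_frequency_table(
    words: Iterable[str], meta: CorpusMeta | None = None
) -> FrequencyTable:
    """Count cleaned words into a :class:`FrequencyTable`.

    ``total_tokens`` equals the number of input words, so conservation
    (sum of counts = token count) holds by construction.
    """
    counts = Counter(words)
    if not counts:
        raise ValueError("empty corpus")
    total = sum(counts.values())
    return FrequencyTable(
        entries=dict(counts),
        total_tokens=total,
        meta=meta or CorpusMeta(language="und"),
    )


def frequency_table_from_lines(
    lines: Iterable[str],
    meta: CorpusMeta | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> FrequencyTable:
    """Tokenize, clean, and count a corpus given as an iterable of documents.

    Counts raw tokens first and cleans unique types afterwards, which is
    equivalent to ``build_frequency_table(clean_tokens(tokenize(...)))``
    because cleaning is a pure per-token map, but far faster on large
    corpora where the type/token ratio is small.
    """
    raw = Counter()
    for line in lines:
        raw.update(tokenize(line))
    cleaned: Counter[str] = Counter()
    for tok, n in raw.items():
        word = _clean_one(tok, min_len, max_len)
        if word is not None:
            cleaned[word] += n
    if not cleaned:
        raise ValueError("empty corpus")
    return FrequencyTable(
        entries=dict(cleaned),
        total_tokens=sum(cleaned.values()),
        meta=meta or CorpusMeta(language="und"),
    )


def write_frequency_tsv(table: FrequencyTable, destination: str | Path | IO[str]) -> None:
    """Write a frequency table as TSV.

    Format: a comment line ``# total_tokens=<N>``, a header
    ``word<TAB>count<TAB>per_million``, then rows sorted by descending
    count with lexicographic tie-break.
    """
    close = False
    if isinstance(destination, (str, Path)):
        fh: IO[str] = open(destination, "w", encoding="utf-8")
        close = True
    else:
        fh = destination
    try:
        fh.write(f"# total_tokens={table.total_tokens}\n")
        fh.write("word\tcount\tper_million\n")
        for word, count in table.sorted_items():
            fh.write(f"{word}\t{count}\t{table.per_million(word):.6g}\n")
    finally:
        if close:
            fh.close()


def _iter_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_frequency_tsv(
    source: str | Path | IO[str], meta: CorpusMeta | None = None
) -> FrequencyTable:
    """Read a frequency table written by :func:`write_frequency_tsv`.

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    entries: dict[str, int] = {}
    total_tokens: int | None = None
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*total_tokens=(\d+)\Z", line)
            if m:
                total_tokens = int(m.group(1))
            continue
        if line == "word\tcount\tper_million":
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        word, count_s, _pm = parts
        try:
            count = int(count_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad count {count_s!r}") from exc
        if count <= 0:
            raise ValueError(f"line {lineno}: non-positive count for {word!r}")
        if word in entries:
            raise ValueError(f"line {lineno}: duplicate word {word!r}")
        entries[word] = count
    if total_tokens is None:
        raise ValueError("missing '# total_tokens=' line")
    if not entries:
        raise ValueError("empty table")
    return FrequencyTable(
        entries=entries,
        total_tokens=total_tokens,
        meta=meta or CorpusMeta(language="und"),
    )
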