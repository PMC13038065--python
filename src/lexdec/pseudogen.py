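"""Character n-gram model fitting and pseudoword sampling.

Pseudowords — wordlike letter strings that are not words of the
language — are produced by a character n-gram model of the real
lexicon: each word is read as a sequence of transitions
``context (k−1 symbols) → next symbol``, the transition probabilities
are estimated by counting, and new strings are sampled transition by
transition.  Because sampling only ever leaves observed contexts, every
window of a sampled string is attested in the training lexicon, which
is what makes the output look like plausible words.

Character-based scripts (Chinese, Japanese, Korean, ...) are handled
through an invertible transliteration into a letter string (e.g.
Pinyin); the model is fitted and sampled in letter space and sampled
strings are decoded back.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .filters import DictionaryResource, is_typo_of_dictionary

__all__ = [
    "START",
    "END",
    "UNDEFINED",
    "CharNGramModel",
    "TransliterationScheme",
    "IDENTITY_SCHEME",
    "toy_syllabary_scheme",
    "PseudowordCandidate",
    "SamplingConstraints",
    "PseudowordExhaustion",
    "fit_ngram",
    "mean_log_prob",
    "sample_pseudoword",
    "generate_pseudoword_set",
    "roundtrip_check",
    "write_model_json",
    "read_model_json",
]

# Boundary symbols padding each training word: k−1 STX on the left, one
# ETX terminator.  Control characters cannot occur in cleaned words.
START = "\x02"
END = "\x03"

#: Sentinel returned by :func:`mean_log_prob` when a word traverses an
#: unseen context or a zero-probability transition.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class TransliterationScheme:
    """Invertible mapping between a script and a letter representation.

    ``decode(encode(w))`` must equal ``w`` for every word the model is
    trained on (checked by :func:`roundtrip_check`); ``decode`` must
    raise ``ValueError`` on strings outside its image.
    """

    name: str
    encode: Callable[[str], str]
    decode: Callable[[str], str]


IDENTITY_SCHEME = TransliterationScheme(
    name="identity", encode=lambda w: w, decode=lambda s: s
)


def toy_syllabary_scheme(symbols: Sequence[str]) -> TransliterationScheme:
    """Invertible letter encoding for a toy syllabary (testing aid).

    Each syllabary symbol maps to ``s<index>.``; the trailing dot makes
    the code self-delimiting, hence decodable.
    """
    to_code = {sym: f"s{i}." for i, sym in enumerate(symbols)}
    if len(to_code) != len(symbols):
        raise ValueError("syllabary symbols must be distinct")
    from_code = {f"s{i}": sym for i, sym in enumerate(symbols)}

    def encode(word: str) -> str:
        try:
            return "".join(to_code[ch] for ch in word)
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not in syllabary") from None

    def decode(text: str) -> str:
        out = []
        for chunk in text.split("."):
            if chunk == "":
                continue
            if chunk not in from_code:
                raise ValueError(f"code {chunk!r} not decodable")
            out.append(from_code[chunk])
        decoded = "".join(out)
        if encode(decoded) != text:
            raise ValueError(f"{text!r} is not a valid syllabary encoding")
        return decoded

    return TransliterationScheme(name="toy-syllabary", encode=encode, decode=decode)


@dataclass
class CharNGramModel:
    """Order-k character transition model with boundary padding.

    ``order`` k means k−1 context symbols predict the next symbol.
    Counts are over word *types* (each lexicon word contributes once
    regardless of corpus frequency), so high-frequency words do not
    dominate the transition statistics.
    """

    order: int
    transitions: dict[str, dict[str, int]]  # context -> {next symbol: count}
    lexicon_fingerprint: str = ""
    scheme_name: str = "identity"

    _probs: dict[str, tuple[list[str], np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")

    @property
    def context_length(self) -> int:
        return self.order - 1

    def _dist(self, context: str) -> tuple[list[str], np.ndarray]:
        cached = self._probs.get(context)
        if cached is None:
            counts = self.transitions[context]
            symbols = list(counts)
            weights = np.array([counts[s] for s in symbols], dtype=float)
            cached = (symbols, weights / weights.sum())
            self._probs[context] = cached
        return cached

    def prob(self, context: str, symbol: str) -> float:
        """P(symbol | context); 0 for unseen pairs or unseen contexts."""
        counts = self.transitions.get(context)
        if not counts:
            return 0.0
        return counts.get(symbol, 0) / sum(counts.values())


def _windows(encoded: str, k: int) -> Iterable[tuple[str, str]]:
    """(context, next-symbol) windows of a padded encoded word."""
    padded = START * (k - 1) + encoded + END
    for i in range(len(encoded) + 1):
        yield padded[i : i + k - 1], padded[i + k - 1]


def _fingerprint(words: Iterable[str]) -> str:
    import hashlib

    h = hashlib.sha256()
    for w in sorted(words):
        h.update(w.encode("utf-8"))
        h.update(b"\x00")
    return h.hexdigest()[:16]


def fit_ngram(
    lexicon: Iterable[str],
    k: int = 5,
    scheme: TransliterationScheme | None = None,
) -> CharNGramModel:
    """Fit an order-*k* character transition model on a lexicon.

    Each word (transliterated first if *scheme* is given) is padded
    with k−1 start symbols and one end symbol; every k-window adds one
    count to its context→next-symbol cell.  No smoothing is applied:
    sampling from observed contexts only guarantees that every window
    of a sampled string is attested, which maximizes wordlikeness.
    """
    words = set(lexicon)
    if not words:
        raise ValueError("empty lexicon")
    scheme = scheme or IDENTITY_SCHEME
    transitions: dict[str, dict[str, int]] = {}
    for word in words:
        if START in word or END in word:
            raise ValueError(f"word {word!r} contains a reserved boundary symbol")
        try:
            encoded = scheme.encode(word)
        except ValueError as exc:
            raise ValueError(f"word {word!r} not encodable: {exc}") from exc
        for context, nxt in _windows(encoded, k):
            transitions.setdefault(context, {})[nxt] = (
                transitions.setdefault(context, {}).get(nxt, 0) + 1
            )
    return CharNGramModel(
        order=k,
        transitions=transitions,
        lexicon_fingerprint=_fingerprint(words),
        scheme_name=scheme.name,
    )


def mean_log_prob(
    model: CharNGramModel,
    word: str,
    scheme: TransliterationScheme | None = None,
) -> float:
    """Mean natural-log transition probability of *word* under *model*.

    Averages ln P(next|context) over the word's padded windows; returns
    NaN (the undefined marker) if any window has zero probability.
    Pass the *scheme* the model was fitted with to score a surface word
    of a transliterated script; without one, *word* is scored as-is.
    """
    if scheme is not None:
        word = scheme.encode(word)
    total = 0.0
    n = 0
    for context, nxt in _windows(word, model.order):
        p = model.prob(context, nxt)
        if p == 0.0:
            return UNDEFINED
        total += math.log(p)
        n += 1
    return total / n


@dataclass(frozen=True)
class PseudowordCandidate:
    """An accepted pseudoword with its model statistics."""

    surface: str
    mean_log_p: float
    length: int
    encoded: str = ""


@dataclass
class SamplingConstraints:
    min_length: int = 2
    max_length: int = 20
    lexicon: frozenset[str] = frozenset()
    dictionary: DictionaryResource | None = None
    max_attempts: int = 10_000
    typo_max_distance: int = 1


class PseudowordExhaustion(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""

    def __init__(self, attempts: int, tallies: Mapping[str, int]):
        self.tallies = dict(tallies)
        detail = ", ".join(f"{k}={v}" for k, v in sorted(self.tallies.items()))
        super().__init__(
            f"no acceptable pseudoword after {attempts} attempts ({detail})"
        )


def _sample_string(model: CharNGramModel, rng: np.random.Generator, max_len: int) -> str | None:
    """Draw one encoded string; None if it exceeds *max_len* symbols."""
    context = START * model.context_length
    out: list[str] = []
    while True:
        symbols, probs = model._dist(context)
        sym = symbols[rng.choice(len(symbols), p=probs)] if len(symbols) > 1 else symbols[0]
        if sym == END:
            return "".join(out)
        out.append(sym)
        if len(out) > max_len:
            return None
        context = (context + sym)[-model.context_length :]


def _attempt(
    model: CharNGramModel,
    constraints: SamplingConstraints,
    scheme: TransliterationScheme,
    rng: np.random.Generator,
    tallies: dict[str, int],
) -> PseudowordCandidate | None:
    encoded = _sample_string(model, rng, max_len=4 * constraints.max_length)
    if encoded is None:
        tallies["too_long"] = tallies.get("too_long", 0) + 1
        return None
    try:
        surface = scheme.decode(encoded)
    except ValueError:
        tallies["undecodable"] = tallies.get("undecodable", 0) + 1
        return None
    if not (constraints.min_length <= len(surface) <= constraints.max_length):
        tallies["length"] = tallies.get("length", 0) + 1
        return None
    if surface in constraints.lexicon:
        tallies["in_lexicon"] = tallies.get("in_lexicon", 0) + 1
        return None
    if constraints.dictionary is not None and is_typo_of_dictionary(
        surface, constraints.dictionary, constraints.typo_max_distance
    ):
        tallies["typo_of_dictionary"] = tallies.get("typo_of_dictionary", 0) + 1
        return None
    return PseudowordCandidate(
        surface=surface,
        mean_log_p=mean_log_prob(model, encoded),
        length=len(surface),
        encoded=encoded,
    )


def sample_pseudoword(
    model: CharNGramModel,
    constraints: SamplingConstraints | None = None,
    seed: int | np.random.Generator = 0,
    scheme: TransliterationScheme | None = None,
) -> PseudowordCandidate:
    """Rejection-sample one acceptable pseudoword.

    Symbols are drawn from the fitted context distributions until the
    end symbol.  A draw is accepted iff it decodes, its surface length
    is within bounds, it is not a lexicon word, and it is not within
    one typo of a dictionary entry.  Deterministic given the seed.
    """
    constraints = constraints or SamplingConstraints()
    scheme = scheme or IDENTITY_SCHEME
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tallies: dict[str, int] = {}
    for _ in range(constraints.max_attempts):
        cand = _attempt(model, constraints, scheme, rng, tallies)
        if cand is not None:
            return cand
    raise PseudowordExhaustion(constraints.max_attempts, tallies)


def generate_pseudoword_set(
    model: CharNGramModel,
    n: int,
    constraints: SamplingConstraints | None = None,
    seed: int = 0,
    scheme: TransliterationScheme | None = None,
) -> list[PseudowordCandidate]:
    """Generate *n* distinct pseudowords.

    Per-candidate random streams are spawned from the master seed, so
    the set is reproducible and insensitive to how many rejections each
    slot needed.  Duplicate surfaces are resampled.
    """
    constraints = constraints or SamplingConstraints()
    scheme = scheme or IDENTITY_SCHEME
    seen: set[str] = set()
    out: list[PseudowordCandidate] = []
    tallies: dict[str, int] = {}
    budget = n + constraints.max_attempts  # streams: n successes + duplicate slack
    stream = 0
    while len(out) < n:
        if stream >= budget:
            raise PseudowordExhaustion(stream, tallies)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))
        stream += 1
        cand = sample_pseudoword(model, constraints, seed=rng, scheme=scheme)
        if cand.surface in seen:
            tallies["duplicate"] = tallies.get("duplicate", 0) + 1
            continue
        seen.add(cand.surface)
        out.append(cand)
    return out


def roundtrip_check(
    scheme: TransliterationScheme, lexicon: Iterable[str]
) -> list[tuple[str, str]]:
    """Words for which decode(encode(w)) ≠ w, with what decoding gave.

    A scheme may only be used for model fitting once this report is
    empty.
    """
    failures = []
    for w in lexicon:
        try:
            back = scheme.decode(scheme.encode(w))
        except ValueError as exc:
            failures.append((w, f"<error: {exc}>"))
            continue
        if back != w:
            failures.append((w, back))
    return failures


def write_model_json(model: CharNGramModel, destination: str | Path) -> None:
    doc = {
        "order": model.order,
        "start_symbol": START,
        "end_symbol": END,
        "scheme_name": model.scheme_name,
        "lexicon_fingerprint": model.lexicon_fingerprint,
        "transitions": {
            ctx: dict(sorted(nxt.items())) for ctx, nxt in sorted(model.transitions.items())
        },
    }
    with open(destination, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def read_model_json(source: str | Path) -> CharNGramModel:
    with open(source, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("start_symbol") != START or doc.get("end_symbol") != END:
        raise ValueError("model file uses unknown boundary symbols")
    return CharNGramModel(
        order=int(doc["order"]),
        transitions={
            ctx: {s: int(c) for s, c in nxt.items()}
            for ctx, nxt in doc["transitions"].items()
        },
        lexicon_fingerprint=doc.get("lexicon_fingerprint", ""),
        scheme_name=doc.get("scheme_name", "identity"),
    )
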