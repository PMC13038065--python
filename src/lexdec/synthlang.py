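"""Synthetic languages, corpora, and simulated responders.

Everything downstream of raw text is testable without any download:
this module builds artificial lexicons from a consonant–vowel template
grammar, samples Zipf-distributed corpora from them, and simulates
participants with controlled hit probabilities.  The word-shape
grammar gives the fitted n-gram model rich but finite context
structure; the Zipfian rank–frequency law reproduces the one statistic
of real corpora the pipeline actually relies on, the shape of the
frequency spectrum.  Morphology, semantics and real phonology are
deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .testkit import AnswerKey, TestSpec

__all__ = [
    "SyntheticLanguage",
    "ResponderProfile",
    "generate_language",
    "generate_corpus",
    "write_corpus",
    "simulate_responses",
]

_VOWELS = "aeiou"


@dataclass
class SyntheticLanguage:
    """A lexicon with Zipfian sampling weights.

    ``weights[r]`` ∝ (r+1)^(−s): the word at rank r (0-based) follows a
    Zipf law with exponent ``zipf_exponent``.
    """

    alphabet: str
    lexicon: list[str]
    zipf_exponent: float
    seed: int
    weights: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.lexicon)) != len(self.lexicon):
            raise ValueError("lexicon words must be distinct")
        if self.weights is None:
            ranks = np.arange(1, len(self.lexicon) + 1, dtype=float)
            w = ranks ** (-self.zipf_exponent)
            self.weights = w / w.sum()

    @property
    def vocabulary_size(self) -> int:
        return len(self.lexicon)


def _make_word(rng: np.random.Generator, consonants: str, vowels: str,
               min_len: int, max_len: int) -> str:
    """One word from the CV template grammar.

    Words are sequences of CV syllables, occasionally closed by a coda
    consonant, truncated to the length bounds.
    """
    target = int(rng.integers(min_len, max_len + 1))
    chars: list[str] = []
    while len(chars) < target:
        chars.append(consonants[rng.integers(len(consonants))])
        if len(chars) >= target:
            break
        chars.append(vowels[rng.integers(len(vowels))])
        # 20% chance of a closing coda for syllable variety
        if len(chars) < target and rng.random() < 0.2:
            chars.append(consonants[rng.integers(len(consonants))])
    return "".join(chars[:target])


def generate_language(
    V: int = 5000,
    s: float = 1.0,
    alphabet_size: int = 20,
    seed: int = 0,
    min_word_len: int = 4,
    max_word_len: int = 10,
) -> SyntheticLanguage:
    """Generate a synthetic language of *V* distinct words.

    The alphabet is the first *alphabet_size* lowercase Latin letters
    (guaranteed to include vowels and consonants); word shapes come
    from the CV grammar; rank r carries Zipf weight ∝ r^(−s).
    """
    if V < 100:
        raise ValueError("V must be >= 100")
    if s <= 0:
        raise ValueError("Zipf exponent must be positive")
    alphabet = "abcdefghijklmnopqrstuvwxyz"[:alphabet_size]
    vowels = "".join(c for c in alphabet if c in _VOWELS)
    consonants = "".join(c for c in alphabet if c not in _VOWELS)
    if not vowels or not consonants:
        raise ValueError("alphabet must contain both vowels and consonants")
    # capacity check before potentially looping forever: CV-template
    # words of maximal length dominate the reachable vocabulary
    capacity = (len(consonants) * max(1, len(vowels))) ** (max_word_len // 2)
    if capacity < 10 * V:
        raise ValueError("alphabet too small for V distinct words in length bounds")
    rng = np.random.default_rng(seed)
    lexicon: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(lexicon) < V:
        attempts += 1
        if attempts > 100 * V:
            raise ValueError("alphabet too small for V distinct words in length bounds")
        w = _make_word(rng, consonants, vowels, min_word_len, max_word_len)
        if w not in seen:
            seen.add(w)
            lexicon.append(w)
    return SyntheticLanguage(alphabet=alphabet, lexicon=lexicon, zipf_exponent=s, seed=seed)


def generate_corpus(
    language: SyntheticLanguage, n_tokens: int, seed: int = 0
) -> np.ndarray:
    """Draw *n_tokens* i.i.d. tokens from the language's Zipf weights."""
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(language.lexicon), size=n_tokens, p=language.weights)
    lex = np.array(language.lexicon, dtype=object)
    return lex[idx]


def write_corpus(
    tokens: Iterable[str], destination: str | Path, tokens_per_line: int = 100
) -> None:
    """Write a token stream as corpus text, one pseudo-document per line."""
    with open(destination, "w", encoding="utf-8") as fh:
        line: list[str] = []
        for tok in tokens:
            line.append(tok)
            if len(line) >= tokens_per_line:
                fh.write(" ".join(line) + "\n")
                line = []
        if line:
            fh.write(" ".join(line) + "\n")


@dataclass(frozen=True)
class ResponderProfile:
    """A simulated participant.

    ``p_correct_real`` / ``p_correct_pseudo`` are the probabilities of
    answering a real-word / pseudoword item correctly on any single
    presentation.  ``repeat_behavior`` is ``"independent"`` (each
    presentation is a fresh Bernoulli draw — consistency converges to
    p² + (1−p)²) or ``"sticky"`` (the second presentation copies the
    first — consistency is exactly 1).
    """

    participant_id: str
    p_correct_real: float = 0.9
    p_correct_pseudo: float = 0.9
    repeat_behavior: str = "independent"

    def __post_init__(self) -> None:
        if not (0 <= self.p_correct_real <= 1 and 0 <= self.p_correct_pseudo <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.repeat_behavior not in ("independent", "sticky"):
            raise ValueError("repeat_behavior must be 'independent' or 'sticky'")


def _flip(label: str) -> str:
    return "pseudoword" if label == "word" else "word"


def simulate_responses(
    spec: TestSpec,
    key: AnswerKey,
    profiles: Sequence[ResponderProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the cohort's response table for *spec*.

    Each participant answers every presentation of every item; a
    presentation is correct with the class-appropriate probability.
    Deterministic given the seed.  Returns the standard responses
    table (``rt_ms`` left empty).
    """
    key.check_against(spec)
    rows = []
    for p_idx, profile in enumerate(profiles):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(p_idx,)))
        for block in spec.blocks:
            seen_count: dict[str, int] = {}
            first_answer: dict[str, str] = {}
            for item in block:
                pres = seen_count.get(item.item_id, 0) + 1
                seen_count[item.item_id] = pres
                truth = key.labels[item.item_id]
                p = (
                    profile.p_correct_real
                    if truth == "word"
                    else profile.p_correct_pseudo
                )
                if pres == 2 and profile.repeat_behavior == "sticky":
                    answer = first_answer[item.item_id]
                else:
                    answer = truth if rng.random() < p else _flip(truth)
                if pres == 1:
                    first_answer[item.item_id] = answer
                rows.append(
                    {
                        "participant_id": profile.participant_id,
                        "item_id": item.item_id,
                        "presentation_index": pres,
                        "response": answer,
                        "rt_ms": np.nan,
                    }
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "item_id", "presentation_index", "response", "rt_ms"]
    )
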