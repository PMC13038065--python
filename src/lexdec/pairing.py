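"""Matching real words to pseudowords on low-level statistics.

A lexical-decision test is only fair if real and fake items cannot be
told apart by superficial cues.  Each selected rare word is therefore
paired with a pseudoword of similar length and similar mean log
transition probability under the fitted n-gram model, so the two item
classes have matched surface statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .pseudogen import CharNGramModel, PseudowordCandidate, TransliterationScheme, mean_log_prob

__all__ = ["ItemPair", "item_features", "pair_items", "write_pairs_tsv", "read_pairs_tsv"]


@dataclass(frozen=True)
class ItemPair:
    """A real word matched to a pseudoword, with their feature distance."""

    real: str
    pseudo: PseudowordCandidate
    feature_distance: float

    def __post_init__(self) -> None:
        if self.real == self.pseudo.surface:
            raise ValueError(f"real and pseudo surfaces coincide: {self.real!r}")
        if self.feature_distance < 0:
            raise ValueError("feature_distance must be non-negative")


def item_features(
    word: str,
    model: CharNGramModel,
    scheme: TransliterationScheme | None = None,
) -> tuple[float, float]:
    """(character length, mean log transition probability) of *word*.

    Raises ``ValueError`` for words the model cannot score (a window
    with zero probability).
    """
    mlp = mean_log_prob(model, word, scheme=scheme)
    if np.isnan(mlp):
        raise ValueError(f"{word!r} is not scorable under the model")
    return (float(len(word)), mlp)


def pair_items(
    real_words: Sequence[str],
    pseudowords: Sequence[PseudowordCandidate],
    model: CharNGramModel,
    seed: int | np.random.Generator = 0,
    scheme: TransliterationScheme | None = None,
) -> list[ItemPair]:
    """Greedily match each real word to its nearest unused pseudoword.

    Features of both pools are standardized jointly to zero mean / unit
    variance so neither dimension dominates; real words are visited in
    seeded random order and each claims the unused pseudoword nearest
    in Euclidean feature distance.  Greedy matching is near-optimal at
    these pool sizes and deterministic given the seed; swap in an
    optimal-assignment solver if exactness matters.
    """
    if len(pseudowords) < len(real_words):
        raise ValueError(
            f"pseudoword pool ({len(pseudowords)}) smaller than "
            f"real-word pool ({len(real_words)})"
        )
    real_feats = np.array([item_features(w, model, scheme) for w in real_words])
    pseudo_feats = np.array(
        [(float(c.length), c.mean_log_p) for c in pseudowords]
    )
    if np.isnan(pseudo_feats).any():
        raise ValueError("pseudoword pool contains unscorable candidates")
    union = np.vstack([real_feats, pseudo_feats])
    mean = union.mean(axis=0)
    std = union.std(axis=0)
    std[std == 0] = 1.0  # constant feature: no contribution either way
    rz = (real_feats - mean) / std
    pz = (pseudo_feats - mean) / std

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(real_words))
    unused = np.ones(len(pseudowords), dtype=bool)
    pairs: list[ItemPair | None] = [None] * len(real_words)
    for i in order:
        d = np.linalg.norm(pz - rz[i], axis=1)
        d[~unused] = np.inf
        j = int(np.argmin(d))
        unused[j] = False
        pairs[i] = ItemPair(
            real=real_words[i], pseudo=pseudowords[j], feature_distance=float(d[j])
        )
    return [p for p in pairs if p is not None]


def write_pairs_tsv(pairs: Sequence[ItemPair], destination: str | Path) -> None:
    with open(destination, "w", encoding="utf-8") as fh:
        fh.write("real\tpseudo\tfeature_distance\n")
        for p in pairs:
            fh.write(f"{p.real}\t{p.pseudo.surface}\t{p.feature_distance:.6g}\n")


def read_pairs_tsv(source: str | Path) -> list[tuple[str, str, float]]:
    """Read a pairs TSV as (real, pseudo, feature_distance) rows."""
    rows = []
    with open(source, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "real\tpseudo\tfeature_distance":
            raise ValueError("unexpected pairs header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields")
            rows.append((parts[0], parts[1], float(parts[2])))
    return rows
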