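"""End-to-end test construction from a corpus.

Chains the pipeline stages: frequency table → real-word filtering and
rare-word selection → n-gram fit → pseudoword sampling → pairing →
block assembly.  Exists so the command-line ``build`` command and
programmatic users share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import corpus as corpus_mod
from . import filters as filters_mod
from .corpus import CorpusMeta, FrequencyTable
from .filters import CasingStats, DictionaryResource, FilterReport
from .pairing import ItemPair, pair_items
from .pseudogen import (
    CharNGramModel,
    SamplingConstraints,
    TransliterationScheme,
    fit_ngram,
    generate_pseudoword_set,
    roundtrip_check,
)
from .testkit import AnswerKey, TestSpec, assemble_test

__all__ = ["BuildResult", "build_test_from_lines", "build_test_from_corpus_file"]


@dataclass
class BuildResult:
    """Everything the build produced, for inspection and serialization."""

    spec: TestSpec
    key: AnswerKey
    table: FrequencyTable
    model: CharNGramModel
    pairs: list[ItemPair]
    real_words: list[str]
    achieved_mean_pm: float
    filter_report: FilterReport


def build_test_from_lines(
    lines: Iterable[str],
    meta: CorpusMeta,
    dictionary: DictionaryResource | None = None,
    scheme: TransliterationScheme | None = None,
    order: int = 5,
    n_blocks: int = 2,
    items_per_block: int = 30,
    repeat_items: bool = False,
    band_pm: tuple[float, float] = (5.0, 20.0),
    target_mean_pm: float = 10.0,
    proper_noun_threshold: float = 0.5,
    compound_filter_enabled: bool = False,
    seed: int = 0,
    test_id: str = "test",
) -> BuildResult:
    """Build a complete lexical-decision test from corpus lines.

    The real-word pool is the frequency table's types, filtered for
    misspellings (dictionary membership, when a dictionary is given),
    proper nouns (capitalization heuristic), and optionally transparent
    compounds; rare words are drawn from the per-million band around
    the target mean.  The n-gram model is fitted on the full cleaned
    type lexicon; pseudowords are sampled from it, rejecting lexicon
    words and dictionary typo-neighbours, then paired to the selected
    real words and laid out into blocks.
    """
    if scheme is not None:
        # a transliteration scheme must be invertible on the data it serves
        lines = list(lines)

    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4) % (2**31)]

    raw_tokens: list[str] = []
    for line in lines:
        raw_tokens.extend(corpus_mod.tokenize(line))
    casing = CasingStats.from_tokens(raw_tokens)
    words = corpus_mod.clean_tokens(raw_tokens)
    table = corpus_mod.build_frequency_table(words, meta)

    lexicon = set(table.entries)
    if scheme is not None:
        failures = roundtrip_check(scheme, lexicon)
        if failures:
            raise ValueError(
                f"transliteration scheme fails round-trip on {len(failures)} "
                f"words, e.g. {failures[:3]}"
            )

    pool = sorted(lexicon)
    pool, rep_spell = filters_mod.filter_misspellings(pool, dictionary)
    pool, rep_proper = filters_mod.filter_proper_nouns(
        pool, casing, threshold=proper_noun_threshold
    )
    pool, rep_comp = filters_mod.compound_filter(
        pool, table, enabled=compound_filter_enabled
    )
    report = FilterReport()
    for rep in (rep_spell, rep_proper, rep_comp):
        report.merge(rep)

    n_items = n_blocks * items_per_block
    n_real = n_items // 2
    excluded = set(table.entries) - set(pool)
    real_words, achieved_mean = filters_mod.select_rare_words(
        table,
        band_pm=band_pm,
        n=n_real,
        seed=seeds[0],
        target_mean_pm=target_mean_pm,
        exclude=excluded,
    )

    model = fit_ngram(lexicon, k=order, scheme=scheme)
    lengths = [len(w) for w in real_words]
    constraints = SamplingConstraints(
        min_length=min(lengths),
        max_length=max(lengths),
        lexicon=frozenset(lexicon),
        dictionary=dictionary,
    )
    pseudos = generate_pseudoword_set(
        model, n=n_real, constraints=constraints, seed=seeds[1], scheme=scheme
    )

    pairs = pair_items(real_words, pseudos, model, seed=seeds[2], scheme=scheme)
    spec, key = assemble_test(
        pairs,
        n_blocks=n_blocks,
        items_per_block=items_per_block,
        repeat_items=repeat_items,
        seed=seeds[3],
        test_id=test_id,
        language=meta.language,
        provenance={
            "source": meta.source,
            "model_order": order,
            "lexicon_fingerprint": model.lexicon_fingerprint,
            "seed": seed,
            "target_mean_pm": target_mean_pm,
            "achieved_mean_pm": achieved_mean,
        },
    )
    return BuildResult(
        spec=spec,
        key=key,
        table=table,
        model=model,
        pairs=pairs,
        real_words=real_words,
        achieved_mean_pm=achieved_mean,
        filter_report=report,
    )


def build_test_from_corpus_file(path: str | Path, meta: CorpusMeta, **kwargs) -> BuildResult:
    with open(path, encoding="utf-8") as fh:
        return build_test_from_lines(fh, meta, **kwargs)
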