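"""Shared fixtures: synthetic languages and pipeline artifacts.

Two session-scoped languages: a small one (V=5,000) for n-gram,
pseudoword, and dictionary tests, and a larger one (V=20,000 types,
600k tokens) for anything touching the rare-frequency band — with a
Zipf exponent of 1, the ranks whose expected frequency lies in the
default 5–20 per-million band only exist inside a vocabulary of
roughly 20,000 types or more.
"""

import numpy as np
import pytest

import lexdec as lx


@pytest.fixture(scope="session")
def language():
    return lx.generate_language(V=5000, s=1.0, seed=7)


@pytest.fixture(scope="session")
def dictionary(language):
    return lx.DictionaryResource(entries=frozenset(language.lexicon), name="synth-dict")


@pytest.fixture(scope="session")
def ngram_model(language):
    return lx.fit_ngram(frozenset(language.lexicon), k=5)


@pytest.fixture(scope="session")
def sel_language():
    return lx.generate_language(V=20_000, s=1.0, seed=7)


@pytest.fixture(scope="session")
def corpus_lines(sel_language):
    tokens = lx.generate_corpus(sel_language, 600_000, seed=8)
    return [" ".join(tokens[i : i + 100]) for i in range(0, len(tokens), 100)]


@pytest.fixture(scope="session")
def freq_table(corpus_lines):
    return lx.frequency_table_from_lines(
        corpus_lines, lx.CorpusMeta(language="syn", source="fixture")
    )


@pytest.fixture(scope="session")
def build_result(corpus_lines):
    return lx.build_test_from_lines(
        corpus_lines, lx.CorpusMeta(language="syn", source="fixture"), seed=3
    )


@pytest.fixture(scope="session")
def repeat_test(build_result):
    """A 20-items-per-block repeat-design test from the same pairs."""
    return lx.assemble_test(
        build_result.pairs, n_blocks=2, items_per_block=20, repeat_items=True, seed=5
    )
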