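"""Pool filtering, edit distance, and rare-word selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lexdec as lx
from lexdec.filters import (
    REASON_MISSPELLING,
    _within_one_edit,
    damerau_levenshtein as dl,
)

short = st.text(alphabet="abc", max_size=5)


# ---------------------------------------------------------------- distance

@pytest.mark.parametrize(
    "a,b,d",
    [
        ("cat", "cat", 0),
        ("cat", "cta", 1),        # adjacent transposition
        ("apple", "azqle", 2),    # two substitutions
        ("aple", "apple", 1),
        ("", "abc", 3),
        ("ca", "abc", 2),         # ca→ac→abc: transposed pair edited in between
    ],
)
def test_damerau_levenshtein_known_values(a, b, d):
    assert dl(a, b) == d


def _osa(a, b):
    """Optimal-string-alignment oracle: textbook DP, upper-bounds DL."""
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = a[i - 1] != b[j - 1]
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1, D[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                D[i][j] = min(D[i][j], D[i - 2][j - 2] + 1)
    return D[la][lb]


@given(short, short)
@settings(max_examples=300, deadline=None)
def test_distance_bounds_and_symmetry(a, b):
    d = dl(a, b)
    assert d == dl(b, a)
    assert (d == 0) == (a == b)
    assert abs(len(a) - len(b)) <= d <= _osa(a, b)


@given(short, short, short)
@settings(max_examples=300, deadline=None)
def test_distance_triangle_inequality(a, b, c):
    assert dl(a, c) <= dl(a, b) + dl(b, c)


@given(st.text(alphabet="abcd", min_size=1, max_size=6), st.data())
@settings(max_examples=300, deadline=None)
def test_single_edit_is_distance_at_most_one(a, data):
    """Applying one random edit operation never moves further than 1."""
    op = data.draw(st.sampled_from(["sub", "ins", "del", "swap"]))
    i = data.draw(st.integers(0, max(0, len(a) - 1)))
    ch = data.draw(st.sampled_from("abcd"))
    if op == "sub":
        b = a[:i] + ch + a[i + 1 :]
    elif op == "ins":
        b = a[:i] + ch + a[i:]
    elif op == "del":
        b = a[:i] + a[i + 1 :]
    else:
        if len(a) < 2:
            b = a
        else:
            i = min(i, len(a) - 2)
            b = a[:i] + a[i + 1] + a[i] + a[i + 2 :]
    assert dl(a, b) <= 1
    assert _within_one_edit(a, b)


@given(short, short)
@settings(max_examples=500, deadline=None)
def test_within_one_edit_matches_distance(a, b):
    assert _within_one_edit(a, b) == (dl(a, b) <= 1)


# ---------------------------------------------------------------- typo scan

@pytest.mark.parametrize(
    "word,entries,expected",
    [
        ("aple", {"apple"}, True),
        ("apple", {"apple"}, True),
        ("zzz", {"apple"}, False),
    ],
)
def test_is_typo_of_dictionary(word, entries, expected):
    d = lx.DictionaryResource(entries=frozenset(entries))
    assert lx.is_typo_of_dictionary(word, d) is expected


def test_typo_check_without_dictionary_is_false():
    assert lx.is_typo_of_dictionary("anything", None) is False


@given(
    st.sets(st.text(alphabet="abc", min_size=1, max_size=5), min_size=1, max_size=200),
    st.text(alphabet="abc", min_size=1, max_size=5),
    st.integers(1, 2),
)
@settings(max_examples=200, deadline=None)
def test_typo_scan_agrees_with_brute_force(entries, word, max_distance):
    d = lx.DictionaryResource(entries=frozenset(entries))
    brute = min(dl(word, e) for e in entries) <= max_distance
    assert lx.is_typo_of_dictionary(word, d, max_distance) == brute


# ---------------------------------------------------------------- word pool

def test_filter_misspellings_membership():
    d = lx.DictionaryResource(entries=frozenset({"cat"}))
    kept, report = lx.filter_misspellings(["cat", "catt"], d)
    assert kept == ["cat"]
    assert report.removed == {"catt": REASON_MISSPELLING}


def test_filter_misspellings_identity_without_dictionary():
    kept, report = lx.filter_misspellings(["cat", "catt"], None)
    assert kept == ["cat", "catt"]
    assert report.removed == {}


def test_proper_noun_fraction():
    stats = lx.CasingStats(
        counts={"london": (98, 100), "the": (10, 1000), "x": (1, 1)}
    )
    assert lx.proper_noun_fraction("london", stats) == pytest.approx(0.98)
    assert lx.proper_noun_fraction("the", stats) == pytest.approx(0.01)
    assert lx.proper_noun_fraction("x", stats) == 1.0
    with pytest.raises(KeyError):
        lx.proper_noun_fraction("unseen", stats)
    kept, report = lx.filter_proper_nouns(["london", "the"], stats)
    assert kept == ["the"] and "london" in report.removed


def test_casing_stats_from_tokens():
    stats = lx.CasingStats.from_tokens(["London", "london", "London", "the"])
    assert stats.counts["london"] == (2, 3)
    assert stats.counts["the"] == (0, 1)


def test_compound_filter():
    words = ["bird"] * 200 + ["house"] * 200 + ["filler"] * 600
    table = lx.build_frequency_table(words + ["birdhouse", "birdq", "qx"])
    kept, report = lx.compound_filter(["birdhouse", "birdq"], table, enabled=True)
    assert kept == ["birdq"]
    assert report.removed == {"birdhouse": "compound"}
    kept_off, _ = lx.compound_filter(["birdhouse"], table, enabled=False)
    assert kept_off == ["birdhouse"]


def test_compound_filter_exhaustive_split_scan():
    """A word only splittable with a rare part is retained."""
    words = ["bird"] * 500 + ["pad"] * 500
    table = lx.build_frequency_table(words + ["birdqqqq"])
    kept, _ = lx.compound_filter(["birdqqqq"], table, enabled=True)
    assert kept == ["birdqqqq"]  # "qqqq" never frequent


# ------------------------------------------------------------- rare words

def test_select_rare_words_forced_pool():
    total = 1_000_000
    entries = {"wa": 9, "wb": 11, "wc": 100, "wd": 1}
    entries["filler"] = total - sum(entries.values())
    table = lx.FrequencyTable(entries=entries, total_tokens=total)
    words, mean = lx.select_rare_words(table, band_pm=(5, 20), n=2, seed=0)
    assert set(words) == {"wa", "wb"}
    assert mean == pytest.approx(10.0)


def test_select_rare_words_entire_pool():
    total = 1_000_000
    entries = {"w" + c: 10 for c in "abcde"}
    entries["filler"] = total - 50
    table = lx.FrequencyTable(entries=entries, total_tokens=total)
    words, mean = lx.select_rare_words(table, n=5, seed=1)
    assert sorted(words) == sorted("w" + c for c in "abcde")
    assert mean == pytest.approx(10.0)


def test_select_rare_words_pool_too_small():
    table = lx.FrequencyTable(entries={"a": 10, "filler": 999_990}, total_tokens=1_000_000)
    with pytest.raises(ValueError, match="pool has 1"):
        lx.select_rare_words(table, n=5, seed=0)


def test_select_rare_words_unreachable_mean():
    total = 1_000_000
    entries = {"w" + c: 20 for c in "abcdefghij"}  # all at pm=20, mean can't reach 13
    entries["filler"] = total - 200
    table = lx.FrequencyTable(entries=entries, total_tokens=total)
    with pytest.raises(RuntimeError, match="resamples"):
        lx.select_rare_words(table, n=5, seed=0, max_resamples=10)


def test_select_rare_words_on_fixture(freq_table):
    """Default selection on the fixture corpus hits the target band and mean."""
    words, mean = lx.select_rare_words(freq_table, n=60, seed=4)
    assert len(set(words)) == 60
    assert all(5 <= freq_table.per_million(w) <= 20 for w in words)
    assert 7 <= mean <= 13
    again, _ = lx.select_rare_words(freq_table, n=60, seed=4)
    assert words == again  # seeded determinism


def test_select_respects_exclusions(freq_table):
    words, _ = lx.select_rare_words(freq_table, n=30, seed=2)
    banned = set(words[:10])
    words2, _ = lx.select_rare_words(freq_table, n=30, seed=2, exclude=banned)
    assert not banned & set(words2)
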