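"""Psychometric scoring: accuracy, consistency, reliability, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lexdec as lx


def _responses(answers, participant="p1", presentation=1):
    """answers: list of (item_id, response)."""
    return pd.DataFrame(
        {
            "participant_id": participant,
            "item_id": [a[0] for a in answers],
            "presentation_index": presentation,
            "response": [a[1] for a in answers],
            "rt_ms": np.nan,
        }
    )


def _key(labels):
    return lx.AnswerKey(labels=labels)


# ---------------------------------------------------------------- accuracy

def test_all_correct_accuracy_and_ci():
    key = _key({"a": "word", "b": "pseudoword"})
    resp = _responses([("a", "word"), ("b", "pseudoword")])
    acc, (lo, hi) = lx.score_accuracy(resp, key, bootstrap_n=200, seed=0)
    assert acc == 1.0 and lo == 1.0 and hi == 1.0


def test_half_correct():
    key = _key({"a": "word", "b": "pseudoword"})
    resp = _responses([("a", "word"), ("b", "word")])
    acc, _ = lx.score_accuracy(resp, key, bootstrap_n=50, seed=0)
    assert acc == 0.5


def test_unknown_item_rejected():
    key = _key({"a": "word"})
    with pytest.raises(ValueError, match="unknown item_id"):
        lx.score_accuracy(_responses([("zz", "word")]), key)


def test_accuracy_within_binomial_oracle():
    """A p=0.8 responder on 60 items lands in the exact binomial 99% interval."""
    p, n = 0.8, 60
    key = _key({f"i{j}": ("word" if j % 2 else "pseudoword") for j in range(n)})
    rng = np.random.default_rng(5)
    answers = [
        (f"i{j}", key.labels[f"i{j}"] if rng.random() < p
         else ("word" if key.labels[f"i{j}"] == "pseudoword" else "pseudoword"))
        for j in range(n)
    ]
    acc, _ = lx.score_accuracy(_responses(answers), key, bootstrap_n=100, seed=0)
    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    assert lo <= acc <= hi


def test_bootstrap_reproducible():
    key = _key({f"i{j}": "word" for j in range(20)})
    answers = [(f"i{j}", "word" if j < 15 else "pseudoword") for j in range(20)]
    r1 = lx.score_accuracy(_responses(answers), key, bootstrap_n=500, seed=7)
    r2 = lx.score_accuracy(_responses(answers), key, bootstrap_n=500, seed=7)
    assert r1 == r2


def test_balanced_accuracy_differs_when_classes_unbalanced():
    key = _key({"a": "word", "b": "word", "c": "pseudoword"})
    resp = _responses([("a", "word"), ("b", "word"), ("c", "word")])
    assert lx.score_accuracy(resp, key, bootstrap_n=10, seed=0)[0] == pytest.approx(2 / 3)
    assert lx.balanced_accuracy(resp, key) == pytest.approx(0.5)


# ------------------------------------------------------------- consistency

def test_consistency_deterministic_responder_is_one():
    first = _responses([("a", "word"), ("b", "word")], presentation=1)
    second = _responses([("a", "word"), ("b", "word")], presentation=2)
    df = pd.concat([first, second])
    assert lx.repetition_consistency(df) == 1.0


def test_consistency_single_item_answered_differently():
    df = pd.concat(
        [
            _responses([("a", "word")], presentation=1),
            _responses([("a", "pseudoword")], presentation=2),
        ]
    )
    assert lx.repetition_consistency(df) == 0.0


def test_consistency_requires_repeats():
    with pytest.raises(ValueError, match="repeated"):
        lx.repetition_consistency(_responses([("a", "word")]))


def test_independent_responder_consistency_closed_form():
    """Independent responses with correctness p agree with rate p² + (1−p)²."""
    p = 0.9
    n_items = 4000
    rng = np.random.default_rng(11)
    rows = []
    for j in range(n_items):
        for pres in (1, 2):
            correct = rng.random() < p
            rows.append(("i%d" % j, "word" if correct else "pseudoword", pres))
    df = pd.DataFrame(
        {
            "participant_id": "p1",
            "item_id": [r[0] for r in rows],
            "presentation_index": [r[2] for r in rows],
            "response": [r[1] for r in rows],
            "rt_ms": np.nan,
        }
    )
    expected = p**2 + (1 - p) ** 2  # 0.82
    assert lx.repetition_consistency(df) == pytest.approx(expected, abs=0.03)


# ------------------------------------------------------------- test-retest

def test_retest_identical_vectors():
    x = [0.5, 0.6, 0.9, 0.3]
    r, _ = lx.test_retest(x, x, bootstrap_n=50, seed=0)
    assert r == pytest.approx(1.0)


def test_retest_exact_negation():
    x = np.array([0.1, 0.5, 0.9, 0.4])
    y = 2 * x.mean() - x
    r, _ = lx.test_retest(x, y, bootstrap_n=50, seed=0)
    assert r == pytest.approx(-1.0)


def test_retest_degenerate_scores_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        lx.test_retest([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


def test_retest_recovers_population_correlation():
    """r̂ within ±0.08 of ρ=0.8 at n=200 in ≥95% of seeded replicates."""
    rho, n, reps = 0.8, 200, 200
    cov = [[1, rho], [rho, 1]]
    hits = 0
    rng = np.random.default_rng(2024)
    for _ in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r, _ = lx.test_retest(xy[:, 0], xy[:, 1], bootstrap_n=0)
        hits += abs(r - rho) <= 0.08
    assert hits / reps >= 0.95


# ----------------------------------------------------------- group contrasts

def test_cohens_d_trivia():
    assert lx.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
    a = [0.0, 2.0]  # sd exactly sqrt(2)... use matched spread groups instead
    x = [0, 1, 2]
    y = [1, 2, 3]
    # means 1 apart, both groups sd = 1
    assert lx.cohens_d(y, x) == pytest.approx(1.0)


def test_cohens_d_simulation_recovery():
    rng = np.random.default_rng(3)
    a = rng.normal(2.0, 1.0, 200)
    b = rng.normal(0.0, 1.0, 200)
    assert lx.cohens_d(a, b) == pytest.approx(2.0, abs=0.25)


def test_cohens_d_zero_sd_rejected():
    with pytest.raises(ValueError, match="pooled"):
        lx.cohens_d([1, 1], [1, 1])


def test_wilcoxon_identical_vectors_rejected():
    with pytest.raises(ValueError, match="zero"):
        lx.paired_wilcoxon([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])


def test_wilcoxon_exact_p_six_positive_differences():
    """All-positive differences, n=6: one-sided exact p = 2⁻⁶ = 1/64."""
    a = [10, 20, 30, 40, 50, 60]
    b = [9, 18, 27, 36, 45, 54]
    _, p = lx.paired_wilcoxon(a, b, alternative="greater")
    assert p == pytest.approx(1 / 64)


def test_wilcoxon_direction_symmetry():
    rng = np.random.default_rng(4)
    a = rng.normal(1, 1, 30)
    b = rng.normal(0, 1, 30)
    _, p_ab = lx.paired_wilcoxon(a, b, alternative="greater")
    _, p_ba = lx.paired_wilcoxon(b, a, alternative="less")
    assert p_ab == pytest.approx(p_ba)


# ------------------------------------------------------------- full report

def test_chance_level_of_random_responder(build_result):
    """A coin-flipping responder scores ~50% on the balanced test."""
    spec, key = build_result.spec, build_result.key
    profile = lx.ResponderProfile(
        participant_id="rand", p_correct_real=0.5, p_correct_pseudo=0.5
    )
    df = lx.simulate_responses(spec, key, [profile], seed=21)
    acc, _ = lx.score_accuracy(df, key, bootstrap_n=50, seed=0)
    n = len(df)
    lo = stats.binom.ppf(0.005, n, 0.5) / n
    hi = stats.binom.ppf(0.995, n, 0.5) / n
    assert lo <= acc <= hi


def test_score_responses_report(build_result):
    spec, key = build_result.spec, build_result.key
    profiles = [
        lx.ResponderProfile(participant_id=f"p{i}", p_correct_real=0.9,
                            p_correct_pseudo=0.85)
        for i in range(8)
    ]
    df = lx.simulate_responses(spec, key, profiles, seed=6)
    report = lx.score_responses(spec, key, df, bootstrap_n=100, seed=1)
    per = report.per_participant
    assert len(per) == 16  # 8 participants × 2 blocks
    assert per["accuracy"].between(0, 1).all()
    assert (per["accuracy_ci_low"] <= per["accuracy_ci_high"]).all()
    assert report.test_retest_r is None or -1 <= report.test_retest_r <= 1


def test_responses_csv_round_trip(tmp_path, build_result):
    spec, key = build_result.spec, build_result.key
    df = lx.simulate_responses(
        spec, key, [lx.ResponderProfile(participant_id="p0")], seed=2
    )
    path = tmp_path / "responses.csv"
    lx.scoring.write_responses(df, path)
    back = lx.read_responses(path)
    assert len(back) == len(df)
    assert (back["response"] == df["response"].values).all()
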