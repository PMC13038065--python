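"""Psychometric scoring of lexical-decision responses.

Scores response tables against an answer key: per-participant accuracy
with percentile-bootstrap confidence intervals, item-repetition
consistency (the fraction of twice-shown items answered the same way
both times), test–retest reliability (the Pearson correlation of
scores across two parallel blocks), and the usual group-contrast
statistics (Cohen's d, paired Wilcoxon signed-rank).

Accuracy and consistency are deliberately distinct: a participant who
always answers "word" is perfectly consistent and at chance accuracy
on a balanced test, so consistency measures response reliability
without needing the answer key at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .testkit import AnswerKey, TestSpec

__all__ = [
    "RESPONSE_COLUMNS",
    "read_responses",
    "write_responses",
    "score_accuracy",
    "balanced_accuracy",
    "repetition_consistency",
    "test_retest",
    "cohens_d",
    "paired_wilcoxon",
    "ScoreReport",
    "score_responses",
]

RESPONSE_COLUMNS = ["participant_id", "item_id", "presentation_index", "response", "rt_ms"]
_VALID_RESPONSES = {"word", "pseudoword"}


def read_responses(source: str | Path) -> pd.DataFrame:
    """Read a responses CSV (``rt_ms`` may be empty) and validate it."""
    df = pd.read_csv(source, dtype={"participant_id": str, "item_id": str})
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"responses CSV missing columns: {sorted(missing)}")
    bad = set(df["response"].unique()) - _VALID_RESPONSES
    if bad:
        raise ValueError(f"invalid response labels: {sorted(bad)}")
    if not df["presentation_index"].isin([1, 2]).all():
        raise ValueError("presentation_index must be 1 or 2")
    dup = df.duplicated(["participant_id", "item_id", "presentation_index"])
    if dup.any():
        raise ValueError("duplicate (participant, item, presentation) rows")
    return df


def write_responses(df: pd.DataFrame, destination: str | Path) -> None:
    df.to_csv(destination, index=False, columns=RESPONSE_COLUMNS)


def _correct_vector(responses: pd.DataFrame, key: AnswerKey) -> np.ndarray:
    unknown = set(responses["item_id"]) - set(key.labels)
    if unknown:
        raise ValueError(f"responses reference unknown item_ids: {sorted(unknown)[:5]}")
    truth = responses["item_id"].map(key.labels)
    return (responses["response"] == truth).to_numpy()


def score_accuracy(
    responses: pd.DataFrame,
    key: AnswerKey,
    bootstrap_n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Accuracy with a 95% percentile-bootstrap confidence interval.

    Accuracy is the fraction of responses matching the key; the CI is
    the 2.5th/97.5th percentile of accuracies over ``bootstrap_n``
    seeded resamples of the response rows.
    """
    correct = _correct_vector(responses, key)
    if len(correct) == 0:
        raise ValueError("no responses to score")
    acc = float(correct.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(correct), size=(bootstrap_n, len(correct)))
    boot = correct[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return acc, (float(lo), float(hi))


def balanced_accuracy(responses: pd.DataFrame, key: AnswerKey) -> float:
    """Mean of real-word and pseudoword accuracies.

    Differs from raw accuracy when the design or the response counts
    are unbalanced across the two item classes.
    """
    correct = _correct_vector(responses, key)
    truth = responses["item_id"].map(key.labels).to_numpy()
    accs = []
    for label in ("word", "pseudoword"):
        mask = truth == label
        if mask.any():
            accs.append(correct[mask].mean())
    if not accs:
        raise ValueError("no responses to score")
    return float(np.mean(accs))


def repetition_consistency(responses: pd.DataFrame) -> float:
    """Fraction of twice-presented items answered identically both times."""
    wide = responses.pivot_table(
        index=["participant_id", "item_id"],
        columns="presentation_index",
        values="response",
        aggfunc="first",
    )
    if 1 not in wide.columns or 2 not in wide.columns:
        raise ValueError("no repeated items in responses")
    both = wide.dropna(subset=[1, 2])
    if both.empty:
        raise ValueError("no repeated items in responses")
    return float((both[1] == both[2]).mean())


def test_retest(
    scores_block1: Sequence[float],
    scores_block2: Sequence[float],
    bootstrap_n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation between paired block scores, with bootstrap CI.

    The CI resamples participants (pairs) with replacement,
    ``bootstrap_n`` times, and takes the 2.5th/97.5th percentiles.
    """
    a = np.asarray(scores_block1, dtype=float)
    b = np.asarray(scores_block2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be paired 1-D arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 paired scores")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate scores: zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    if bootstrap_n <= 0:
        return r, (float("nan"), float("nan"))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(a)
    idx = rng.integers(0, n, size=(bootstrap_n, n))
    ar, br = a[idx], b[idx]
    ac = ar - ar.mean(axis=1, keepdims=True)
    bc = br - br.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = (ac * bc).sum(axis=1) / denom
    boot = boot[np.isfinite(boot)]  # degenerate resamples carry no information
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return r, (float(lo), float(hi))


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference with pooled (n−1) standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def paired_wilcoxon(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; with 25 or fewer untied informative
    pairs the exact null distribution is used, otherwise the normal
    approximation with continuity correction.  Ties in the absolute
    differences take average ranks (which forces the approximation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    if len(d) < 5:
        raise ValueError("need at least 5 nonzero differences")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, method=method, correction=(method == "approx"),
        zero_method="wilcox",
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScoreReport:
    """Scores of a cohort on one test.

    ``per_participant`` has one row per participant × block with
    accuracy, balanced accuracy, and (when the design repeats items)
    consistency; cohort-level statistics are attached as computed.
    """

    per_participant: pd.DataFrame
    test_retest_r: float | None = None
    test_retest_ci: tuple[float, float] | None = None
    cohort: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        doc = {
            "per_participant": self.per_participant.to_dict(orient="records"),
            "test_retest_r": self.test_retest_r,
            "test_retest_ci": list(self.test_retest_ci) if self.test_retest_ci else None,
        }
        doc.update(self.cohort)
        return doc


def score_responses(
    spec: TestSpec,
    key: AnswerKey,
    responses: pd.DataFrame,
    bootstrap_n: int = 1000,
    seed: int = 0,
) -> ScoreReport:
    """Full scoring pass: per-participant × block scores plus reliability.

    Accuracy uses first presentations only, so the repeat design does
    not double-weight items; consistency uses both presentations.
    Test–retest reliability is computed across the first two blocks
    when both are present for at least 3 participants.
    """
    key.check_against(spec)
    block_of = {
        item.item_id: b for b, block in enumerate(spec.blocks) for item in block
    }
    df = responses.copy()
    df["block"] = df["item_id"].map(block_of)
    if df["block"].isna().any():
        raise ValueError("responses reference item_ids outside the test")
    first = df[df["presentation_index"] == 1]
    has_repeats = (df["presentation_index"] == 2).any()

    rows = []
    rng = np.random.default_rng(seed)
    for (pid, block), grp in first.groupby(["participant_id", "block"], sort=True):
        acc, ci = score_accuracy(grp, key, bootstrap_n=bootstrap_n, seed=rng)
        row = {
            "participant_id": pid,
            "block": int(block),
            "n_items": len(grp),
            "accuracy": acc,
            "accuracy_ci_low": ci[0],
            "accuracy_ci_high": ci[1],
            "balanced_accuracy": balanced_accuracy(grp, key),
        }
        if has_repeats:
            sub = df[(df["participant_id"] == pid) & (df["block"] == block)]
            try:
                row["consistency"] = repetition_consistency(sub)
            except ValueError:
                row["consistency"] = float("nan")
        rows.append(row)
    per_participant = pd.DataFrame(rows)

    report = ScoreReport(per_participant=per_participant)
    if len(spec.blocks) >= 2 and not per_participant.empty:
        wide = per_participant.pivot_table(
            index="participant_id", columns="block", values="accuracy"
        )
        if 0 in wide.columns and 1 in wide.columns:
            both = wide.dropna(subset=[0, 1])
            if len(both) >= 3 and both[0].std() > 0 and both[1].std() > 0:
                r, ci = test_retest(
                    both[0].to_numpy(), both[1].to_numpy(),
                    bootstrap_n=bootstrap_n, seed=rng,
                )
                report.test_retest_r = r
                report.test_retest_ci = ci
    return report
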