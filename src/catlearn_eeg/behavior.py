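"""Behavioral analyses: learning curves, the consecutive-correct learning
criterion, confusion matrices, condition contrasts, and generalization.

The learning criterion is the fixed-number-of-consecutive-correct-responses
(FCCR) rule: a stimulus counts as learned at the earliest presentation that
completes a run of ``k`` (default 4) consecutive correct responses.  Trials
at/after a stimulus's criterion are its "post-learning" trials.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CATEGORIES, DISTINCT_CATEGORY, SIMILAR_CATEGORIES
from .stats import TTestResult, binomial_test, paired_t

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "phase", "block", "trial", "stimulus_id",
                    "category", "response", "correct")


def _check_table(b: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in b.columns]
    if missing:
        raise ValueError(f"Behavior table missing columns {missing}")


def _training(b: pd.DataFrame) -> pd.DataFrame:
    return b[b["phase"] == "training"]


def learning_curves(b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy per subject × training block × category, plus group summary.

    Cells with no trials are reported as missing (NaN), never as 0.  The
    group table carries the across-subject mean and standard error per
    block × category.
    """
    _check_table(b)
    t = _training(b)
    grouped = t.groupby(["subject", "block", "category"])["correct"]
    cells = grouped.agg(n_trials="size", n_correct="sum").reset_index()
    cells["accuracy"] = cells["n_correct"] / cells["n_trials"]

    subjects = sorted(b["subject"].unique())
    blocks = sorted(t["block"].unique())
    grid = pd.MultiIndex.from_product([subjects, blocks, list(CATEGORIES)],
                                      names=["subject", "block", "category"])
    per_subject = (cells.set_index(["subject", "block", "category"])
                   .reindex(grid).reset_index())

    group = (per_subject.groupby(["block", "category"])["accuracy"]
             .agg(mean_accuracy="mean",
                  se_accuracy=lambda a: a.std(ddof=1) / np.sqrt(a.notna().sum())
                  if a.notna().sum() > 1 else np.nan,
                  n_subjects=lambda a: a.notna().sum())
             .reset_index())
    return per_subject, group


def _run_values(sub: pd.DataFrame, nonresponse_breaks_run: bool) -> np.ndarray:
    """Per-presentation values feeding the FCCR run: 1 counts toward the run."""
    correct = sub["correct"].to_numpy(dtype=bool)
    nonresponse = sub["response"].isna().to_numpy()
    values = correct.copy()
    if not nonresponse_breaks_run:
        # the criterion's parenthetical: a non-response does not break a run
        values |= nonresponse
    else:
        values &= ~nonresponse
    return values


def fccr_learning_points(b: pd.DataFrame, k: int = 4,
                         nonresponse_breaks_run: bool = True) -> pd.DataFrame:
    """Earliest presentation completing ``k`` consecutive correct responses.

    One row per subject × stimulus, with the 1-based training presentation
    index at which the criterion run completes (NaN when the stimulus never
    reaches criterion).  Only training trials count toward the criterion.
    """
    _check_table(b)
    if k < 1:
        raise ValueError(f"FCCR run length k must be >= 1, got {k}")
    rows = []
    t = _training(b).sort_values(["subject", "block", "trial"], kind="stable")
    for (subject, stimulus), sub in t.groupby(["subject", "stimulus_id"], sort=True):
        values = _run_values(sub, nonresponse_breaks_run)
        criterion = np.nan
        run = 0
        for i, v in enumerate(values):
            run = run + 1 if v else 0
            if run >= k:
                criterion = i + 1  # 1-based presentation index
                break
        rows.append({"subject": subject, "stimulus_id": stimulus,
                     "criterion_presentation": criterion})
    return pd.DataFrame(rows)


def mark_post_learning(b: pd.DataFrame, k: int = 4,
                       nonresponse_breaks_run: bool = True) -> pd.Series:
    """Boolean per-row flag: training trial at/after its stimulus's criterion.

    The criterion-completing presentation itself counts as post-learning.
    Stimuli that never reach criterion contribute no post-learning trials
    (logged); generalization trials are never flagged.
    """
    _check_table(b)
    points = fccr_learning_points(b, k, nonresponse_breaks_run)
    lookup = {(row.subject, row.stimulus_id): row.criterion_presentation
              for row in points.itertuples()}
    never = points["criterion_presentation"].isna().sum()
    if never:
        logger.info("%d subject × stimulus series never reached the learning "
                    "criterion; their trials are excluded from post-learning "
                    "averages", int(never))
    flag = np.zeros(len(b), dtype=bool)
    t = _training(b).sort_values(["subject", "block", "trial"], kind="stable")
    for (subject, stimulus), sub in t.groupby(["subject", "stimulus_id"], sort=True):
        criterion = lookup.get((subject, stimulus), np.nan)
        if np.isnan(criterion):
            continue
        presentation = np.arange(1, len(sub) + 1)
        flag[sub.index[presentation >= criterion]] = True
    return pd.Series(flag, index=b.index, name="post_learning")


def confusion_matrix(b: pd.DataFrame, block: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3×3 response counts (rows: true category) plus row-normalized rates.

    Non-responses are excluded from the counts.  Row sums equal the number of
    responded trials of that category (in the selected block, if given).
    """
    _check_table(b)
    sub = b if block is None else b[b["block"] == block]
    sub = sub[sub["response"].notna()]
    counts = pd.crosstab(sub["category"], sub["response"]).reindex(
        index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0)
    counts.index.name = "true_category"
    counts.columns.name = "response"
    row_sums = counts.sum(axis=1)
    proportions = counts.div(row_sums.replace(0, np.nan), axis=0)
    return counts, proportions


def per_subject_accuracy(b: pd.DataFrame, weighting: str = "trial") -> pd.DataFrame:
    """Per-subject training accuracy for the distinct vs pooled-similar contrast.

    ``weighting='trial'`` averages over trials within each category;
    ``'block'`` first computes per-block accuracies and averages those.  The
    pooled similar score is the mean of the two similar categories' scores.
    """
    _check_table(b)
    if weighting not in ("trial", "block"):
        raise ValueError("weighting must be 'trial' or 'block'")
    t = _training(b)
    if weighting == "trial":
        acc = (t.groupby(["subject", "category"])["correct"].mean()
               .unstack("category"))
    else:
        acc = (t.groupby(["subject", "category", "block"])["correct"].mean()
               .groupby(["subject", "category"]).mean().unstack("category"))
    out = pd.DataFrame({
        "distinct": acc[DISTINCT_CATEGORY],
        "similar": acc[list(SIMILAR_CATEGORIES)].mean(axis=1),
        "overall": t.groupby("subject")["correct"].mean(),
    })
    out.index.name = "subject"
    return out.reset_index()


def condition_contrast(b: pd.DataFrame, weighting: str = "trial") -> TTestResult:
    """Paired t-test of per-subject accuracy, distinct vs pooled similar."""
    acc = per_subject_accuracy(b, weighting)
    return paired_t(acc["distinct"], acc["similar"])


def generalization_summary(b: pd.DataFrame, chance: float = 1.0 / 3.0
                           ) -> pd.DataFrame:
    """Accuracy by old/novel × category in the generalization block.

    Each cell carries trial counts, accuracy, and an exact two-sided binomial
    p-value against chance (1/3 for three response options).  An ``all``
    category row pools the three categories within each old/novel group.
    """
    _check_table(b)
    g = b[b["phase"] == "generalization"]
    rows = []
    for novel, label in ((False, "old"), (True, "novel")):
        sub = g[g["novel"] == novel]
        groups = [(cat, sub[sub["category"] == cat]) for cat in CATEGORIES]
        groups.append(("all", sub))
        for cat, cell in groups:
            n = len(cell)
            if n == 0:
                rows.append({"stimulus_type": label, "category": cat, "n_trials": 0,
                             "n_correct": 0, "accuracy": np.nan, "p_vs_chance": np.nan})
                continue
            k = int(cell["correct"].sum())
            rows.append({"stimulus_type": label, "category": cat, "n_trials": n,
                         "n_correct": k, "accuracy": k / n,
                         "p_vs_chance": binomial_test(k, n, chance)})
    return pd.DataFrame(rows)
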