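"""Behavioral analyses: learning curves, FCCR criterion, confusion matrices,
condition contrast, generalization."""

import math

import numpy as np
import pandas as pd
import pytest

from catlearn_eeg import behavior as beh
from catlearn_eeg.config import CATEGORIES
from catlearn_eeg.stats import paired_t


def _table_from_sequence(responses, category="distinct", stimulus="distinct/old1",
                         subject="s00"):
    """One subject, one stimulus, one presentation per trial."""
    rows = []
    for i, resp in enumerate(responses):
        rows.append({"subject": subject, "phase": "training", "block": 1,
                     "trial": i + 1, "stimulus_id": stimulus,
                     "category": category, "response": resp,
                     "correct": resp == category})
    return pd.DataFrame(rows)


def _fccr_oracle(values, k):
    """Brute-force scan of all k-windows for the earliest all-correct run."""
    for end in range(k, len(values) + 1):
        if all(values[end - k:end]):
            return end
    return np.nan


class TestLearningCurves:
    def test_cell_accuracy(self):
        responses = ["distinct"] * 9 + ["similar_1"]
        table = _table_from_sequence(responses)
        per_subject, _ = beh.learning_curves(table)
        cell = per_subject[(per_subject["category"] == "distinct")
                           & (per_subject["block"] == 1)]
        assert cell["accuracy"].iloc[0] == pytest.approx(0.9)

    def test_all_correct_cells_are_one(self):
        table = _table_from_sequence(["distinct"] * 10)
        per_subject, group = beh.learning_curves(table)
        observed = per_subject.dropna(subset=["accuracy"])
        assert (observed["accuracy"] == 1.0).all()

    def test_empty_cells_are_missing_not_zero(self):
        table = _table_from_sequence(["distinct"] * 4)
        per_subject, _ = beh.learning_curves(table)
        empty = per_subject[per_subject["category"] == "similar_1"]
        assert empty["accuracy"].isna().all()
        assert not (per_subject["accuracy"] == 0).any()

    def test_invariant_to_trial_order_within_block(self, rng):
        responses = ["distinct"] * 6 + ["similar_1"] * 4
        table = _table_from_sequence(responses)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["trial"] = np.arange(1, len(shuffled) + 1)
        a, _ = beh.learning_curves(table)
        b, _ = beh.learning_curves(shuffled)
        assert a.equals(b)


class TestFccr:
    def test_immediate_run(self):
        table = _table_from_sequence(["distinct"] * 4)
        points = beh.fccr_learning_points(table)
        assert points["criterion_presentation"].iloc[0] == 4

    def test_broken_then_completed_run(self):
        seq = ["distinct", "distinct", "similar_1", "distinct", "distinct",
               "distinct", "distinct"]
        points = beh.fccr_learning_points(_table_from_sequence(seq))
        assert points["criterion_presentation"].iloc[0] == 7

    def test_no_run_gives_missing(self):
        seq = ["distinct", "distinct", "distinct", "similar_1"] * 3
        points = beh.fccr_learning_points(_table_from_sequence(seq))
        assert np.isnan(points["criterion_presentation"].iloc[0])

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            beh.fccr_learning_points(_table_from_sequence(["distinct"] * 4), k=0)

    def test_oracle_equivalence_on_random_sequences(self, rng):
        """FCCR matches a brute-force window scan on 10,000 random series."""
        frames = []
        expected = {}
        for i in range(10_000):
            length = int(rng.integers(1, 81))
            p = rng.random()
            correct = rng.random(length) < p
            responses = np.where(correct, "distinct", "similar_1")
            stimulus = f"stim{i}"
            frames.append(pd.DataFrame({
                "subject": "s00", "phase": "training", "block": 1,
                "trial": np.arange(1, length + 1), "stimulus_id": stimulus,
                "category": "distinct", "response": responses,
                "correct": correct}))
            expected[stimulus] = _fccr_oracle(correct.tolist(), 4)
        table = pd.concat(frames, ignore_index=True)
        points = beh.fccr_learning_points(table, k=4)
        for row in points.itertuples():
            want = expected[row.stimulus_id]
            got = row.criterion_presentation
            assert (np.isnan(want) and np.isnan(got)) or want == got

    def test_nonresponse_run_handling(self):
        seq = ["distinct", "distinct", None, "distinct", "distinct", "distinct",
               "distinct"]
        table = _table_from_sequence(seq)
        table.loc[table["response"].isna(), "correct"] = False
        breaks = beh.fccr_learning_points(table, nonresponse_breaks_run=True)
        keeps = beh.fccr_learning_points(table, nonresponse_breaks_run=False)
        assert breaks["criterion_presentation"].iloc[0] == 7
        # the criterion's parenthetical: non-responses count toward the run
        assert keeps["criterion_presentation"].iloc[0] == 4

    def test_post_learning_includes_criterion_trial(self):
        seq = ["similar_1", "distinct", "distinct", "distinct", "distinct",
               "distinct"]
        table = _table_from_sequence(seq)
        flags = beh.mark_post_learning(table)
        assert flags.tolist() == [False, False, False, False, True, True]


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        rows = []
        for trial, cat in enumerate(CATEGORIES * 5, start=1):
            rows.append({"subject": "s00", "phase": "training", "block": 1,
                         "trial": trial, "stimulus_id": f"{cat}/old1",
                         "category": cat, "response": cat, "correct": True})
        counts, props = beh.confusion_matrix(pd.DataFrame(rows))
        assert np.allclose(np.diag(counts), 5)
        assert counts.to_numpy().sum() == 15
        assert np.allclose(np.diag(props), 1.0)

    def test_single_error_cell(self):
        table = _table_from_sequence(["similar_2"], category="similar_1",
                                     stimulus="similar_1/old1")
        counts, _ = beh.confusion_matrix(table)
        assert counts.loc["similar_1", "similar_2"] == 1
        assert counts.to_numpy().sum() == 1

    def test_counts_conserve_trials_per_block(self, rng):
        rows = []
        for trial in range(200):
            cat = CATEGORIES[rng.integers(3)]
            resp = CATEGORIES[rng.integers(3)]
            rows.append({"subject": "s00", "phase": "training",
                         "block": 1 + trial % 2, "trial": trial,
                         "stimulus_id": f"{cat}/old1", "category": cat,
                         "response": resp, "correct": cat == resp})
        table = pd.DataFrame(rows)
        for block in (1, 2):
            counts, _ = beh.confusion_matrix(table, block=block)
            assert counts.to_numpy().sum() == (table["block"] == block).sum()


class TestConditionContrast:
    def _multi_subject_table(self, accuracies):
        """accuracies: subject -> {category: fraction correct of 10 trials}."""
        rows = []
        for subject, accs in accuracies.items():
            trial = 0
            for cat, acc in accs.items():
                n_correct = int(round(acc * 10))
                for i in range(10):
                    trial += 1
                    correct = i < n_correct
                    rows.append({"subject": subject, "phase": "training",
                                 "block": 1, "trial": trial,
                                 "stimulus_id": f"{cat}/old1", "category": cat,
                                 "response": cat if correct else "none_cat",
                                 "correct": correct})
        return pd.DataFrame(rows)

    def test_identical_accuracies_give_t_zero(self):
        table = self._multi_subject_table({
            s: {"distinct": 0.8, "similar_1": 0.8, "similar_2": 0.8}
            for s in ("s00", "s01", "s02")})
        result = beh.condition_contrast(table)
        assert result.t == 0.0 and result.p == 1.0

    def test_constant_shift_reports_infinite_t(self):
        table = self._multi_subject_table({
            s: {"distinct": 0.9, "similar_1": 0.7, "similar_2": 0.7}
            for s in ("s00", "s01", "s02")})
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            result = beh.condition_contrast(table)
        assert np.isinf(result.t) and result.t > 0
        assert result.p == 0.0

    def test_five_subject_closed_form(self):
        distinct = np.array([0.9, 1.0, 0.8, 0.9, 1.0])
        similar = np.array([0.8, 0.8, 0.7, 0.9, 0.8])
        table = self._multi_subject_table({
            f"s{i:02d}": {"distinct": d, "similar_1": s, "similar_2": s}
            for i, (d, s) in enumerate(zip(distinct, similar))})
        result = beh.condition_contrast(table)
        diffs = distinct - similar
        t_manual = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(5))
        assert result.t == pytest.approx(t_manual)
        assert result.df == 4


class TestGeneralization:
    def _gen_table(self, n, k, novel=True, category="similar_1"):
        rows = []
        for i in range(n):
            correct = i < k
            rows.append({"subject": "s00", "phase": "generalization", "block": 9,
                         "trial": i + 1, "stimulus_id": f"{category}/x",
                         "category": category,
                         "response": category if correct else "distinct",
                         "correct": correct, "novel": novel})
        return pd.DataFrame(rows)

    def test_all_correct_novel_cell(self):
        summary = beh.generalization_summary(self._gen_table(15, 15))
        cell = summary[(summary["stimulus_type"] == "novel")
                       & (summary["category"] == "similar_1")]
        assert cell["accuracy"].iloc[0] == 1.0

    def test_binomial_p_matches_enumeration_oracle(self):
        summary = beh.generalization_summary(self._gen_table(100, 92))
        cell = summary[(summary["stimulus_type"] == "novel")
                       & (summary["category"] == "similar_1")]
        p_pkg = cell["p_vs_chance"].iloc[0]
        # exact two-sided binomial: sum of outcome probabilities <= P(X=92)
        n, k, p0 = 100, 92, 1 / 3
        pmf = [math.comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
               for j in range(n + 1)]
        p_oracle = sum(q for q in pmf if q <= pmf[k] * (1 + 1e-12))
        assert p_pkg == pytest.approx(p_oracle, rel=1e-9)

    def test_uniform_random_responses_near_chance(self, rng):
        n = 1500
        correct = rng.integers(0, 3, n) == 0
        rows = pd.DataFrame({
            "subject": "s00", "phase": "generalization", "block": 9,
            "trial": np.arange(1, n + 1), "stimulus_id": "similar_1/x",
            "category": "similar_1",
            "response": np.where(correct, "similar_1", "distinct"),
            "correct": correct, "novel": True})
        summary = beh.generalization_summary(rows)
        cell = summary[(summary["stimulus_type"] == "novel")
                       & (summary["category"] == "similar_1")]
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(cell["accuracy"].iloc[0] - 1 / 3) < 3 * se


def test_paired_t_requires_matching_lengths():
    with pytest.raises(ValueError):
        paired_t([1, 2, 3], [1, 2])
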