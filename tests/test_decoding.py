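"""Region averaging, temporal binning, forced-choice LOSO decoding."""

import numpy as np
import pandas as pd
import pytest

from catlearn_eeg.containers import ERPWaveform, epoch_times_ms
from catlearn_eeg.decoding import (DecodingMatrix, TimecourseResult,
                                   behavior_correlation, build_decoding_matrix,
                                   forced_choice, loso_timepoint_decode,
                                   region_average, summarize_timecourse,
                                   temporal_bin)
from catlearn_eeg.montage import Montage

TIMES = epoch_times_ms(250.0)


def _erp(montage, data, condition="distinct", subject="s00"):
    return ERPWaveform(data=data, times_ms=TIMES, condition=condition,
                       n_trials_averaged=5, sampling_rate=250.0,
                       channel_labels=list(montage.channel_labels),
                       subject_id=subject)


class TestRegionAverage:
    def test_balanced_pair_averages_to_zero(self):
        montage = Montage(channel_labels=["a", "b"], clusters={},
                          regions={"left_frontal": ["a", "b"]})
        data = np.stack([np.ones(len(TIMES)), -np.ones(len(TIMES))])
        assert np.allclose(region_average(_erp(montage, data), montage), 0.0)

    def test_single_channel_region_passthrough(self, rng):
        montage = Montage(channel_labels=["a"], clusters={},
                          regions={"left_frontal": ["a"]})
        data = rng.standard_normal((1, len(TIMES)))
        assert np.allclose(region_average(_erp(montage, data), montage), data)

    def test_matches_brute_force_and_region_order(self, montage64, rng):
        data = rng.standard_normal((montage64.n_channels, len(TIMES)))
        matrix = region_average(_erp(montage64, data), montage64)
        for row, region in enumerate(montage64.region_names):
            idx = montage64.region_indices(region)
            assert np.allclose(matrix[row], data[idx].mean(axis=0))

    def test_invariant_to_channel_permutation_within_region(self, montage64, rng):
        data = rng.standard_normal((montage64.n_channels, len(TIMES)))
        erp = _erp(montage64, data)
        permuted = data.copy()
        idx = montage64.region_indices("posterior_parietal")
        permuted[idx] = data[np.random.default_rng(0).permutation(idx)]
        assert np.allclose(region_average(erp, montage64),
                           region_average(_erp(montage64, permuted), montage64))


class TestTemporalBin:
    def test_300_samples_give_50_retained_bins(self, rng):
        x = rng.standard_normal((10, 300))
        assert temporal_bin(x).shape == (50, 10)

    def test_constant_waveform_preserved(self):
        assert np.allclose(temporal_bin(np.full((3, 300), 2.5)), 2.5)

    def test_ramp_bins_match_enumeration(self):
        x = np.arange(300.0)[None, :]
        binned = temporal_bin(x)
        brute = np.array([x[0, (10 + i) * 5:(10 + i + 1) * 5].mean()
                          for i in range(50)])
        assert np.allclose(binned[:, 0], brute)

    def test_non_divisible_length_names_remainder(self):
        with pytest.raises(ValueError, match="remainder 2"):
            temporal_bin(np.zeros((2, 302)))

    def test_build_decoding_matrix_metadata(self, montage64, rng):
        erp = _erp(montage64, rng.standard_normal((montage64.n_channels,
                                                   len(TIMES))))
        matrix = build_decoding_matrix(erp, montage64)
        assert matrix.values.shape == (50, 10)
        assert matrix.bin_duration_ms == 20.0
        assert matrix.bin_start_times_ms[0] == 0.0
        assert matrix.bin_start_times_ms[-1] == 980.0


class TestForcedChoice:
    @pytest.mark.parametrize("ev_a,ev_b,a_sim,expected", [
        (0.7, 0.4, True, 1.0),
        (0.4, 0.7, True, 0.0),
        (0.7, 0.4, False, 0.0),
        (0.5, 0.5, True, 0.5),
    ])
    def test_credit(self, ev_a, ev_b, a_sim, expected):
        assert forced_choice(ev_a, ev_b, a_sim) == expected


def _matrices_from_patterns(patterns):
    """patterns: subject -> condition -> (timepoints, features) array."""
    out = {}
    first = next(iter(patterns.values()))["distinct"]
    n_timepoints, n_features = first.shape
    region_names = tuple(["left_frontal", "right_frontal", "medial_prefrontal",
                          "medial_frontal", "posterior_parietal",
                          "left_temporoparietal", "right_temporoparietal",
                          "left_occipital", "right_occipital",
                          "medial_occipital"][:n_features])
    for subject, by_condition in patterns.items():
        out[subject] = {
            condition: DecodingMatrix(
                subject=subject, condition=condition, values=values,
                bin_start_times_ms=np.arange(n_timepoints) * 20.0,
                bin_duration_ms=20.0, region_names=region_names)
            for condition, values in by_condition.items()}
    return out


class TestLosoDecode:
    def test_hand_worked_margin_toy(self):
        """3 subjects, 1 timepoint, 2 features, hand-workable geometry: the
        max-margin separator of the 4 training points {(2,0),(2,1)} vs
        {(0,0),(0,1)} is x₁ = 1 with w = (1, 0), b = −1, so similar evidence
        is x₁ − 1 for every test pattern."""
        from catlearn_eeg.decoding import _fold_evidence

        train_x = np.array([[2.0, 0.0], [2.0, 1.0], [0.0, 0.0], [0.0, 1.0]])
        train_y = np.array([1.0, 1.0, 0.0, 0.0])
        test_x = np.array([[1.5, 0.3], [0.2, 0.9]])
        evidence = _fold_evidence(train_x, train_y, test_x, C=1000.0,
                                  standardize=False)
        assert evidence == pytest.approx([0.5, -0.8], abs=1e-3)
        assert forced_choice(evidence[0], evidence[1], a_is_similar=True) == 1.0
        assert forced_choice(evidence[0], evidence[1], a_is_similar=False) == 0.0

        sim = {"s0": [2.0, 0.0], "s1": [2.0, 1.0], "s2": [2.0, 0.5]}
        dist = {"s0": [0.0, 0.0], "s1": [0.0, 1.0], "s2": [0.0, 0.5]}
        patterns = {s: {"similar_1": np.array([sim[s]]),
                        "similar_2": np.array([sim[s]]),
                        "distinct": np.array([dist[s]])}
                    for s in sim}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = loso_timepoint_decode(_matrices_from_patterns(patterns),
                                           C=1000.0, standardize=False)
        assert result.correctness[:, 0].tolist() == [1.0, 1.0, 1.0]
        assert result.accuracy[0] == 1.0

    def test_pairwise_problems_are_averaged(self):
        """similar_1 separable, similar_2 identical to distinct: per-subject
        credit is (1 + 0.5)/2 and group accuracy equals its mean."""
        rng = np.random.default_rng(3)
        patterns = {}
        for i in range(4):
            base = rng.standard_normal((1, 2)) * 0.1
            patterns[f"s{i}"] = {
                "similar_1": base + np.array([[2.0, 0.0]]),
                "similar_2": base.copy(),
                "distinct": base.copy()}
        result = loso_timepoint_decode(_matrices_from_patterns(patterns),
                                       standardize=False)
        assert np.allclose(result.correctness[:, 0], 0.75)
        assert result.accuracy[0] == pytest.approx(
            result.correctness[:, 0].mean())

    def test_degenerate_training_scores_chance(self):
        patterns = {f"s{i}": {c: np.ones((2, 3))
                              for c in ("similar_1", "similar_2", "distinct")}
                    for i in range(4)}
        with pytest.warns(RuntimeWarning, match="identical training"):
            result = loso_timepoint_decode(_matrices_from_patterns(patterns))
        assert np.allclose(result.accuracy, 0.5)

    def test_requires_three_subjects(self):
        patterns = {f"s{i}": {c: np.zeros((1, 2))
                              for c in ("similar_1", "similar_2", "distinct")}
                    for i in range(2)}
        with pytest.raises(ValueError, match="3 subjects"):
            loso_timepoint_decode(_matrices_from_patterns(patterns))

    def test_monotone_in_effect_size(self):
        """Larger condition gaps never reduce accuracy (±1 SE tolerance)."""
        gaps = [0.0, 0.5, 1.0, 2.0]
        n_subjects, n_seeds = 12, 20
        mean_acc, se_acc = [], []
        for gap in gaps:
            accs = []
            for seed in range(n_seeds):
                rng = np.random.default_rng(1000 + seed)
                patterns = {}
                for i in range(n_subjects):
                    noise = rng.standard_normal((3, 1, 4))
                    offset = np.zeros((1, 4))
                    offset[0, 2] = gap
                    patterns[f"s{i:02d}"] = {
                        "similar_1": noise[0] + offset,
                        "similar_2": noise[1] + offset,
                        "distinct": noise[2]}
                result = loso_timepoint_decode(_matrices_from_patterns(patterns))
                accs.append(result.accuracy[0])
            mean_acc.append(np.mean(accs))
            se_acc.append(np.std(accs, ddof=1) / np.sqrt(n_seeds))
        for lo, hi in zip(range(3), range(1, 4)):
            assert mean_acc[hi] >= mean_acc[lo] - se_acc[lo]
        assert mean_acc[0] < 0.65 and mean_acc[-1] > 0.85


class TestBehaviorCorrelation:
    def _result(self, correctness):
        correctness = np.asarray(correctness, dtype=float)
        n_subjects, n_timepoints = correctness.shape
        return TimecourseResult(
            subjects=tuple(f"s{i}" for i in range(n_subjects)),
            bin_start_times_ms=np.arange(n_timepoints) * 20.0,
            bin_duration_ms=20.0, accuracy=correctness.mean(axis=0),
            correctness=correctness, t=np.zeros(n_timepoints),
            p=np.ones(n_timepoints),
            significant=np.zeros(n_timepoints, dtype=bool), alpha=0.05,
            region=None)

    def test_proportional_gives_r_one(self):
        correctness = np.array([[0.0], [0.5], [1.0], [0.5]])
        behavior = {"s0": 0.2, "s1": 0.4, "s2": 0.6, "s3": 0.4}
        result = behavior_correlation(self._result(correctness), behavior)
        assert result.behavior_r[0] == pytest.approx(1.0)

    def test_zero_variance_is_missing(self):
        correctness = np.array([[1.0], [1.0], [1.0], [1.0]])
        behavior = {"s0": 0.2, "s1": 0.4, "s2": 0.6, "s3": 0.8}
        result = behavior_correlation(self._result(correctness), behavior)
        assert np.isnan(result.behavior_r[0])

    def test_five_point_closed_form(self):
        x = np.array([[0.0], [0.5], [1.0], [0.0], [1.0]])
        y = {"s0": 0.9, "s1": 0.7, "s2": 0.8, "s3": 0.6, "s4": 0.95}
        result = behavior_correlation(self._result(x), y)
        xv = x[:, 0]
        yv = np.array([y[f"s{i}"] for i in range(5)])
        r_manual = (((xv - xv.mean()) * (yv - yv.mean())).sum()
                    / np.sqrt(((xv - xv.mean()) ** 2).sum()
                              * ((yv - yv.mean()) ** 2).sum()))
        assert result.behavior_r[0] == pytest.approx(r_manual)

    def test_null_correlation_small_on_average(self, rng):
        """|r| stays below 3/sqrt(n) on average under independence."""
        n = 24
        magnitudes = []
        for _ in range(200):
            correctness = rng.choice([0.0, 0.5, 1.0], size=(n, 1))
            behavior = {f"s{i}": rng.random() for i in range(n)}
            result = behavior_correlation(self._result(correctness), behavior)
            if not np.isnan(result.behavior_r[0]):
                magnitudes.append(abs(result.behavior_r[0]))
        assert np.mean(magnitudes) < 3 / np.sqrt(n)


class TestSummarizeTimecourse:
    def _result_with_flags(self, flags):
        flags = np.asarray(flags, dtype=bool)
        n = len(flags)
        return TimecourseResult(subjects=("s0", "s1", "s2"),
                                bin_start_times_ms=np.arange(n) * 20.0,
                                bin_duration_ms=20.0, accuracy=np.full(n, 0.5),
                                correctness=np.full((3, n), 0.5),
                                t=np.zeros(n), p=np.ones(n), significant=flags,
                                alpha=0.05, region=None)

    def test_interior_run(self):
        windows = summarize_timecourse(self._result_with_flags([0, 1, 1, 0]))
        assert windows.values.tolist() == [[20.0, 60.0]]

    def test_no_significant_bins(self):
        windows = summarize_timecourse(self._result_with_flags([0, 0, 0]))
        assert len(windows) == 0

    def test_alternating_flags_give_single_bin_windows(self):
        windows = summarize_timecourse(self._result_with_flags([1, 0, 1, 0, 1]))
        assert windows.values.tolist() == [[0.0, 20.0], [40.0, 60.0],
                                           [80.0, 100.0]]

    def test_trailing_run_closed_at_axis_end(self):
        windows = summarize_timecourse(self._result_with_flags([0, 1, 1]))
        assert windows.values.tolist() == [[20.0, 60.0]]
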