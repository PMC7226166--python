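"""Time-resolved leave-one-subject-out decoding of categorization condition.

Per-subject condition ERPs are reduced to 10 region averages, binned into
20 ms timepoints (5 samples at 250 samples/s; the 10 baseline bins are
dropped, leaving 50), and at every timepoint a linear max-margin classifier
is trained across subjects to separate visually-similar from
visually-distinct patterns.  Each held-out subject is scored by forced
choice: of their two test patterns, the one with greater similar-class
evidence (signed distance to the hyperplane, oriented toward the similar
class) is called "similar".  The two pairwise problems (similar-1 vs
distinct, similar-2 vs distinct) are averaged, so per-subject correctness is
0, 0.5, or 1, and group accuracy is tested against the 0.5 chance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import ERPWaveform
from .montage import Montage
from .stats import one_sample_t, pearson_r

logger = logging.getLogger(__name__)

PAIRWISE_PROBLEMS = (("similar_1", "distinct"), ("similar_2", "distinct"))


@dataclass
class DecodingMatrix:
    """One subject × condition pattern: binned timepoints × regions (µV)."""

    subject: str
    condition: str
    values: np.ndarray  # (n_timepoints, n_regions)
    bin_start_times_ms: np.ndarray
    bin_duration_ms: float
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_start_times_ms = np.asarray(self.bin_start_times_ms, dtype=float)
        if self.values.shape != (len(self.bin_start_times_ms),
                                 len(self.region_names)):
            raise ValueError("DecodingMatrix values shape does not match bins × regions")


def region_average(erp: ERPWaveform, montage: Montage) -> np.ndarray:
    """Per-region sample-wise mean voltage: (n_regions, n_samples)."""
    return np.stack([erp.data[montage.region_indices(region)].mean(axis=0)
                     for region in montage.region_names])


def temporal_bin(x: np.ndarray, bin_size: int = 5, drop_baseline_bins: int = 10
                 ) -> np.ndarray:
    """Non-overlapping bin means along time; baseline bins dropped.

    ``x`` is (n_regions, n_samples); the output is (n_bins_retained,
    n_regions).  300 samples → 60 bins → 50 retained with the defaults.
    """
    x = np.asarray(x, dtype=float)
    n_regions, n_samples = x.shape
    remainder = n_samples % bin_size
    if remainder:
        raise ValueError(f"{n_samples} samples are not divisible by the bin size "
                         f"{bin_size} (remainder {remainder})")
    n_bins = n_samples // bin_size
    if drop_baseline_bins >= n_bins:
        raise ValueError(f"cannot drop {drop_baseline_bins} of {n_bins} bins")
    binned = x.reshape(n_regions, n_bins, bin_size).mean(axis=2)
    return binned[:, drop_baseline_bins:].T


def build_decoding_matrix(erp: ERPWaveform, montage: Montage, bin_size: int = 5,
                          drop_baseline_bins: int = 10) -> DecodingMatrix:
    """Region-average then bin one condition ERP into a pattern matrix."""
    values = temporal_bin(region_average(erp, montage), bin_size,
                          drop_baseline_bins)
    bin_ms = bin_size * 1000.0 / erp.sampling_rate
    starts = np.arange(values.shape[0]) * bin_ms
    return DecodingMatrix(subject=erp.subject_id, condition=erp.condition,
                          values=values, bin_start_times_ms=starts,
                          bin_duration_ms=bin_ms,
                          region_names=montage.region_names)


def forced_choice(evidence_a: float, evidence_b: float, a_is_similar: bool
                  ) -> float:
    """Correctness credit for labeling the higher-evidence pattern "similar".

    Returns 1.0 when the truly similar pattern has strictly greater
    similar-class evidence, 0.0 when strictly smaller, 0.5 on an exact tie.
    """
    if evidence_a == evidence_b:
        return 0.5
    return float((evidence_a > evidence_b) == a_is_similar)


@dataclass
class TimecourseResult:
    """Group decoding accuracy and statistics per retained timepoint."""

    subjects: tuple[str, ...]
    bin_start_times_ms: np.ndarray
    bin_duration_ms: float
    accuracy: np.ndarray          # (n_timepoints,) group mean
    correctness: np.ndarray       # (n_subjects, n_timepoints), values {0, .5, 1}
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray       # p < alpha and accuracy above chance
    alpha: float
    region: str | None            # None = whole scalp
    behavior_r: np.ndarray | None = None
    behavior_p: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "region": self.region or "all",
            "bin_start_ms": self.bin_start_times_ms,
            "bin_end_ms": self.bin_start_times_ms + self.bin_duration_ms,
            "accuracy": self.accuracy,
            "t_vs_chance": self.t,
            "p_uncorrected": self.p,
            "significant": self.significant,
        })
        if self.behavior_r is not None:
            frame["behavior_r"] = self.behavior_r
            frame["behavior_p"] = self.behavior_p
        return frame


def _fold_evidence(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
                   C: float, standardize: bool) -> np.ndarray | None:
    """Similar-class evidence for the two test patterns, or None if degenerate."""
    if np.allclose(train_x, train_x[0]):
        return None
    if standardize:
        mean = train_x.mean(axis=0)
        sd = train_x.std(axis=0)
        sd[sd == 0.0] = 1.0
        train_x = (train_x - mean) / sd
        test_x = (test_x - mean) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_x, train_y)
    # classes_ is sorted [0, 1]; decision_function > 0 favors class 1 (similar)
    return clf.decision_function(test_x)


def loso_timepoint_decode(matrices: Mapping[str, Mapping[str, DecodingMatrix]],
                          region: str | None = None, C: float = 1.0,
                          standardize: bool = True, alpha: float = 0.05
                          ) -> TimecourseResult:
    """Per-timepoint leave-one-subject-out forced-choice decoding.

    ``matrices`` maps subject → condition → :class:`DecodingMatrix`, with the
    conditions ``similar_1``, ``similar_2``, and ``distinct``.  With
    ``region`` set, only that region's single feature is used.  Folds whose
    training patterns are all identical are scored at chance (0.5) with a
    warning.
    """
    subjects = tuple(sorted(matrices))
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out decoding requires >= 3 subjects")
    reference = matrices[subjects[0]]["distinct"]
    n_timepoints = reference.values.shape[0]
    if region is not None:
        if region not in reference.region_names:
            raise ValueError(f"unknown region {region!r}; "
                             f"available: {reference.region_names}")
        feature_idx = np.array([reference.region_names.index(region)])
    else:
        feature_idx = np.arange(len(reference.region_names))

    # patterns[cond][subject] -> (n_timepoints, n_features)
    patterns = {cond: np.stack([matrices[s][cond].values[:, feature_idx]
                                for s in subjects])
                for cond in ("similar_1", "similar_2", "distinct")}

    n_subjects = len(subjects)
    correctness = np.zeros((n_subjects, n_timepoints))
    n_degenerate = 0
    for t_idx in range(n_timepoints):
        for problem_similar, _ in PAIRWISE_PROBLEMS:
            sim = patterns[problem_similar][:, t_idx, :]
            dist = patterns["distinct"][:, t_idx, :]
            for held in range(n_subjects):
                keep = np.arange(n_subjects) != held
                train_x = np.concatenate([sim[keep], dist[keep]])
                train_y = np.concatenate([np.ones(n_subjects - 1),
                                          np.zeros(n_subjects - 1)])
                evidence = _fold_evidence(train_x, train_y,
                                          np.stack([sim[held], dist[held]]),
                                          C, standardize)
                if evidence is None:
                    n_degenerate += 1
                    credit = 0.5
                else:
                    credit = forced_choice(evidence[0], evidence[1],
                                           a_is_similar=True)
                correctness[held, t_idx] += credit / len(PAIRWISE_PROBLEMS)
    if n_degenerate:
        warnings.warn(f"{n_degenerate} folds had identical training patterns and "
                      "were scored at chance", RuntimeWarning, stacklevel=2)

    accuracy = correctness.mean(axis=0)
    t_stats = np.empty(n_timepoints)
    p_values = np.empty(n_timepoints)
    for t_idx in range(n_timepoints):
        result = one_sample_t(correctness[:, t_idx], 0.5)
        t_stats[t_idx] = result.t
        p_values[t_idx] = result.p
    significant = (p_values < alpha) & (accuracy > 0.5)
    return TimecourseResult(subjects=subjects,
                            bin_start_times_ms=reference.bin_start_times_ms,
                            bin_duration_ms=reference.bin_duration_ms,
                            accuracy=accuracy, correctness=correctness,
                            t=t_stats, p=p_values, significant=significant,
                            alpha=alpha, region=region)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def behavior_correlation(result: TimecourseResult,
                         behavior_accuracy: Mapping[str, float]
                         ) -> TimecourseResult:
    """Pearson correlation of per-subject decoding correctness with behavior.

    Computed per timepoint across subjects; timepoints with zero variance in
    either vector are reported as missing (NaN), not zero.  Returns the
    result with ``behavior_r``/``behavior_p`` filled in.
    """
    accuracy = np.array([behavior_accuracy[s] for s in result.subjects])
    n_timepoints = len(result.bin_start_times_ms)
    r = np.empty(n_timepoints)
    p = np.empty(n_timepoints)
    for t_idx in range(n_timepoints):
        r[t_idx], p[t_idx] = pearson_r(result.correctness[:, t_idx], accuracy)
    result.behavior_r = r
    result.behavior_p = p
    return result


def summarize_timecourse(result: TimecourseResult) -> pd.DataFrame:
    """Maximal runs of consecutive significant bins, with bin-edge times."""
    flags = np.asarray(result.significant, dtype=bool)
    starts = result.bin_start_times_ms
    width = result.bin_duration_ms
    windows = []
    run_start = None
    for i, flag in enumerate(flags):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            windows.append((starts[run_start], starts[i - 1] + width))
            run_start = None
    if run_start is not None:
        windows.append((starts[run_start], starts[len(flags) - 1] + width))
    return pd.DataFrame(windows, columns=["start_ms", "end_ms"])
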