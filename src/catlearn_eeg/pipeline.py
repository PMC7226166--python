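"""End-to-end orchestration: raw recordings → behavioral, ERP, and decoding
results.

The per-subject stage order is fixed and logged: band-pass filter →
segmentation → artifact rejection → baseline correction → average reference
→ post-learning trial selection (learning criterion + correctness) →
per-condition averaging → component measurement → pattern construction.
Group-level statistics (condition contrasts, decoding timecourses,
behavior correlations) are computed once all subjects are processed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import behavior as beh
from .components import (ComponentContrast, ComponentMeasure, component_contrast,
                         default_component_defs, measure_component,
                         measures_to_frame)
from .config import CATEGORIES, SIMILAR_CATEGORIES
from .containers import ERPWaveform, Recording
from .decoding import (DecodingMatrix, TimecourseResult, behavior_correlation,
                       build_decoding_matrix, loso_timepoint_decode,
                       summarize_timecourse)
from .montage import Montage
from .preprocess import (EmptySelectionError, PreprocessParams, average_erp,
                         merge_similar_conditions, preprocess_recording)
from .simulate import SimulationConfig, SubjectData, simulate_study
from .stats import TTestResult

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Parameters of the analysis stages, defaulting to the study's values."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    fccr_k: int = 4
    nonresponse_breaks_run: bool = True
    #: restrict post-learning ERP averages to correctly answered trials
    require_correct: bool = True
    #: use all artifact-free trials instead of post-learning ones (for
    #: reduced schedules where the criterion leaves too few trials)
    use_all_trials: bool = False
    svm_C: float = 1.0
    standardize_features: bool = True
    alpha: float = 0.05
    accuracy_weighting: str = "trial"
    bin_size: int = 5
    drop_baseline_bins: int = 10


@dataclass
class SubjectOutputs:
    subject_id: str
    measures: list[ComponentMeasure]
    matrices: dict[str, DecodingMatrix]
    rejection_log: pd.DataFrame
    n_trials_by_condition: dict[str, int]
    cluster_waveforms: dict[str, np.ndarray]
    times_ms: np.ndarray


def process_subject(recording: Recording, behavior_table: pd.DataFrame,
                    montage: Montage, params: AnalysisParams | None = None
                    ) -> SubjectOutputs | None:
    """Run the per-subject pipeline; None if any condition ends up empty."""
    params = params or AnalysisParams()
    epochs, rejection_log = preprocess_recording(recording, params.preprocess)

    flagged = behavior_table.reset_index(drop=True)
    flagged["post_learning"] = beh.mark_post_learning(
        flagged, params.fccr_k, params.nonresponse_breaks_run)
    key = ["phase", "block", "trial"]
    labels = epochs.labels.merge(
        flagged[key + ["post_learning"]], on=key, how="left", validate="1:1")
    selected = labels["post_learning"].fillna(False).to_numpy(dtype=bool)
    if params.use_all_trials:
        selected = (labels["phase"] == "training").to_numpy()
    if params.require_correct:
        selected &= labels["correct"].to_numpy(dtype=bool)

    erps: dict[str, ERPWaveform] = {}
    try:
        for category in CATEGORIES:
            erps[category] = average_erp(epochs, category, selected)
    except EmptySelectionError as err:
        logger.warning("subject %s excluded from ERP/decoding analyses: %s",
                       recording.subject_id, err)
        return None
    erps["similar"] = merge_similar_conditions(
        erps[SIMILAR_CATEGORIES[0]], erps[SIMILAR_CATEGORIES[1]])

    defs = default_component_defs()
    measures = [measure_component(erps[condition], montage, cdef)
                for cdef in defs.values()
                for condition in ("distinct", "similar", "similar_1", "similar_2")]
    matrices = {category: build_decoding_matrix(
        erps[category], montage, params.bin_size, params.drop_baseline_bins)
        for category in CATEGORIES}
    cluster_waveforms = {
        f"{cluster}/{condition}": erps[condition].data[
            montage.cluster_indices(cluster)].mean(axis=0)
        for cluster in montage.clusters for condition in ("distinct", "similar")}
    return SubjectOutputs(
        subject_id=recording.subject_id, measures=measures, matrices=matrices,
        rejection_log=rejection_log,
        n_trials_by_condition={c: erps[c].n_trials_averaged for c in erps},
        cluster_waveforms=cluster_waveforms, times_ms=epochs.times_ms)


@dataclass
class StudyResult:
    """Aggregated behavioral, ERP, and decoding results for one study."""

    behavior_table: pd.DataFrame
    learning_curves_subject: pd.DataFrame
    learning_curves_group: pd.DataFrame
    behavior_contrast: TTestResult
    behavior_accuracy: pd.DataFrame
    generalization: pd.DataFrame
    confusion_counts: pd.DataFrame
    measures: pd.DataFrame
    contrasts: dict[str, ComponentContrast]
    subject_outputs: list[SubjectOutputs]
    timecourses: dict[str, TimecourseResult]     # "all" plus region names
    significant_windows: dict[str, pd.DataFrame]
    excluded_subjects: list[str]

    @property
    def matrices(self) -> dict[str, dict[str, DecodingMatrix]]:
        return {out.subject_id: out.matrices for out in self.subject_outputs}


def analyze_study(subjects: Iterable[tuple[Recording, pd.DataFrame]],
                  montage: Montage, params: AnalysisParams | None = None,
                  decode_regions: Sequence[str] = (),
                  decode: bool = True) -> StudyResult:
    """Run the full analysis over a stream of (recording, behavior) pairs.

    ``decode_regions`` may list region names for region-wise decoding, or
    ``("*",)`` for all regions; the whole-scalp timecourse is always
    computed when at least 3 subjects survive.
    """
    params = params or AnalysisParams()
    outputs: list[SubjectOutputs] = []
    excluded: list[str] = []
    behavior_tables = []
    for recording, behavior_table in subjects:
        behavior_tables.append(behavior_table)
        result = process_subject(recording, behavior_table, montage, params)
        if result is None:
            excluded.append(recording.subject_id)
        else:
            outputs.append(result)

    behavior_table = pd.concat(behavior_tables, ignore_index=True)
    curves_subject, curves_group = beh.learning_curves(behavior_table)
    contrast = beh.condition_contrast(behavior_table, params.accuracy_weighting)
    accuracy = beh.per_subject_accuracy(behavior_table, params.accuracy_weighting)
    generalization = beh.generalization_summary(behavior_table)
    confusion_counts, _ = beh.confusion_matrix(behavior_table)

    measures = measures_to_frame([m for out in outputs for m in out.measures]) \
        if outputs else pd.DataFrame()
    contrasts = {}
    if len(outputs) >= 2:
        all_measures = [m for out in outputs for m in out.measures]
        for component in default_component_defs():
            contrasts[component] = component_contrast(all_measures, component)

    timecourses: dict[str, TimecourseResult] = {}
    windows: dict[str, pd.DataFrame] = {}
    if decode and len(outputs) >= 3:
        matrices = {out.subject_id: out.matrices for out in outputs}
        behavior_by_subject = dict(zip(accuracy["subject"], accuracy["overall"]))
        region_list: list[str | None] = [None]
        if tuple(decode_regions) == ("*",):
            region_list += list(montage.region_names)
        else:
            region_list += list(decode_regions)
        for region in region_list:
            result = loso_timepoint_decode(
                matrices, region=region, C=params.svm_C,
                standardize=params.standardize_features, alpha=params.alpha)
            result = behavior_correlation(result, behavior_by_subject)
            key = region or "all"
            timecourses[key] = result
            windows[key] = summarize_timecourse(result)
            logger.info("decoded %s: peak accuracy %.3f", key,
                        float(result.accuracy.max()))

    return StudyResult(
        behavior_table=behavior_table, learning_curves_subject=curves_subject,
        learning_curves_group=curves_group, behavior_contrast=contrast,
        behavior_accuracy=accuracy, generalization=generalization,
        confusion_counts=confusion_counts, measures=measures,
        contrasts=contrasts, subject_outputs=outputs, timecourses=timecourses,
        significant_windows=windows, excluded_subjects=excluded)


def simulated_subject_stream(config: SimulationConfig
                             ) -> Iterator[tuple[Recording, pd.DataFrame]]:
    for subject in simulate_study(config):
        yield subject.recording, subject.behavior


def run_simulated_study(config: SimulationConfig, montage: Montage,
                        params: AnalysisParams | None = None,
                        decode_regions: Sequence[str] = (),
                        decode: bool = True) -> StudyResult:
    """Simulate a study and analyze it, one subject in memory at a time."""
    return analyze_study(simulated_subject_stream(config), montage, params,
                         decode_regions, decode)
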