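"""Preprocessing: band-pass filter, epoch, reject, baseline, re-reference.

The enforced stage order is filter → segment → artifact rejection →
baseline correction → average reference (see :func:`preprocess_recording`).
Artifact detection operates on filtered, pre-baseline voltages with a
strictly-greater-than threshold; both choices are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, ERPWaveform, Recording, epoch_times_ms

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing pipeline, defaulting to the study's values."""

    band_hz: tuple[float, float] = (0.1, 30.0)
    filter_order: int = 4
    pre_ms: float = 200.0
    post_ms: float = 1000.0
    artifact_threshold_uv: float = 140.0
    artifact_min_channels: int = 10
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)


def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Zero-phase (forward–backward) application preserves component latencies.
    Length and events are unchanged.
    """
    nyquist = rec.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(f"Invalid band ({low_hz}, {high_hz}) Hz for sampling rate "
                         f"{rec.sampling_rate}; need 0 < low < high < {nyquist}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    # pad generously: the low-cut transient decays over ~1/(2π·low_hz) seconds
    padlen = min(rec.n_samples - 1, int(3 * rec.sampling_rate / low_hz))
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1,
                                  padlen=padlen).astype(rec.data.dtype)
    return Recording(data=filtered, sampling_rate=rec.sampling_rate,
                     channel_labels=rec.channel_labels, events=rec.events,
                     subject_id=rec.subject_id)


def segment(rec: Recording, pre_ms: float = 200.0, post_ms: float = 1000.0
            ) -> EpochSet:
    """Cut one epoch per event, time-locked to stimulus onset.

    Events too close to a recording edge are dropped with a logged warning.
    At 250 samples/s the default −200..+1000 ms window yields 300 samples.
    """
    fs = rec.sampling_rate
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    times = epoch_times_ms(fs, pre_ms, post_ms)

    epochs, kept_rows = [], []
    for row_index, event in rec.events.iterrows():
        onset = int(event["sample_index"])
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > rec.n_samples:
            logger.warning("dropping event at sample %d: needs [%d, %d) of %d samples",
                           onset, start, stop, rec.n_samples)
            continue
        epochs.append(rec.data[:, start:stop])
        kept_rows.append(row_index)

    n_samples = n_pre + n_post
    data = (np.stack(epochs) if epochs
            else np.empty((0, rec.n_channels, n_samples), dtype=rec.data.dtype))
    labels = rec.events.loc[kept_rows].reset_index(drop=True)
    return EpochSet(data=data, times_ms=times, labels=labels, sampling_rate=fs,
                    channel_labels=rec.channel_labels, subject_id=rec.subject_id)


def reject_artifacts(epochs: EpochSet, abs_threshold_uv: float = 140.0,
                     min_channels: int = 10) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs in which ≥ ``min_channels`` channels exceed the threshold.

    A channel counts as offending when its maximum absolute voltage is
    *strictly greater than* ``abs_threshold_uv``.  Retained epochs are
    bit-identical to their inputs.  Returns the cleaned set plus a log with
    per-epoch offending-channel counts.
    """
    if abs_threshold_uv <= 0:
        raise ValueError("abs_threshold_uv must be > 0")
    if epochs.n_trials == 0:
        log = pd.DataFrame(columns=["epoch_index", "n_offending_channels", "rejected"])
        return epochs, log
    peak = np.max(np.abs(epochs.data), axis=2)          # (trials, channels)
    n_offending = np.sum(peak > abs_threshold_uv, axis=1)
    rejected = n_offending >= min_channels
    log = pd.DataFrame({"epoch_index": np.arange(epochs.n_trials),
                        "n_offending_channels": n_offending,
                        "rejected": rejected})
    if rejected.any():
        logger.info("rejected %d/%d epochs (>%g µV on >=%d channels)",
                    int(rejected.sum()), epochs.n_trials, abs_threshold_uv,
                    min_channels)
    return epochs.select(~rejected), log


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each channel's mean over the (half-open) baseline window."""
    lo, hi = baseline_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValueError(f"Baseline window {baseline_ms} ms contains no samples of "
                         f"the epoch time axis [{epochs.times_ms[0]}, "
                         f"{epochs.times_ms[-1]}] ms")
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data=epochs.data - means, times_ms=epochs.times_ms,
                    labels=epochs.labels, sampling_rate=epochs.sampling_rate,
                    channel_labels=epochs.channel_labels, subject_id=epochs.subject_id)


def average_reference(x: EpochSet | ERPWaveform) -> EpochSet | ERPWaveform:
    """Re-reference so the instantaneous mean across channels is zero."""
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ValueError("average reference requires at least 2 channels")
        data = x.data - x.data.mean(axis=1, keepdims=True)
        return EpochSet(data=data, times_ms=x.times_ms, labels=x.labels,
                        sampling_rate=x.sampling_rate,
                        channel_labels=x.channel_labels, subject_id=x.subject_id)
    if x.data.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = x.data - x.data.mean(axis=0, keepdims=True)
    return ERPWaveform(data=data, times_ms=x.times_ms, condition=x.condition,
                       n_trials_averaged=x.n_trials_averaged,
                       sampling_rate=x.sampling_rate,
                       channel_labels=x.channel_labels, subject_id=x.subject_id)


class EmptySelectionError(ValueError):
    """No trials matched the averaging filter."""


def average_erp(epochs: EpochSet, condition: str,
                trial_mask: np.ndarray | None = None) -> ERPWaveform:
    """Sample-wise mean over the selected trials of one condition."""
    mask = np.asarray(epochs.labels["category"] == condition)
    if trial_mask is not None:
        mask &= np.asarray(trial_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptySelectionError(
            f"No trials selected for condition {condition!r}")
    data = epochs.data[mask].mean(axis=0)
    return ERPWaveform(data=data, times_ms=epochs.times_ms, condition=condition,
                       n_trials_averaged=n, sampling_rate=epochs.sampling_rate,
                       channel_labels=epochs.channel_labels,
                       subject_id=epochs.subject_id)


def merge_similar_conditions(erp_a: ERPWaveform, erp_b: ERPWaveform,
                             condition: str = "similar") -> ERPWaveform:
    """Trial-count-weighted mean of the two visually similar categories' ERPs.

    Equivalent to re-averaging the underlying trials of both categories.
    """
    if erp_a.data.shape != erp_b.data.shape:
        raise ValueError("Cannot merge ERPs with differing shapes")
    n_a, n_b = erp_a.n_trials_averaged, erp_b.n_trials_averaged
    data = (n_a * erp_a.data + n_b * erp_b.data) / (n_a + n_b)
    return ERPWaveform(data=data, times_ms=erp_a.times_ms, condition=condition,
                       n_trials_averaged=n_a + n_b,
                       sampling_rate=erp_a.sampling_rate,
                       channel_labels=erp_a.channel_labels,
                       subject_id=erp_a.subject_id)


def preprocess_recording(rec: Recording, params: PreprocessParams | None = None
                         ) -> tuple[EpochSet, pd.DataFrame]:
    """Run the full stage order on one recording.

    filter → segment → reject → baseline-correct → average-reference.
    Returns the cleaned, corrected, re-referenced epochs and the rejection log.
    """
    params = params or PreprocessParams()
    logger.info("preprocess %s: band %s Hz, epoch -%g..+%g ms, reject >%g µV on "
                ">=%d channels", rec.subject_id, params.band_hz, params.pre_ms,
                params.post_ms, params.artifact_threshold_uv,
                params.artifact_min_channels)
    filtered = bandpass_filter(rec, *params.band_hz, order=params.filter_order)
    epochs = segment(filtered, params.pre_ms, params.post_ms)
    epochs, rejection_log = reject_artifacts(epochs, params.artifact_threshold_uv,
                                             params.artifact_min_channels)
    epochs = baseline_correct(epochs, params.baseline_window_ms)
    epochs = average_reference(epochs)
    return epochs, rejection_log
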