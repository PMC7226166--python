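"""Synthetic study generator: trial schedules, behavior, and dense-array EEG.

Each simulated trial's epoch is a sum of ERP components — a raised-cosine
temporal kernel at the component's condition-specific latency, scaled by the
condition-specific amplitude and projected through a fixed per-channel
topography — plus independent Gaussian channel noise (optionally with a 1/f
spectral profile).  A configurable fraction of trials receives a
high-amplitude artifact pulse on a dozen channels so the rejection rule has
something to reject.  Ground truth (the realized per-subject per-condition
amplitudes and latencies) is emitted alongside the data so recovery tests
never have to re-derive it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .config import (CATEGORIES, DISTINCT_CATEGORY, SIMILAR_CATEGORIES,
                     BehaviorParams, ComponentSpec, ConfigError, ScheduleSpec,
                     SimulationConfig)
from .containers import Recording, epoch_times_ms
from .montage import Montage, component_topography, default_montage, scaled_montage

logger = logging.getLogger(__name__)

PRE_MS = 200.0
POST_MS = 1000.0

#: pulse injected on artifact trials (µV, comfortably past the 140 µV rule)
ARTIFACT_AMPLITUDE_UV = 300.0
ARTIFACT_N_CHANNELS = 12
ARTIFACT_DURATION_S = 0.2

_ONSET_GAP_S = 1.3       # minimum onset-to-onset spacing (epoch is 1.2 s)
_ONSET_JITTER_S = 0.1
_EDGE_PAD_S = 1.0


def child_seed(*keys: int) -> int:
    """A stable sub-2**31 integer seed derived from a tuple of keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


# ----------------------------------------------------------------------
# temporal kernel
# ----------------------------------------------------------------------

def raised_cosine(t_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Raised-cosine bump: peak 1 at ``center_ms``, zero outside ±``width_ms``."""
    u = np.abs(np.asarray(t_ms, dtype=float) - center_ms)
    out = np.zeros_like(u)
    inside = u < width_ms
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * u[inside] / width_ms))
    return out


def adaptive_mean_factor(width_ms: float, halfwidth_ms: float, dt_ms: float) -> float:
    """Mean of the unit raised-cosine over the on-grid ±halfwidth window.

    This is the factor by which an adaptive-mean measurement shrinks a kernel
    peak; its inverse calibrates ``amplitude_mode='adaptive_mean'`` specs.
    """
    m = int(np.floor(halfwidth_ms / dt_ms + 1e-9))
    offsets = dt_ms * np.arange(-m, m + 1)
    return float(np.mean(raised_cosine(offsets, 0.0, width_ms)))


# ----------------------------------------------------------------------
# trial schedule
# ----------------------------------------------------------------------

def _stimulus_ids(spec: ScheduleSpec) -> tuple[list[tuple[str, str, bool]], ...]:
    per_cat_novel = spec.n_novel_stimuli // len(CATEGORIES)
    old = [(f"{cat}/old{j + 1}", cat, False)
           for cat in CATEGORIES for j in range(spec.n_stimuli_per_category)]
    novel = [(f"{cat}/novel{j + 1}", cat, True)
             for cat in CATEGORIES for j in range(per_cat_novel)]
    return old, novel


def build_schedule(spec: ScheduleSpec, seed: int) -> pd.DataFrame:
    """Randomized trial table: training blocks then a generalization block.

    Within every training block each trained stimulus appears exactly
    ``exposures_per_stimulus_per_block`` times in shuffled order; the
    generalization block mixes trained and novel stimuli, each repeated
    ``generalization_repeats`` times.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    old, novel = _stimulus_ids(spec)
    rows: list[tuple] = []
    for block in range(1, spec.n_training_blocks + 1):
        trials = old * spec.exposures_per_stimulus_per_block
        order = rng.permutation(len(trials))
        for within, idx in enumerate(order, start=1):
            sid, cat, is_novel = trials[idx]
            rows.append(("training", block, within, sid, cat, is_novel))
    gen_block = spec.n_training_blocks + 1
    trials = (old + novel) * spec.generalization_repeats
    order = rng.permutation(len(trials))
    for within, idx in enumerate(order, start=1):
        sid, cat, is_novel = trials[idx]
        rows.append(("generalization", gen_block, within, sid, cat, is_novel))
    return pd.DataFrame(rows, columns=["phase", "block", "trial", "stimulus_id",
                                       "category", "novel"])


# ----------------------------------------------------------------------
# behavior
# ----------------------------------------------------------------------

def _accuracy_curve(exposure: np.ndarray, rate: float, asymptote: float,
                    start: float) -> np.ndarray:
    """p(e) = a − (a − start)·exp(−rate·e), with e the 1-based exposure index."""
    with np.errstate(over="ignore"):
        decay = np.exp(-rate * exposure.astype(float))
    return asymptote - (asymptote - start) * decay


def simulate_behavior(config: SimulationConfig, schedule: pd.DataFrame,
                      seed: int) -> pd.DataFrame:
    """Add per-trial ``response`` and ``correct`` columns to a schedule.

    Accuracy follows each category's exponential learning curve over stimulus
    presentations (so the curve is monotone non-decreasing); errors on a
    similar category are assigned predominantly to the other similar category.
    Generalization trials use the end-of-training accuracy (no feedback, so
    no further learning); novel stimuli get the above-chance part of it
    scaled by the transfer fraction.  Deterministic given ``seed``.
    """
    params: BehaviorParams = config.behavior_params
    rng = np.random.default_rng(seed)
    rate_gain = float(np.exp(params.subject_rate_sigma * rng.standard_normal())) \
        if params.subject_rate_sigma > 0 else 1.0

    table = schedule.copy()
    training = table["phase"] == "training"
    # 1-based presentation index of each stimulus within training
    exposure = table.groupby("stimulus_id").cumcount().to_numpy() + 1

    p_correct = np.empty(len(table))
    p_final: dict[str, float] = {}
    for cat in CATEGORIES:
        rate = params.learning_rate[cat] * rate_gain
        asym = params.asymptote[cat]
        p_final[cat] = float(_accuracy_curve(
            np.array([config.trial_schedule.total_exposures_per_stimulus]),
            rate, asym, params.start_accuracy)[0])
        mask = (table["category"] == cat).to_numpy()
        curve = _accuracy_curve(exposure[mask], rate, asym, params.start_accuracy)
        p_correct[mask] = curve
        gen_mask = mask & ~training.to_numpy()
        p_gen_old = p_final[cat]
        p_gen_novel = params.start_accuracy + params.generalization_transfer * (
            p_gen_old - params.start_accuracy)
        novel = table["novel"].to_numpy()
        p_correct[gen_mask & ~novel] = p_gen_old
        p_correct[gen_mask & novel] = p_gen_novel

    correct = rng.random(len(table)) < p_correct
    response = np.array(table["category"], dtype=object)
    err_idx = np.flatnonzero(~correct)
    err_draw = rng.random(len(err_idx))
    for pos, i in enumerate(err_idx):
        true_cat = table["category"].iat[i]
        if true_cat in SIMILAR_CATEGORIES:
            other = SIMILAR_CATEGORIES[1 - SIMILAR_CATEGORIES.index(true_cat)]
            response[i] = other if err_draw[pos] < params.similar_confusion \
                else DISTINCT_CATEGORY
        else:
            response[i] = SIMILAR_CATEGORIES[0] if err_draw[pos] < 0.5 \
                else SIMILAR_CATEGORIES[1]
    table["response"] = response
    table["correct"] = correct
    return table


# ----------------------------------------------------------------------
# EEG
# ----------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, unit-variance per channel then scaled by ``sd``."""
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    for start in range(0, n_channels, 32):
        stop = min(start + 32, n_channels)
        white = rng.standard_normal((stop - start, n_samples))
        spectrum = np.fft.rfft(white, axis=-1) * shaping
        pink = np.fft.irfft(spectrum, n=n_samples, axis=-1)
        pink /= pink.std(axis=-1, keepdims=True)
        out[start:stop] = (sd * pink).astype(np.float32)
    return out


def _realized_parameters(config: SimulationConfig, rng: np.random.Generator
                         ) -> list[dict]:
    """Per-subject realized amplitude/latency for every component×condition."""
    realized = []
    for spec in config.component_specs:
        gain = float(np.exp(config.between_subject_amplitude_sigma
                            * rng.standard_normal())) \
            if config.between_subject_amplitude_sigma > 0 else 1.0
        lat_sd = config.between_subject_latency_sd_ms
        lat_offset = float(np.clip(lat_sd * rng.standard_normal(),
                                   -2 * lat_sd, 2 * lat_sd)) if lat_sd > 0 else 0.0
        realized.append({
            "spec": spec,
            "gain": gain,
            "amplitude": {cat: spec.amplitude_uv[cat] * gain for cat in CATEGORIES},
            "latency": {cat: spec.peak_latency_ms[cat] + lat_offset
                        for cat in CATEGORIES},
        })
    return realized


def _condition_templates(config: SimulationConfig, realized: list[dict],
                         times_ms: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free epoch signal (channels × samples) per condition."""
    dt = 1000.0 / config.sampling_rate
    templates = {}
    for cat in CATEGORIES:
        signal = np.zeros((config.n_channels, len(times_ms)), dtype=np.float64)
        for item in realized:
            spec: ComponentSpec = item["spec"]
            peak = item["amplitude"][cat]
            if spec.amplitude_mode == "adaptive_mean":
                factor = adaptive_mean_factor(spec.temporal_width_ms,
                                              spec.calibration_halfwidth_ms, dt)
                peak = peak / factor
            kernel = raised_cosine(times_ms, item["latency"][cat],
                                   spec.temporal_width_ms)
            signal += peak * np.outer(spec.topography, kernel)
        templates[cat] = signal.astype(np.float32)
    return templates


def simulate_subject_eeg(config: SimulationConfig, schedule_behavior: pd.DataFrame,
                         subject_index: int) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording + event table + ground truth for one subject.

    Deterministic given ``(config, subject_index)``; the per-subject random
    stream is derived from ``config.seed``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(f"subject_index {subject_index} out of range "
                          f"[0, {config.n_subjects})")
    fs = config.sampling_rate
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), 2, subject_index])
    subject_id = f"s{subject_index:02d}"

    times_ms = epoch_times_ms(fs, PRE_MS, POST_MS)
    n_pre = int(round(PRE_MS / 1000.0 * fs))
    n_epoch = len(times_ms)

    realized = _realized_parameters(config, rng)
    templates = _condition_templates(config, realized, times_ms)

    n_trials = len(schedule_behavior)
    gaps = _ONSET_GAP_S + _ONSET_JITTER_S * rng.random(n_trials)
    onsets_s = _EDGE_PAD_S + np.cumsum(gaps) - gaps[0] + 0.0
    onset_samples = np.round(onsets_s * fs).astype(int)
    n_samples = int(onset_samples[-1] + (n_epoch - n_pre) + round(_EDGE_PAD_S * fs))

    if config.noise_sd > 0:
        if config.noise_model == "pink":
            data = _pink_noise(rng, config.n_channels, n_samples, config.noise_sd)
        else:
            data = rng.standard_normal((config.n_channels, n_samples),
                                       dtype=np.float32)
            data *= np.float32(config.noise_sd)
    else:
        data = np.zeros((config.n_channels, n_samples), dtype=np.float32)

    artifact_flags = rng.random(n_trials) < config.artifact_rate
    art_len = int(round(ARTIFACT_DURATION_S * fs))
    for i in range(n_trials):
        cat = schedule_behavior["category"].iat[i]
        start = onset_samples[i] - n_pre
        data[:, start:start + n_epoch] += templates[cat]
        if artifact_flags[i]:
            n_art = min(ARTIFACT_N_CHANNELS, config.n_channels)
            channels = rng.choice(config.n_channels, size=n_art, replace=False)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            offset = int(rng.integers(0, max(1, n_epoch - n_pre - art_len)))
            seg = slice(onset_samples[i] + offset,
                        onset_samples[i] + offset + art_len)
            data[channels, seg] += np.float32(sign * ARTIFACT_AMPLITUDE_UV)

    events = schedule_behavior.copy()
    events["sample_index"] = onset_samples
    events["artifact_injected"] = artifact_flags

    ground_truth = pd.DataFrame([
        {"subject": subject_id, "component": item["spec"].name, "condition": cat,
         "amplitude_uv": item["amplitude"][cat], "latency_ms": item["latency"][cat],
         "gain": item["gain"], "amplitude_mode": item["spec"].amplitude_mode}
        for item in realized for cat in CATEGORIES])

    labels = [f"E{i + 1}" for i in range(config.n_channels)]
    recording = Recording(data=data, sampling_rate=fs, channel_labels=labels,
                          events=events, subject_id=subject_id)
    return recording, ground_truth


# ----------------------------------------------------------------------
# calibrated defaults and study-level driver
# ----------------------------------------------------------------------

#: Calibrated per-condition adaptive-mean amplitudes (µV).  The raw MFN values
#: are the published peak-to-peak targets (−2.31 distinct / −2.07 similar)
#: plus the P200 reference amplitude, so the referenced measure reproduces the
#: published numbers.  The right LIAN is larger for the similar condition.
DEFAULT_AMPLITUDES_UV: Mapping[str, Mapping[str, float]] = {
    "P200": {"similar_1": 1.5, "similar_2": 1.5, "distinct": 1.5},
    "MFN": {"similar_1": -0.57, "similar_2": -0.57, "distinct": -0.81},
    "P3b": {"similar_1": 5.34, "similar_2": 5.34, "distinct": 6.02},
    "LIAN_left": {"similar_1": -5.54, "similar_2": -5.54, "distinct": -7.06},
    "LIAN_right": {"similar_1": -3.55, "similar_2": -3.55, "distinct": -2.92},
}

DEFAULT_LATENCIES_MS: Mapping[str, float] = {
    "P200": 168.0, "MFN": 248.0, "P3b": 560.0, "LIAN_left": 640.0,
    "LIAN_right": 640.0,
}

#: half-support of each raised-cosine kernel (ms); the P200 and MFN supports
#: are narrow enough that neither leaks into the other's averaging window
DEFAULT_KERNEL_WIDTHS_MS: Mapping[str, float] = {
    "P200": 56.0, "MFN": 52.0, "P3b": 300.0, "LIAN_left": 300.0,
    "LIAN_right": 300.0,
}

_COMPONENT_CLUSTER = {"P200": "MFN", "MFN": "MFN", "P3b": "P3b",
                      "LIAN_left": "LIAN_left", "LIAN_right": "LIAN_right"}
_CALIBRATION_HALFWIDTH_MS = {"P200": 20.0, "MFN": 20.0, "P3b": 22.0,
                             "LIAN_left": 22.0, "LIAN_right": 22.0}


def default_component_specs(montage: Montage, *, null: bool = False
                            ) -> list[ComponentSpec]:
    """The five calibrated component specs on a given montage.

    With ``null=True`` every component's amplitudes are replaced by their
    cross-condition mean, making the three conditions statistically
    identical — the configuration used for chance-level calibration.
    """
    specs = []
    for name, amps in DEFAULT_AMPLITUDES_UV.items():
        amplitude = dict(amps)
        if null:
            mean = float(np.mean(list(amps.values())))
            amplitude = {cat: mean for cat in CATEGORIES}
        specs.append(ComponentSpec(
            name=name,
            peak_latency_ms={cat: DEFAULT_LATENCIES_MS[name] for cat in CATEGORIES},
            amplitude_uv=amplitude,
            temporal_width_ms=DEFAULT_KERNEL_WIDTHS_MS[name],
            topography=component_topography(montage, _COMPONENT_CLUSTER[name]),
            amplitude_mode="adaptive_mean",
            calibration_halfwidth_ms=_CALIBRATION_HALFWIDTH_MS[name],
        ))
    return specs


def make_default_config(n_subjects: int, seed: int, *, n_channels: int = 256,
                        null: bool = False, montage: Montage | None = None,
                        **overrides) -> tuple[SimulationConfig, Montage]:
    """Convenience constructor: scaled montage + calibrated specs + config."""
    if montage is None:
        montage = default_montage() if n_channels == 256 else scaled_montage(n_channels)
    specs = default_component_specs(montage, null=null)
    config = SimulationConfig(n_subjects=n_subjects, component_specs=specs,
                              n_channels=n_channels, seed=seed, **overrides)
    return config, montage


@dataclass
class SubjectData:
    """One subject's simulated raw data and its ground truth."""

    subject_id: str
    recording: Recording
    behavior: pd.DataFrame  # schedule + responses, with subject column
    ground_truth: pd.DataFrame


def simulate_study(config: SimulationConfig) -> Iterator[SubjectData]:
    """Yield subjects one at a time (recordings are large; stream them)."""
    for subject_index in range(config.n_subjects):
        subject_id = f"s{subject_index:02d}"
        schedule = build_schedule(config.trial_schedule,
                                  child_seed(config.seed, 0, subject_index))
        behavior = simulate_behavior(config, schedule,
                                     child_seed(config.seed, 1, subject_index))
        recording, ground_truth = simulate_subject_eeg(config, behavior, subject_index)
        table = behavior.copy()
        table.insert(0, "subject", subject_id)
        logger.info("simulated subject %s: %d trials, %d samples",
                    subject_id, len(table), recording.n_samples)
        yield SubjectData(subject_id=subject_id, recording=recording,
                          behavior=table, ground_truth=ground_truth)
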