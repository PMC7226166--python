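"""Configuration types for the synthetic study generator.

Amplitude conventions
---------------------
A :class:`ComponentSpec` amplitude can be interpreted two ways, selected by
``amplitude_mode``:

``"peak"``
    The amplitude is the peak value of the temporal kernel (µV at the
    component's latency, for a channel with topography weight 1).

``"adaptive_mean"``
    The amplitude is the *adaptive-mean* value the measurement stage will
    report: the mean of the kernel over the ±``calibration_halfwidth_ms``
    window centred on the peak, evaluated on the sampling grid.  The kernel
    peak is scaled up accordingly.  This is the unit in which ERP component
    amplitudes are conventionally reported, and the calibrated defaults in
    :func:`catlearn_eeg.simulate.default_component_specs` use it so that a
    noiseless measurement recovers the configured value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CATEGORIES = ("similar_1", "similar_2", "distinct")
SIMILAR_CATEGORIES = ("similar_1", "similar_2")
DISTINCT_CATEGORY = "distinct"

COMPONENT_NAMES = ("P200", "MFN", "P3b", "LIAN_left", "LIAN_right")
#: components constrained to be negative-going / positive-going
NEGATIVE_COMPONENTS = ("MFN", "LIAN_left", "LIAN_right")
POSITIVE_COMPONENTS = ("P200", "P3b")

#: analysis search windows (ms post-onset) each component's latency must fall in
COMPONENT_WINDOWS_MS = {
    "P200": (150.0, 200.0),
    "MFN": (180.0, 300.0),
    "P3b": (450.0, 950.0),
    "LIAN_left": (450.0, 950.0),
    "LIAN_right": (450.0, 950.0),
}


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented constraints."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


@dataclass(frozen=True)
class ScheduleSpec:
    """Trial-schedule parameters for one subject.

    Defaults reproduce the study design: 8 training blocks of 90 trials
    (10 exposures of each of 9 stimuli per block, 80 exposures total), then a
    feedback-free generalization block in which the 9 trained and 9 novel
    stimuli each appear 5 times (90 trials).
    """

    n_training_blocks: int = 8
    exposures_per_stimulus_per_block: int = 10
    n_stimuli_per_category: int = 3
    generalization_repeats: int = 5
    n_novel_stimuli: int = 9

    def __post_init__(self) -> None:
        for name in (
            "n_training_blocks",
            "exposures_per_stimulus_per_block",
            "n_stimuli_per_category",
            "generalization_repeats",
            "n_novel_stimuli",
        ):
            value = getattr(self, name)
            _require(isinstance(value, (int, np.integer)) and value >= 1,
                     f"ScheduleSpec.{name} must be an integer >= 1, got {value!r}")
        _require(self.n_novel_stimuli % len(CATEGORIES) == 0,
                 "ScheduleSpec.n_novel_stimuli must be divisible by the number of "
                 f"categories ({len(CATEGORIES)}), got {self.n_novel_stimuli}")

    @property
    def n_old_stimuli(self) -> int:
        return self.n_stimuli_per_category * len(CATEGORIES)

    @property
    def training_trials_per_block(self) -> int:
        return self.exposures_per_stimulus_per_block * self.n_old_stimuli

    @property
    def total_exposures_per_stimulus(self) -> int:
        return self.exposures_per_stimulus_per_block * self.n_training_blocks

    @property
    def generalization_trials(self) -> int:
        return (self.n_old_stimuli + self.n_novel_stimuli) * self.generalization_repeats


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the simulated learning curves.

    Per-category accuracy follows an exponential approach to asymptote over
    stimulus presentations ``e = 1, 2, ...``::

        p(e) = asymptote - (asymptote - 1/3) * exp(-rate * e)

    so a flat curve (rate 0) stays at chance and an infinitely fast learner
    with asymptote 1 is always correct.  Errors on a visually similar category
    land on the *other* similar category with probability
    ``similar_confusion``; errors on the distinct category split evenly.
    Defaults are calibrated so that trial-weighted mean training accuracy is
    ~96% (distinct) vs ~90% (similar), the acquired-first ordering of the
    study's learning curves.
    """

    learning_rate: Mapping[str, float] = field(
        default_factory=lambda: {"similar_1": 0.12, "similar_2": 0.12, "distinct": 0.30})
    asymptote: Mapping[str, float] = field(
        default_factory=lambda: {"similar_1": 0.97, "similar_2": 0.97, "distinct": 0.99})
    start_accuracy: float = 1.0 / 3.0
    similar_confusion: float = 0.8
    #: lognormal sigma of the per-subject multiplicative learning-rate jitter
    subject_rate_sigma: float = 0.3
    #: fraction of the above-chance asymptote that transfers to novel stimuli
    generalization_transfer: float = 0.9

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            _require(cat in self.learning_rate, f"BehaviorParams.learning_rate missing {cat!r}")
            _require(cat in self.asymptote, f"BehaviorParams.asymptote missing {cat!r}")
            _require(self.learning_rate[cat] >= 0,
                     f"BehaviorParams.learning_rate[{cat!r}] must be >= 0")
            _require(0.0 <= self.asymptote[cat] <= 1.0,
                     f"BehaviorParams.asymptote[{cat!r}] must be in [0, 1]")
        _require(0.0 <= self.start_accuracy <= 1.0, "BehaviorParams.start_accuracy in [0, 1]")
        _require(0.0 <= self.similar_confusion <= 1.0,
                 "BehaviorParams.similar_confusion must be in [0, 1]")
        _require(self.subject_rate_sigma >= 0, "BehaviorParams.subject_rate_sigma must be >= 0")
        _require(0.0 <= self.generalization_transfer <= 1.0,
                 "BehaviorParams.generalization_transfer must be in [0, 1]")


@dataclass
class ComponentSpec:
    """One embedded ERP component: raised-cosine bump × fixed topography.

    ``peak_latency_ms`` and ``amplitude_uv`` map each category to that
    condition's latency/amplitude.  ``temporal_width_ms`` is the half-support
    of the raised-cosine kernel (the kernel is zero outside
    ``latency ± temporal_width_ms``).  ``topography`` is a per-channel weight
    vector, conventionally 1 on the component's electrode cluster and a small
    negative counterweight elsewhere so the scalp field sums to zero (which
    makes the component invariant under average referencing, as a dipolar
    field is).
    """

    name: str
    peak_latency_ms: Mapping[str, float]
    amplitude_uv: Mapping[str, float]
    temporal_width_ms: float
    topography: np.ndarray
    amplitude_mode: str = "peak"
    calibration_halfwidth_ms: float | None = None

    def __post_init__(self) -> None:
        _require(self.name in COMPONENT_NAMES,
                 f"ComponentSpec.name must be one of {COMPONENT_NAMES}, got {self.name!r}")
        _require(self.temporal_width_ms > 0, "ComponentSpec.temporal_width_ms must be > 0")
        _require(self.amplitude_mode in ("peak", "adaptive_mean"),
                 f"ComponentSpec.amplitude_mode must be 'peak' or 'adaptive_mean', "
                 f"got {self.amplitude_mode!r}")
        if self.amplitude_mode == "adaptive_mean":
            _require(self.calibration_halfwidth_ms is not None
                     and self.calibration_halfwidth_ms > 0,
                     "ComponentSpec.calibration_halfwidth_ms must be set (> 0) when "
                     "amplitude_mode='adaptive_mean'")
        self.topography = np.asarray(self.topography, dtype=float)
        _require(np.all(np.isfinite(self.topography)),
                 f"ComponentSpec({self.name}).topography must be finite")
        window = COMPONENT_WINDOWS_MS[self.name]
        for cat in CATEGORIES:
            _require(cat in self.peak_latency_ms,
                     f"ComponentSpec({self.name}).peak_latency_ms missing {cat!r}")
            _require(cat in self.amplitude_uv,
                     f"ComponentSpec({self.name}).amplitude_uv missing {cat!r}")
            lat = self.peak_latency_ms[cat]
            _require(window[0] <= lat <= window[1],
                     f"ComponentSpec({self.name}).peak_latency_ms[{cat!r}]={lat} outside "
                     f"the component's analysis window {window}")
            amp = self.amplitude_uv[cat]
            if self.name in NEGATIVE_COMPONENTS:
                _require(amp <= 0, f"ComponentSpec({self.name}) amplitudes must be <= 0")
            else:
                _require(amp >= 0, f"ComponentSpec({self.name}) amplitudes must be >= 0")


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic multi-subject study."""

    n_subjects: int
    component_specs: Sequence[ComponentSpec]
    sampling_rate: float = 250.0
    n_channels: int = 256
    noise_sd: float = 5.0
    noise_model: str = "white"
    artifact_rate: float = 0.05
    trial_schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    #: lognormal sigma of the per-subject per-component amplitude gain
    between_subject_amplitude_sigma: float = 0.15
    #: sd (ms) of the per-subject per-component latency offset, clipped to ±2 sd
    between_subject_latency_sd_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 1, "SimulationConfig.n_subjects must be >= 1")
        _require(self.sampling_rate > 0, "SimulationConfig.sampling_rate must be > 0")
        _require(self.n_channels >= 2, "SimulationConfig.n_channels must be >= 2")
        _require(self.noise_sd >= 0, "SimulationConfig.noise_sd must be >= 0")
        _require(self.noise_model in ("white", "pink"),
                 "SimulationConfig.noise_model must be 'white' or 'pink'")
        _require(0.0 <= self.artifact_rate <= 1.0,
                 "SimulationConfig.artifact_rate must be in [0, 1]")
        _require(self.between_subject_amplitude_sigma >= 0,
                 "SimulationConfig.between_subject_amplitude_sigma must be >= 0")
        _require(self.between_subject_latency_sd_ms >= 0,
                 "SimulationConfig.between_subject_latency_sd_ms must be >= 0")
        for spec in self.component_specs:
            _require(spec.topography.shape == (self.n_channels,),
                     f"ComponentSpec({spec.name}).topography has shape "
                     f"{spec.topography.shape}, expected ({self.n_channels},)")
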