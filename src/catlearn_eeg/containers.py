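"""In-memory containers for continuous recordings, epochs, and averaged ERPs.

Time-axis convention: with a 250 samples/s rate and a −200..+1000 ms epoch,
an epoch has 300 samples whose centres run from −200 to +996 ms in 4 ms
steps; sample *k* covers the half-open interval ``[k·4, k·4+4)`` ms relative
to stimulus onset, so time 0 is the first post-baseline sample and the
baseline comprises the 50 samples with negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """Continuous multichannel EEG (µV) with an event table.

    ``events`` must contain a ``sample_index`` column (stimulus-onset sample)
    plus whatever trial labels downstream stages need (category, phase,
    block, trial, stimulus_id, novel, response, correct).
    """

    data: np.ndarray  # (n_channels, n_samples) µV
    sampling_rate: float
    channel_labels: Sequence[str]
    events: pd.DataFrame
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sampling_rate <= 0:
            raise ValueError("Recording.sampling_rate must be > 0")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} rows")
        if "sample_index" in self.events.columns and len(self.events):
            idx = self.events["sample_index"].to_numpy()
            if idx.min() < 0 or idx.max() >= self.data.shape[1]:
                raise ValueError("Recording event sample indices out of data bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch_times_ms(sampling_rate: float, pre_ms: float = 200.0,
                   post_ms: float = 1000.0) -> np.ndarray:
    """Sample-centre times (ms) of a ``−pre_ms..+post_ms`` epoch."""
    dt = 1000.0 / sampling_rate
    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    return (np.arange(n_pre + n_post) - n_pre) * dt


@dataclass
class EpochSet:
    """Trials × channels × samples, time-locked to stimulus onset."""

    data: np.ndarray  # (n_trials, n_channels, n_samples) µV
    times_ms: np.ndarray
    labels: pd.DataFrame  # one row per trial
    sampling_rate: float
    channel_labels: Sequence[str]
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (trials, channels, samples)")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("EpochSet time axis length does not match data")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("EpochSet.labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(data=self.data[mask],
                        times_ms=self.times_ms,
                        labels=self.labels.iloc[mask].reset_index(drop=True),
                        sampling_rate=self.sampling_rate,
                        channel_labels=self.channel_labels,
                        subject_id=self.subject_id)


@dataclass
class ERPWaveform:
    """Per-condition averaged waveform (channels × samples, µV)."""

    data: np.ndarray
    times_ms: np.ndarray
    condition: str
    n_trials_averaged: int
    sampling_rate: float
    channel_labels: Sequence[str]
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("ERPWaveform time axis length does not match data")
        if self.n_trials_averaged < 1:
            raise ValueError("ERPWaveform.n_trials_averaged must be >= 1")
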