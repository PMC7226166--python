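"""HDF5 study container and TSV helpers.

Layout of a study container::

    /subjects/s00/data           float32, channels × samples (µV)
                  /events/<col>  event table columns (onsets + trial labels)
                  /ground_truth/<col>   optional simulator ground truth
    /channel_labels              shared channel-label list
    attrs: sampling_rate, n_subjects

Tables are stored column-wise; strings as UTF-8, booleans as uint8 with a
``pandas_dtype`` attribute for faithful round-trips.  Behavior and result
tables on disk are plain TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, Recording
from .simulate import SubjectData

logger = logging.getLogger(__name__)


def _write_frame(group: h5py.Group, frame: pd.DataFrame) -> None:
    group.attrs["columns"] = list(frame.columns)
    group.attrs["n_rows"] = len(frame)
    for col in frame.columns:
        series = frame[col]
        if series.dtype == object or pd.api.types.is_string_dtype(series):
            data = series.astype(str).to_numpy(dtype=object)
            dset = group.create_dataset(col, data=data, track_times=False,
                                        dtype=h5py.string_dtype("utf-8"))
            dset.attrs["pandas_dtype"] = "str"
        elif series.dtype == bool:
            dset = group.create_dataset(col, data=series.to_numpy(np.uint8),
                                        track_times=False)
            dset.attrs["pandas_dtype"] = "bool"
        else:
            dset = group.create_dataset(col, data=series.to_numpy(),
                                        track_times=False)
            dset.attrs["pandas_dtype"] = str(series.dtype)


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    columns = list(group.attrs["columns"])
    data = {}
    for col in columns:
        dset = group[col]
        kind = dset.attrs.get("pandas_dtype", "")
        values = dset[()]
        if kind == "str":
            values = np.array([v.decode() if isinstance(v, bytes) else str(v)
                               for v in values], dtype=object)
        elif kind == "bool":
            values = values.astype(bool)
        data[col] = values
    return pd.DataFrame(data, columns=columns)


def write_study(path: str | Path, subjects: Iterable[SubjectData],
                sampling_rate: float) -> list[str]:
    """Stream subjects into a study container; returns the subject ids."""
    path = Path(path)
    subject_ids = []
    with h5py.File(path, "w") as fh:
        fh.attrs["sampling_rate"] = sampling_rate
        root = fh.create_group("subjects")
        for subject in subjects:
            grp = root.create_group(subject.subject_id)
            grp.create_dataset("data", data=subject.recording.data,
                               dtype="float32", track_times=False)
            _write_frame(grp.create_group("events"), subject.recording.events)
            _write_frame(grp.create_group("ground_truth"), subject.ground_truth)
            if "channel_labels" not in fh:
                fh.create_dataset(
                    "channel_labels", track_times=False,
                    data=np.array(subject.recording.channel_labels, dtype=object),
                    dtype=h5py.string_dtype("utf-8"))
            subject_ids.append(subject.subject_id)
            logger.info("wrote subject %s (%d samples)", subject.subject_id,
                        subject.recording.n_samples)
        fh.attrs["n_subjects"] = len(subject_ids)
    return subject_ids


def list_subjects(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return sorted(fh["subjects"].keys())


def read_subject(path: str | Path, subject_id: str
                 ) -> tuple[Recording, pd.DataFrame]:
    """Read one subject's recording (with events) and its ground truth."""
    with h5py.File(path, "r") as fh:
        grp = fh["subjects"][subject_id]
        labels = [v.decode() if isinstance(v, bytes) else str(v)
                  for v in fh["channel_labels"][()]]
        recording = Recording(data=grp["data"][()],
                              sampling_rate=float(fh.attrs["sampling_rate"]),
                              channel_labels=labels,
                              events=_read_frame(grp["events"]),
                              subject_id=subject_id)
        ground_truth = _read_frame(grp["ground_truth"])
    return recording, ground_truth


def read_study_ground_truth(path: str | Path) -> pd.DataFrame:
    frames = []
    with h5py.File(path, "r") as fh:
        for subject_id in sorted(fh["subjects"]):
            frames.append(_read_frame(fh["subjects"][subject_id]["ground_truth"]))
    return pd.concat(frames, ignore_index=True)


def iter_study(path: str | Path) -> Iterator[tuple[Recording, pd.DataFrame]]:
    """Yield (recording, behavior table) per subject, one at a time.

    The behavior table is reconstructed from the stored event table (which
    carries the full schedule + response labels) with a subject column.
    """
    for subject_id in list_subjects(path):
        recording, _ = read_subject(path, subject_id)
        behavior = recording.events.drop(
            columns=[c for c in ("sample_index", "artifact_injected")
                     if c in recording.events.columns]).copy()
        behavior.insert(0, "subject", subject_id)
        yield recording, behavior


def write_epochs(path: str | Path, epochs: EpochSet,
                 rejection_log: pd.DataFrame | None = None) -> None:
    """Persist one subject's epochs (trials × channels × samples)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, dtype="float32",
                          track_times=False)
        fh.create_dataset("times_ms", data=epochs.times_ms, track_times=False)
        fh.create_dataset("channel_labels", track_times=False,
                          data=np.array(epochs.channel_labels, dtype=object),
                          dtype=h5py.string_dtype("utf-8"))
        fh.attrs["sampling_rate"] = epochs.sampling_rate
        fh.attrs["subject_id"] = epochs.subject_id
        _write_frame(fh.create_group("labels"), epochs.labels)
        if rejection_log is not None:
            _write_frame(fh.create_group("rejection_log"), rejection_log)


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        labels = [v.decode() if isinstance(v, bytes) else str(v)
                  for v in fh["channel_labels"][()]]
        return EpochSet(data=fh["data"][()], times_ms=fh["times_ms"][()],
                        labels=_read_frame(fh["labels"]),
                        sampling_rate=float(fh.attrs["sampling_rate"]),
                        channel_labels=labels,
                        subject_id=str(fh.attrs["subject_id"]))


def read_edf(path: str | Path, events: pd.DataFrame,
             subject_id: str = "s00") -> Recording:
    """Read a continuous EDF recording (optional; requires ``mne``).

    ``events`` must supply the stimulus-onset sample indices and trial
    labels, as EDF annotations rarely carry the full trial structure.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("EDF ingestion requires the optional 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    return Recording(data=data_uv.astype(np.float32),
                     sampling_rate=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), events=events,
                     subject_id=subject_id)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
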