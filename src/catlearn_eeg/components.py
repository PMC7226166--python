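"""ERP component quantification via adaptive mean amplitudes.

Each component is measured on the average of its electrode cluster: the
extremum of the stated polarity is located inside the component's search
window, and the amplitude is the mean voltage over a fixed ±halfwidth window
centred on that per-subject peak (the *adaptive mean*).  The medial frontal
negativity (MFN, 180–300 ms, ±20 ms) is expressed peak-to-peak against the
preceding P200 positivity (150–200 ms); the P3b (450–950 ms, ±22 ms) and the
bilateral lateral inferior anterior negativities (LIAN, same window, ±22 ms)
are measured directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .containers import ERPWaveform
from .montage import Montage
from .stats import TTestResult, paired_t

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentDef:
    """How to measure one component: cluster, polarity, window, halfwidth."""

    name: str
    cluster: str
    polarity: str  # "negative" | "positive"
    search_window_ms: tuple[float, float]
    halfwidth_ms: float
    reference: Optional["ComponentDef"] = None
    #: when True, the reference amplitude is the point value at the reference
    #: peak instead of an adaptive mean around it
    point_reference: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be 'negative' or 'positive', "
                             f"got {self.polarity!r}")
        if self.halfwidth_ms <= 0:
            raise ValueError("halfwidth_ms must be > 0")
        if self.search_window_ms[0] >= self.search_window_ms[1]:
            raise ValueError(f"empty search window {self.search_window_ms}")


def default_component_defs() -> dict[str, ComponentDef]:
    """The study's component definitions (windows and halfwidths as printed)."""
    p200 = ComponentDef(name="P200", cluster="MFN", polarity="positive",
                        search_window_ms=(150.0, 200.0), halfwidth_ms=20.0)
    return {
        "P200": p200,
        "MFN": ComponentDef(name="MFN", cluster="MFN", polarity="negative",
                            search_window_ms=(180.0, 300.0), halfwidth_ms=20.0,
                            reference=p200),
        "P3b": ComponentDef(name="P3b", cluster="P3b", polarity="positive",
                            search_window_ms=(450.0, 950.0), halfwidth_ms=22.0),
        "LIAN_left": ComponentDef(name="LIAN_left", cluster="LIAN_left",
                                  polarity="negative",
                                  search_window_ms=(450.0, 950.0),
                                  halfwidth_ms=22.0),
        "LIAN_right": ComponentDef(name="LIAN_right", cluster="LIAN_right",
                                   polarity="negative",
                                   search_window_ms=(450.0, 950.0),
                                   halfwidth_ms=22.0),
    }


@dataclass(frozen=True)
class ComponentMeasure:
    """One subject × condition measurement of one component."""

    component: str
    subject: str
    condition: str
    amplitude_uv: float
    peak_latency_ms: float
    reference_amplitude_uv: float | None = None
    reference_latency_ms: float | None = None
    n_trials: int | None = None


def cluster_waveform(erp: ERPWaveform, montage: Montage, cluster: str
                     ) -> np.ndarray:
    """Sample-wise mean over the cluster's channels (1-D, µV)."""
    idx = montage.cluster_indices(cluster)
    return erp.data[idx].mean(axis=0)


def find_peak(waveform: np.ndarray, times_ms: np.ndarray,
              window_ms: tuple[float, float], polarity: str
              ) -> tuple[float, float]:
    """Latency and value of the windowed extremum of the stated polarity.

    Negative polarity takes the minimum, positive the maximum; ties break
    toward the earliest latency.  The window is inclusive on sample centres.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"search window {window_ms} ms is outside the time axis "
                         f"[{times_ms[0]}, {times_ms[-1]}] ms")
    values = waveform[mask]
    local = np.argmin(values) if polarity == "negative" else np.argmax(values)
    idx = np.flatnonzero(mask)[local]
    return float(times_ms[idx]), float(waveform[idx])


def adaptive_mean(waveform: np.ndarray, times_ms: np.ndarray,
                  peak_latency_ms: float, halfwidth_ms: float) -> float:
    """Mean of the samples whose centres lie within ±halfwidth of the peak.

    Clipped (with a logged warning) if the window extends past the epoch.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    lo = peak_latency_ms - halfwidth_ms
    hi = peak_latency_ms + halfwidth_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        logger.warning("adaptive-mean window [%g, %g] ms clipped to epoch "
                       "[%g, %g] ms", lo, hi, times_ms[0], times_ms[-1])
    mask = (times_ms >= lo) & (times_ms <= hi)
    return float(np.asarray(waveform, dtype=float)[mask].mean())


def measure_component(erp: ERPWaveform, montage: Montage, cdef: ComponentDef
                      ) -> ComponentMeasure:
    """Adaptive-mean amplitude (peak-to-peak if referenced) of one component."""
    w = cluster_waveform(erp, montage, cdef.cluster)
    latency, _ = find_peak(w, erp.times_ms, cdef.search_window_ms, cdef.polarity)
    amplitude = adaptive_mean(w, erp.times_ms, latency, cdef.halfwidth_ms)

    ref_amplitude = ref_latency = None
    if cdef.reference is not None:
        ref = cdef.reference
        ref_w = cluster_waveform(erp, montage, ref.cluster)
        ref_latency, ref_point = find_peak(ref_w, erp.times_ms,
                                           ref.search_window_ms, ref.polarity)
        if ref_latency >= latency:
            warnings.warn(
                f"{cdef.name}: reference peak ({ref.name}, {ref_latency:g} ms) "
                f"does not precede the component peak ({latency:g} ms)",
                RuntimeWarning, stacklevel=2)
        ref_amplitude = ref_point if cdef.point_reference else adaptive_mean(
            ref_w, erp.times_ms, ref_latency, ref.halfwidth_ms)
        amplitude -= ref_amplitude
    return ComponentMeasure(component=cdef.name, subject=erp.subject_id,
                            condition=erp.condition, amplitude_uv=amplitude,
                            peak_latency_ms=latency,
                            reference_amplitude_uv=ref_amplitude,
                            reference_latency_ms=ref_latency,
                            n_trials=erp.n_trials_averaged)


def measures_to_frame(measures: Iterable[ComponentMeasure]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in measures])


@dataclass(frozen=True)
class ComponentContrast:
    """Distinct vs pooled-similar paired contrast for one component."""

    component: str
    distinct_mean_uv: float
    similar_mean_uv: float
    test: TTestResult
    #: paired t of similar_1 vs similar_2 (the pooling-equivalence check)
    similar_equivalence: TTestResult | None = None


def component_contrast(measures: Iterable[ComponentMeasure], component: str,
                       similar_condition: str = "similar") -> ComponentContrast:
    """Paired t of per-subject amplitudes, distinct vs (pooled) similar.

    ``similar_condition`` names the measurement taken on the pooled
    similar-categories ERP; when per-category measurements (``similar_1``,
    ``similar_2``) are also present, their paired equivalence test is
    reported alongside.
    """
    frame = measures_to_frame(measures)
    frame = frame[frame["component"] == component]
    wide = frame.pivot(index="subject", columns="condition", values="amplitude_uv")
    for needed in ("distinct", similar_condition):
        if needed not in wide.columns:
            raise ValueError(f"missing condition {needed!r} for component "
                             f"{component!r}")
    paired = wide.dropna(subset=["distinct", similar_condition])
    test = paired_t(paired["distinct"], paired[similar_condition])
    equivalence = None
    if {"similar_1", "similar_2"} <= set(wide.columns):
        both = wide.dropna(subset=["similar_1", "similar_2"])
        if len(both) >= 2:
            equivalence = paired_t(both["similar_1"], both["similar_2"])
    return ComponentContrast(component=component,
                             distinct_mean_uv=float(paired["distinct"].mean()),
                             similar_mean_uv=float(paired[similar_condition].mean()),
                             test=test, similar_equivalence=equivalence)
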