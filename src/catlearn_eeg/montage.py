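"""Electrode montage: component clusters and decoding regions.

The canonical montage covers a 256-channel geodesic net.  Four electrode
clusters quantify the ERP components (medial frontal 12-channel MFN cluster,
posterior-parietal 17-channel P3b cluster, and two 22-channel lateral
inferior anterior clusters for the left/right LIAN), and ten scalp regions
feed the decoding analysis: left/right frontal, medial prefrontal, medial
frontal, posterior parietal, left/right temporoparietal, and left/right/
medial occipital.

The published cluster memberships exist only as sensor-layout figures, so the
default assignment here is a synthetic-but-plausible partition of the channel
list into regions of the stated sizes, with each component cluster nested in
the matching region; it is fully user-overridable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .config import ConfigError

#: canonical cluster sizes in the 256-channel montage
CANONICAL_CLUSTER_SIZES = {"MFN": 12, "P3b": 17, "LIAN_left": 22, "LIAN_right": 22}

#: region order used for decoding-matrix columns (fixed everywhere)
REGION_NAMES = (
    "left_frontal",
    "right_frontal",
    "medial_prefrontal",
    "medial_frontal",
    "posterior_parietal",
    "left_temporoparietal",
    "right_temporoparietal",
    "left_occipital",
    "right_occipital",
    "medial_occipital",
)

# region sizes for the default 256-channel montage (sum 198; the remaining 58
# channels model the face/neck ring that is excluded from scalp analyses)
_DEFAULT_REGION_SIZES = {
    "left_frontal": 22,
    "right_frontal": 22,
    "medial_prefrontal": 16,
    "medial_frontal": 16,
    "posterior_parietal": 20,
    "left_temporoparietal": 24,
    "right_temporoparietal": 24,
    "left_occipital": 18,
    "right_occipital": 18,
    "medial_occipital": 18,
}

#: which region hosts each component cluster
_CLUSTER_HOST_REGION = {
    "MFN": "medial_frontal",
    "P3b": "posterior_parietal",
    "LIAN_left": "left_frontal",
    "LIAN_right": "right_frontal",
}


@dataclass
class Montage:
    """Channel labels plus cluster and region memberships.

    ``clusters`` maps component-cluster names to channel-label subsets;
    ``regions`` maps the ten decoding regions likewise.  Channels belonging to
    no region (outer ring) are available as the zero-sum counterweight pool
    for synthetic topographies.
    """

    channel_labels: Sequence[str]
    clusters: Mapping[str, Sequence[str]]
    regions: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ConfigError("Montage channel labels must be unique")
        self._index = {label: i for i, label in enumerate(labels)}
        for group_kind, groups in (("cluster", self.clusters), ("region", self.regions)):
            for name, members in groups.items():
                missing = [ch for ch in members if ch not in self._index]
                if missing:
                    raise ConfigError(
                        f"Montage {group_kind} {name!r} references unknown channels "
                        f"{missing[:5]}")
                if len(set(members)) != len(members):
                    raise ConfigError(f"Montage {group_kind} {name!r} has duplicate channels")
        unknown = set(self.regions) - set(REGION_NAMES)
        if unknown:
            raise ConfigError(f"Unknown region names: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def region_names(self) -> tuple[str, ...]:
        """Regions in canonical order (only those present in this montage)."""
        return tuple(name for name in REGION_NAMES if name in self.regions)

    def channel_indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self._index[label] for label in labels], dtype=int)

    def cluster_indices(self, cluster: str) -> np.ndarray:
        if cluster not in self.clusters:
            raise ConfigError(f"Montage has no cluster {cluster!r}; "
                              f"available: {sorted(self.clusters)}")
        return self.channel_indices(self.clusters[cluster])

    def region_indices(self, region: str) -> np.ndarray:
        if region not in self.regions:
            raise ConfigError(f"Montage has no region {region!r}; "
                              f"available: {sorted(self.regions)}")
        return self.channel_indices(self.regions[region])

    def free_channel_indices(self) -> np.ndarray:
        """Channels in no region and no cluster (counterweight pool)."""
        used: set[str] = set()
        for members in self.clusters.values():
            used.update(members)
        for members in self.regions.values():
            used.update(members)
        return np.array([i for label, i in self._index.items() if label not in used],
                        dtype=int)

    def check_canonical(self) -> None:
        """Assert the stated cluster sizes of the default 256-channel montage."""
        for name, size in CANONICAL_CLUSTER_SIZES.items():
            if name not in self.clusters:
                raise ConfigError(f"Canonical montage must define cluster {name!r}")
            if len(self.clusters[name]) != size:
                raise ConfigError(
                    f"Cluster {name!r} has {len(self.clusters[name])} channels, "
                    f"expected {size}")
        missing = set(REGION_NAMES) - set(self.regions)
        if missing:
            raise ConfigError(f"Canonical montage missing regions {sorted(missing)}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channel_labels": list(self.channel_labels),
            "clusters": {k: list(v) for k, v in self.clusters.items()},
            "regions": {k: list(v) for k, v in self.regions.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Montage":
        for key in ("channel_labels", "clusters", "regions"):
            if key not in data:
                raise ConfigError(f"Montage definition missing field {key!r}")
        return cls(channel_labels=list(data["channel_labels"]),
                   clusters={k: list(v) for k, v in data["clusters"].items()},
                   regions={k: list(v) for k, v in data["regions"].items()})

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _build(n_channels: int, region_sizes: Mapping[str, int],
           cluster_sizes: Mapping[str, int]) -> Montage:
    total = sum(region_sizes.values())
    if total > n_channels:
        raise ConfigError(f"Region sizes sum to {total} > n_channels={n_channels}")
    labels = [f"E{i + 1}" for i in range(n_channels)]
    regions: dict[str, list[str]] = {}
    cursor = 0
    for name in REGION_NAMES:
        size = region_sizes[name]
        regions[name] = labels[cursor:cursor + size]
        cursor += size
    clusters = {}
    for cname, size in cluster_sizes.items():
        host = regions[_CLUSTER_HOST_REGION[cname]]
        if size > len(host):
            raise ConfigError(f"Cluster {cname!r} size {size} exceeds its host region "
                              f"({len(host)} channels)")
        clusters[cname] = host[:size]
    return Montage(channel_labels=labels, clusters=clusters, regions=regions)


def default_montage() -> Montage:
    """The default 256-channel montage with canonical cluster sizes."""
    montage = _build(256, _DEFAULT_REGION_SIZES, CANONICAL_CLUSTER_SIZES)
    montage.check_canonical()
    return montage


def scaled_montage(n_channels: int) -> Montage:
    """A proportionally scaled montage for reduced-size simulations.

    Region and cluster sizes shrink with ``n_channels / 256`` (each region
    keeps at least one channel, clusters at least one channel, and at least
    one free counterweight channel remains).  At ``n_channels=256`` this is
    the default montage.
    """
    if n_channels == 256:
        return default_montage()
    factor = n_channels / 256.0
    region_sizes = {name: max(1, round(size * factor))
                    for name, size in _DEFAULT_REGION_SIZES.items()}
    while sum(region_sizes.values()) > n_channels - 1:
        biggest = max(region_sizes, key=region_sizes.get)
        if region_sizes[biggest] == 1:
            raise ConfigError(f"n_channels={n_channels} too small for a 10-region montage")
        region_sizes[biggest] -= 1
    cluster_sizes = {}
    for cname, size in CANONICAL_CLUSTER_SIZES.items():
        host = region_sizes[_CLUSTER_HOST_REGION[cname]]
        cluster_sizes[cname] = min(host, max(1, round(size * factor)))
    return _build(n_channels, region_sizes, cluster_sizes)


def component_topography(montage: Montage, cluster: str, n_channels: int | None = None,
                         zero_sum: bool = True) -> np.ndarray:
    """Weight-1 topography on ``cluster``, optionally balanced to zero sum.

    With ``zero_sum`` the counterweight is spread uniformly over the free
    (no-region, no-cluster) channels, so average referencing leaves the
    component untouched and no other cluster or region picks up leakage.
    """
    n = montage.n_channels if n_channels is None else n_channels
    topo = np.zeros(n)
    idx = montage.cluster_indices(cluster)
    topo[idx] = 1.0
    if zero_sum:
        free = montage.free_channel_indices()
        if len(free) == 0:
            raise ConfigError("zero-sum topography requires free channels outside all "
                              "regions and clusters")
        topo[free] = -len(idx) / len(free)
    return topo
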