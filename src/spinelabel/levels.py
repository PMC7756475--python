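"""Canonical vertebral level naming and the :class:`CentroidSet` container.

The spine is modelled as 24 vertebral bodies (C1-C7, T1-T12, L1-L5) plus two
sacral landmarks (S1, S2).  Network channels are numbered 1..27: channels
1-26 map onto the anatomical levels in superior-to-inferior order and
channel 27 is the null/background channel.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

CERVICAL = tuple(f"C{i}" for i in range(1, 8))
THORACIC = tuple(f"T{i}" for i in range(1, 13))
LUMBAR = tuple(f"L{i}" for i in range(1, 6))
SACRAL = ("S1", "S2")

#: All 26 canonical levels, superior to inferior.
LEVEL_NAMES: tuple[str, ...] = CERVICAL + THORACIC + LUMBAR + SACRAL

#: level name -> 0-based channel index (channel 26 is the null channel).
CHANNEL_OF: dict[str, int] = {name: i for i, name in enumerate(LEVEL_NAMES)}
N_CHANNELS = len(LEVEL_NAMES) + 1  # 26 anatomical + 1 null
NULL_CHANNEL = N_CHANNELS - 1

#: Region groupings by 1-based class index: cervical 1-7, thoracic 8-19,
#: lumbar 20-24, sacral 25-26.
REGIONS: dict[str, tuple[str, ...]] = {
    "cervical": CERVICAL,
    "thoracic": THORACIC,
    "lumbar": LUMBAR,
    "sacral": SACRAL,
}

#: Anomalous level names understood by the phantom generator.  They have no
#: channel of their own: the network's label space is fixed at 26 levels.
ANOMALOUS_NAMES = ("T13", "L6")


def anatomical_order(name: str) -> int:
    """Sort key placing levels superior-to-inferior, anomalies interleaved.

    ``T13`` sits between T12 and L1; ``L6`` between L5 and S1.
    """
    if name in CHANNEL_OF:
        return 2 * CHANNEL_OF[name]
    if name == "T13":
        return 2 * CHANNEL_OF["T12"] + 1
    if name == "L6":
        return 2 * CHANNEL_OF["L5"] + 1
    raise KeyError(f"unknown vertebral level name: {name!r}")


def validate_level_name(name: str) -> str:
    if name not in CHANNEL_OF and name not in ANOMALOUS_NAMES:
        raise ValueError(f"unknown vertebral level name: {name!r}")
    return name


@dataclass
class CentroidSet:
    """Ordered mapping from level name to a 3D world coordinate in mm.

    Coordinates use the package-wide (SI, AP, LR) axis convention.
    ``flags`` marks levels with free-text annotations (e.g. ``"anomaly"``).
    """

    coords: dict[str, np.ndarray] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = {}
        for name in sorted(self.coords, key=anatomical_order):
            validate_level_name(name)
            xyz = np.asarray(self.coords[name], dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"level {name}: coordinate must be 3 finite mm values")
            ordered[name] = xyz
        self.coords = ordered

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, Iterable[float]]] | Mapping) -> "CentroidSet":
        if isinstance(items, Mapping):
            items = items.items()
        coords: dict[str, np.ndarray] = {}
        for name, xyz in items:
            if name in coords:
                raise ValueError(f"duplicate level name: {name!r}")
            coords[name] = np.asarray(xyz, dtype=float)
        return cls(coords)

    def __len__(self) -> int:
        return len(self.coords)

    def __contains__(self, name: str) -> bool:
        return name in self.coords

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[name]

    def __iter__(self):
        return iter(self.coords)

    def items(self):
        return self.coords.items()

    def names(self) -> list[str]:
        return list(self.coords)

    def array(self) -> np.ndarray:
        """(n, 3) array of coordinates in anatomical order."""
        if not self.coords:
            return np.empty((0, 3))
        return np.stack(list(self.coords.values()))

    def subset(self, names: Iterable[str]) -> "CentroidSet":
        keep = set(names)
        out = CentroidSet({k: v.copy() for k, v in self.coords.items() if k in keep})
        out.flags = {k: v for k, v in self.flags.items() if k in keep}
        return out

    def translated(self, offset) -> "CentroidSet":
        off = np.asarray(offset, dtype=float)
        out = CentroidSet({k: v + off for k, v in self.coords.items()})
        out.flags = dict(self.flags)
        return out
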