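"""The in-memory CT volume container and its geometry conventions.

Package-wide conventions (used by every module):

* axis order ``(SI, AP, LR)`` — axis 0 runs superior -> inferior, axis 1
  anterior -> posterior, axis 2 left -> right;
* 0-based voxel indices; world coordinates in mm are voxel centers,
  ``world = origin + index * spacing``;
* crop intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AX_SI, AX_AP, AX_LR = 0, 1, 2


@dataclass
class CTVolume:
    """A 3D scalar volume in Hounsfield units with voxel geometry."""

    data: np.ndarray  # (SI, AP, LR), HU
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (SI, AP, LR)")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be 3 positive mm values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be 3 mm values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx) -> np.ndarray:
        """Voxel index (possibly fractional) -> world mm."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz) -> np.ndarray:
        """World mm -> fractional voxel index."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def extent_mm(self) -> np.ndarray:
        """Physical size per axis (edge-to-edge over voxel centers)."""
        return (np.asarray(self.shape) - 1) * self.spacing
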