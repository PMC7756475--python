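"""File formats: NIfTI volumes, centroid annotations, centerlines, reports.

Internally everything is (SI, AP, LR); NIfTI stores (LR, AP, SI) so data
is transposed on the way in/out and voxel spacing is carried in the
header.  Annotation files map level names to 3D world coordinates in mm
(never voxel indices), as JSON ``{"L1": [si, ap, lr], ...}`` or CSV with
columns ``level,si_mm,ap_mm,lr_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .levels import CentroidSet, validate_level_name
from .volume import CTVolume


def save_volume(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz), spacing in the header."""
    data = np.ascontiguousarray(volume.data.transpose(2, 1, 0))
    affine = np.diag([*volume.spacing[::-1], 1.0])
    affine[:3, 3] = volume.origin[::-1]
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(volume.spacing[::-1]))
    nib.save(img, str(path))


def load_volume(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    zooms = np.asarray(img.header.get_zooms()[:3], float)[::-1]
    origin = np.asarray(img.affine[:3, 3], float)[::-1]
    return CTVolume(data, zooms, origin)


def save_mask(mask: np.ndarray, spacing, path) -> None:
    save_volume(CTVolume(mask.astype(np.uint8), spacing), path)


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    vol = load_volume(path)
    return vol.data > 0.5, vol.spacing


def write_annotations(centroids: CentroidSet, path) -> None:
    """JSON or CSV by extension; coordinates are world mm."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {name: [float(v) for v in xyz]
                   for name, xyz in centroids.items()}
        path.write_text(json.dumps(payload, indent=1))
    else:
        rows = [
            {"level": name, "si_mm": xyz[0], "ap_mm": xyz[1], "lr_mm": xyz[2]}
            for name, xyz in centroids.items()
        ]
        pd.DataFrame(rows, columns=["level", "si_mm", "ap_mm", "lr_mm"]).to_csv(
            path, index=False, float_format="%.17g"
        )


def read_annotations(path) -> CentroidSet:
    """Read JSON/CSV centroid annotations with name validation and
    canonical anatomical ordering."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    items: list[tuple[str, list[float]]] = []
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        items = list(payload.items())
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
        required = {"level", "si_mm", "ap_mm", "lr_mm"}
        if not required.issubset(frame.columns):
            raise ValueError(
                f"annotation CSV needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        for _, row in frame.iterrows():
            items.append((str(row["level"]),
                          [row["si_mm"], row["ap_mm"], row["lr_mm"]]))
    for name, xyz in items:
        validate_level_name(name)
        if len(xyz) != 3 or not np.all(np.isfinite(np.asarray(xyz, float))):
            raise ValueError(f"level {name}: malformed coordinate row {xyz!r}")
    return CentroidSet.from_items(items)


def write_centerline(centerline, path) -> None:
    rows = pd.DataFrame({
        "slice": centerline.slices,
        "ap_mm": centerline.pos_mm[:, 0],
        "lr_mm": centerline.pos_mm[:, 1],
    })
    rows.to_csv(path, index=False, float_format="%.17g")


def read_centerline(path, spacing):
    from .canal import Centerline

    frame = pd.read_csv(path)
    return Centerline(int(frame["slice"].iloc[0]),
                      frame[["ap_mm", "lr_mm"]].to_numpy(float),
                      np.asarray(spacing, float))
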