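"""From per-arm heatmaps to named 3D vertebral centroids.

Inference fuses the raw sigmoid outputs of the projection variants by
element-wise summation, keeps only values strictly above 1.0, extracts a
2D coordinate per channel and view, and combines the views into 3D mm
coordinates (SI averaged across views, AP from the sagittal view, LR from
the coronal view).  Predictions of several models are ensembled by
majority-vote presence and component-wise median coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .levels import LEVEL_NAMES, NULL_CHANNEL, CentroidSet
from .projection import ImageGeometry

FUSION_THRESHOLD = 1.0


@dataclass
class LevelPrediction:
    """One named level: 3D mm coordinate plus per-view provenance."""

    level: str
    xyz_mm: np.ndarray
    view_px: dict  # view -> (row, col)
    confidence: float
    source: str = "single model"


def fuse_cips(raw_outputs: list[np.ndarray],
              threshold: float = FUSION_THRESHOLD) -> np.ndarray:
    """Sum raw per-arm (H, W, C) outputs over projection variants and zero
    everything not strictly above the threshold.

    With a single sigmoid-range input every value is <= 1.0, so a
    single-variant list fuses to all zeros (documented behavior: no
    detections without multiple variants or a lower threshold).
    """
    if not raw_outputs:
        raise ValueError("no raw outputs to fuse")
    shapes = {a.shape for a in map(np.asarray, raw_outputs)}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between raw outputs: {shapes}")
    fused = np.sum([np.asarray(a, np.float32) for a in raw_outputs], axis=0)
    return np.where(fused > threshold, fused, 0.0).astype(np.float32)


def decode_heatmaps(fused: np.ndarray, presence_min_mass: float = 1e-6):
    """Per-channel 2D coordinate + confidence from a fused (H, W, C) array.

    A channel is present when its suprathreshold mass reaches
    ``presence_min_mass``; its coordinate is the center of mass of the
    connected component containing the global maximum.  Ties between equal
    maxima break toward the superior (lower row index) one.  The null
    channel is never decoded.
    """
    fused = np.asarray(fused)
    if np.any(fused < 0):
        raise ValueError("fused array must be non-negative")
    out: dict[str, tuple[np.ndarray, float]] = {}
    for ch, name in enumerate(LEVEL_NAMES):
        if ch == NULL_CHANNEL:
            continue
        plane = fused[:, :, ch]
        mass = float(plane.sum())
        if mass < presence_min_mass or mass == 0.0:
            continue
        peak_val = plane.max()
        # argmax scans row-major, so the first hit is the most superior
        peak = np.unravel_index(int(np.argmax(plane)), plane.shape)
        comps, _ = ndimage.label(plane > 0)
        comp_mask = comps == comps[peak]
        weights = np.where(comp_mask, plane, 0.0)
        com = ndimage.center_of_mass(weights)
        out[name] = (np.array(com, dtype=float), float(peak_val))
    return out


def combine_views(sag: dict, cor: dict, geom_sag: ImageGeometry,
                  geom_cor: ImageGeometry) -> CentroidSet:
    """Merge per-view 2D decodings into 3D world-mm centroids.

    A level is emitted only if present in both views; SI is the mean of
    the two views' SI estimates, AP comes from the sagittal view and LR
    from the coronal view.
    """
    if geom_sag.view != "sagittal" or geom_cor.view != "coronal":
        raise ValueError("geometries must be (sagittal, coronal), registered")
    if abs(geom_sag.si_step - geom_cor.si_step) > 1e-9:
        raise ValueError("views disagree on SI sampling")
    coords = {}
    for name, (px_s, conf_s) in sag.items():
        if name not in cor:
            continue
        px_c, conf_c = cor[name]
        si_s, ap = geom_sag.pixel_to_mm(px_s[0], px_s[1])
        si_c, lr = geom_cor.pixel_to_mm(px_c[0], px_c[1])
        coords[name] = np.array([(si_s + si_c) / 2.0, ap, lr])
    return CentroidSet(coords)


def predict_centroids(per_arm_outputs: list[tuple[np.ndarray, np.ndarray]],
                      geom_sag: ImageGeometry, geom_cor: ImageGeometry,
                      presence_min_mass: float = 1e-6,
                      threshold: float = FUSION_THRESHOLD) -> CentroidSet:
    """Full single-model decode: fuse projection variants per arm, decode
    each arm, combine views."""
    fused_s = fuse_cips([o[0] for o in per_arm_outputs], threshold)
    fused_c = fuse_cips([o[1] for o in per_arm_outputs], threshold)
    sag = decode_heatmaps(fused_s, presence_min_mass)
    cor = decode_heatmaps(fused_c, presence_min_mass)
    return combine_views(sag, cor, geom_sag, geom_cor)


def ensemble_predictions(per_model: list[CentroidSet]) -> CentroidSet:
    """Median-coordinate ensemble with strict-majority presence voting."""
    if not per_model:
        raise ValueError("empty model list")
    n = len(per_model)
    coords = {}
    for name in LEVEL_NAMES:
        members = [m[name] for m in per_model if name in m]
        if len(members) * 2 > n:
            coords[name] = np.median(np.stack(members), axis=0)
    return CentroidSet(coords)
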