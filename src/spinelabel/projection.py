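"""Custom intensity projections (CIPs), label stacks, and augmentation.

A CIP collapses the canal-tracking VOI of a CT volume into a 2D image per
view, combining average and maximum intensity projections:

    x_view = w * AIP(VOI) + MIP(VOI) + (w - 2) * MIP(VOI~)

with the default weight ``w = 2``, under which the complement term
vanishes and the image depends on VOI voxels only.  HU values are clipped
to a normalization window and scaled to [0, 1] *before* projection, which
keeps implant intensities from dominating the MIP.  The sagittal view
projects along LR onto an (SI, AP) image; the coronal view projects along
AP onto (SI, LR); the two share the SI sampling.

Ground-truth labels are per-channel 2D Gaussians (sigma in px) at the
projected centroid, peak-scaled to 225 intensity levels, thresholded
strictly above 75 and stored as Boolean masks; channel 27 is the
background complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .canal import VOISpec
from .levels import LEVEL_NAMES, N_CHANNELS, NULL_CHANNEL, CentroidSet
from .volume import AX_AP, AX_LR, AX_SI, CTVolume

log = logging.getLogger(__name__)

DEFAULT_CANVAS = (608, 192)
DEFAULT_WINDOWS = ((-1000.0, 1600.0), (-200.0, 800.0))


@dataclass
class ImageGeometry:
    """Affine pixel -> mm map of one projection image.

    Pixel ``(row, col)`` maps to ``(si, t)`` mm where ``t`` is AP for the
    sagittal view and LR for the coronal view.  ``content_box`` records
    where the unpadded content sits on the canvas so padding round-trips
    exactly.
    """

    si_origin: float  # mm of the first *content* row
    si_step: float
    t_origin: float  # mm of the first *content* column
    t_step: float
    view: str  # "sagittal" | "coronal"
    content_box: tuple[int, int, int, int] | None = None  # r0, h, c0, w

    def _offsets(self) -> tuple[int, int]:
        if self.content_box is None:
            return 0, 0
        return self.content_box[0], self.content_box[2]

    def pixel_to_mm(self, row, col) -> tuple:
        r0, c0 = self._offsets()
        return (self.si_origin + (np.asarray(row) - r0) * self.si_step,
                self.t_origin + (np.asarray(col) - c0) * self.t_step)

    def mm_to_pixel(self, si_mm, t_mm) -> tuple:
        r0, c0 = self._offsets()
        return ((np.asarray(si_mm) - self.si_origin) / self.si_step + r0,
                (np.asarray(t_mm) - self.t_origin) / self.t_step + c0)

    def project_centroid(self, xyz_mm) -> tuple[float, float]:
        """World (SI, AP, LR) mm -> (row, col) px in this view."""
        si = xyz_mm[AX_SI]
        t = xyz_mm[AX_AP] if self.view == "sagittal" else xyz_mm[AX_LR]
        r, c = self.mm_to_pixel(si, t)
        return float(r), float(c)


@dataclass
class CIPPair:
    """Registered sagittal + coronal projection images with geometry."""

    sagittal: np.ndarray
    coronal: np.ndarray
    window: tuple[float, float]
    w: float
    anterior_constrained: bool
    geometry_sagittal: ImageGeometry
    geometry_coronal: ImageGeometry


@dataclass
class LabelStack:
    """Per-view (H, W, 27) Boolean channel labels."""

    sagittal: np.ndarray
    coronal: np.ndarray
    sigma: float
    channel_names: tuple[str, ...] = LEVEL_NAMES


def resample_volume(volume: CTVolume, target_slice_mm: float = 2.5) -> CTVolume:
    """Order-1 (linear) resampling of the SI axis to ``target_slice_mm``.

    In-plane sampling is untouched and world coordinates of the content are
    preserved (the SI origin stays fixed; new slice centers lie on the old
    physical extent).  A volume already at the target spacing is returned
    unchanged.
    """
    if target_slice_mm <= 0:
        raise ValueError("target slice thickness must be positive")
    sp = volume.spacing
    if sp[AX_SI] == target_slice_mm:
        return volume
    extent = (volume.shape[AX_SI] - 1) * sp[AX_SI]
    n_new = int(np.floor(extent / target_slice_mm)) + 1
    src = np.arange(n_new) * target_slice_mm / sp[AX_SI]
    i0 = np.floor(src).astype(int)
    frac = (src - i0).astype(np.float32)
    i1 = np.minimum(i0 + 1, volume.shape[AX_SI] - 1)
    data = (
        volume.data[i0] * (1.0 - frac)[:, None, None]
        + volume.data[i1] * frac[:, None, None]
    ).astype(np.float32)
    spacing = sp.copy()
    spacing[AX_SI] = target_slice_mm
    return CTVolume(data, spacing, volume.origin.copy())


def _normalize(data: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValueError("normalization window must have lower < upper")
    return ((np.clip(data, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def form_cip(volume: CTVolume, voi: VOISpec, view: str,
             window=DEFAULT_WINDOWS[0], w: float = 2.0,
             rescale: bool = True) -> tuple[np.ndarray, ImageGeometry]:
    """Project one view of the VOI into a CIP image.

    Returns the image and its pixel->mm geometry.  Columns with no VOI
    voxel are 0 (logged at debug level).  With ``rescale`` the combined
    image is min-max scaled to [0, 1].
    """
    if view not in ("sagittal", "coronal"):
        raise ValueError(f"unknown view: {view!r}")
    norm = _normalize(volume.data, window)
    mask = voi.mask(volume.shape)
    proj_ax = AX_LR if view == "sagittal" else AX_AP
    t_ax = AX_AP if view == "sagittal" else AX_LR

    cl = voi.centerline
    rows = cl.slices
    rows = rows[(rows >= 0) & (rows < volume.shape[AX_SI])]
    # shared in-plane extent: the union of (unconstrained) window bounds
    base = replace(voi, anterior_constrained=False)
    wins = base.windows(volume.shape)
    col_lo = int(wins[:, 0 if t_ax == AX_AP else 2].min())
    col_hi = int(wins[:, 1 if t_ax == AX_AP else 3].max())

    sub = norm[rows]
    msub = mask[rows]
    cnt = msub.sum(axis=proj_ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        aip = np.where(cnt > 0, (sub * msub).sum(axis=proj_ax) / cnt, 0.0)
    mip = np.where(msub, sub, -np.inf).max(axis=proj_ax)
    mip = np.where(cnt > 0, mip, 0.0)
    img = w * aip + mip
    if w != 2.0:
        comp = np.where(~msub, sub, -np.inf).max(axis=proj_ax)
        comp = np.where(np.isfinite(comp), comp, 0.0)
        img = img + (w - 2.0) * comp
    img = np.where(cnt > 0, img, 0.0)
    if np.any(cnt.sum(axis=0) == 0):
        log.debug("form_cip(%s): %d empty columns set to 0", view,
                  int(np.sum(cnt.sum(axis=0) == 0)))
    img = img[:, col_lo:col_hi]
    if rescale:
        ptp = img.max() - img.min()
        img = (img - img.min()) / ptp if ptp > 0 else np.zeros_like(img)

    sp = volume.spacing
    geom = ImageGeometry(
        si_origin=float(volume.origin[AX_SI] + rows[0] * sp[AX_SI]),
        si_step=float(sp[AX_SI]),
        t_origin=float(volume.origin[t_ax] + col_lo * sp[t_ax]),
        t_step=float(sp[t_ax]),
        view=view,
    )
    return img.astype(np.float32), geom


def form_cip_pair(volume: CTVolume, voi: VOISpec, window, w: float = 2.0,
                  rescale: bool = True) -> CIPPair:
    sag, gs = form_cip(volume, voi, "sagittal", window, w, rescale)
    cor, gc = form_cip(volume, voi, "coronal", window, w, rescale)
    return CIPPair(sag, cor, tuple(window), w, voi.anterior_constrained, gs, gc)


def select_cip_set(volume: CTVolume, voi: VOISpec,
                   windows=DEFAULT_WINDOWS,
                   anterior_window=DEFAULT_WINDOWS[1],
                   w: float = 2.0) -> list[CIPPair]:
    """The three projection variants used per scan: two full-VOI pairs at
    two distinct windows plus one anterior-constrained pair."""
    if len(set(map(tuple, windows))) != len(tuple(windows)):
        raise ValueError("duplicate window configurations")
    full = replace(voi, anterior_constrained=False)
    ant = replace(voi, anterior_constrained=True)
    pairs = [form_cip_pair(volume, full, win, w) for win in windows]
    pairs.append(form_cip_pair(volume, ant, anterior_window, w))
    return pairs


def pad_and_register(image: np.ndarray, geometry: ImageGeometry,
                     canvas=DEFAULT_CANVAS) -> tuple[np.ndarray, ImageGeometry]:
    """Zero-pad onto the canvas, content centered, geometry updated so that
    pixel -> mm round-trips exactly.  The SI canvas capacity in mm is
    logged."""
    h, w = image.shape
    ch, cw = canvas
    if h > ch:
        raise ValueError(f"image SI extent {h} px exceeds canvas {ch} px")
    if w > cw:
        raise ValueError(f"image in-plane extent {w} px exceeds canvas {cw} px")
    r0 = (ch - h) // 2
    c0 = (cw - w) // 2
    out = np.zeros((ch, cw), dtype=np.float32)
    out[r0:r0 + h, c0:c0 + w] = image
    if geometry.content_box is not None:
        raise ValueError("image is already padded onto a canvas")
    geom = replace(geometry, content_box=(r0, h, c0, w))
    log.debug("canvas SI capacity: %.1f mm (%d px at %.3f mm/px)",
              ch * geometry.si_step, ch, geometry.si_step)
    return out, geom


def unpad(image: np.ndarray, geometry: ImageGeometry) -> np.ndarray:
    """Recover the original content from a padded canvas, bit-exactly."""
    if geometry.content_box is None:
        return image
    r0, h, c0, w = geometry.content_box
    return image[r0:r0 + h, c0:c0 + w]


def pad_pair(pair: CIPPair, canvas=DEFAULT_CANVAS) -> CIPPair:
    sag, gs = pad_and_register(pair.sagittal, pair.geometry_sagittal, canvas)
    cor, gc = pad_and_register(pair.coronal, pair.geometry_coronal, canvas)
    return replace(pair, sagittal=sag, coronal=cor,
                   geometry_sagittal=gs, geometry_coronal=gc)


def gaussian_blob_radius(sigma: float = 2.0, levels: float = 225.0,
                         cut: float = 75.0) -> float:
    """Radius (px) of the Boolean blob: sigma * sqrt(2 ln(levels / cut))."""
    return float(sigma * np.sqrt(2.0 * np.log(levels / cut)))


def gaussian_label_image(shape, center_px, sigma: float = 2.0,
                         levels: float = 225.0, cut: float = 75.0) -> np.ndarray:
    r, c = center_px
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    blob = levels * np.exp(-d2 / (2.0 * sigma * sigma))
    return blob > cut  # strictly-greater tie-break


def make_gaussian_labels(centroids: CentroidSet, geometry: ImageGeometry,
                         shape, sigma: float = 2.0, levels: float = 225.0,
                         cut: float = 75.0) -> np.ndarray:
    """One view's (H, W, 27) Boolean label stack.

    Each anatomical channel gets an isotropic Gaussian at the projected
    centroid, peak-scaled to ``levels`` and thresholded strictly above
    ``cut``; the null channel is the complement of the union.  Channels
    without a centroid are all-False.  Anomalous level names (no channel of
    their own) are skipped.
    """
    stack = np.zeros((shape[0], shape[1], N_CHANNELS), dtype=bool)
    for name, xyz in centroids.items():
        if name not in LEVEL_NAMES:
            continue
        r, c = geometry.project_centroid(xyz)
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(
                f"centroid {name} projects outside the canvas: ({r:.1f}, {c:.1f})"
            )
        stack[:, :, LEVEL_NAMES.index(name)] = gaussian_label_image(
            shape, (r, c), sigma, levels, cut
        )
    stack[:, :, NULL_CHANNEL] = ~np.any(stack[:, :, :NULL_CHANNEL], axis=2)
    return stack


def make_label_stack(pair: CIPPair, centroids: CentroidSet, sigma: float = 2.0,
                     levels: float = 225.0, cut: float = 75.0) -> LabelStack:
    sag = make_gaussian_labels(centroids, pair.geometry_sagittal,
                               pair.sagittal.shape, sigma, levels, cut)
    cor = make_gaussian_labels(centroids, pair.geometry_coronal,
                               pair.coronal.shape, sigma, levels, cut)
    return LabelStack(sag, cor, sigma)


def crop_augment(pair: CIPPair, labels: LabelStack, truth: CentroidSet,
                 increment_mm: float = 25.0, mode: str = "sup_to_inf",
                 canvas=None, sigma: float = 2.0) -> list[tuple[CIPPair, LabelStack]]:
    """Successive SI croppings of an (unpadded or padded) image pair.

    Each step shrinks the SI extent by ``increment_mm`` (from the superior
    end, the inferior end, or both ends toward the middle).  A cropping is
    emitted only if the span removed at that step contained at least one
    truth centroid.  Labels are recomputed on the re-registered geometry
    for the centroids that remain inside.
    """
    if increment_mm <= 0:
        raise ValueError("increment_mm must be positive")
    if mode not in ("sup_to_inf", "inf_to_sup", "medial"):
        raise ValueError(f"unknown crop mode: {mode!r}")
    gs = pair.geometry_sagittal
    sag = unpad(pair.sagittal, gs)
    cor = unpad(pair.coronal, pair.geometry_coronal)
    if canvas is None:
        canvas = pair.sagittal.shape
    si0 = gs.si_origin  # mm of content row 0
    step = gs.si_step
    h = sag.shape[0]
    si_vals = np.array([xyz[AX_SI] for _, xyz in truth.items()])
    names = truth.names()

    inc_px = max(int(round(increment_mm / step)), 1)
    out: list[tuple[CIPPair, LabelStack]] = []
    lo, hi = 0, h  # half-open row interval of remaining content
    while True:
        if mode == "sup_to_inf":
            new_lo, new_hi = lo + inc_px, hi
            removed = [(lo, new_lo)]
        elif mode == "inf_to_sup":
            new_lo, new_hi = lo, hi - inc_px
            removed = [(new_hi, hi)]
        else:  # medial: shrink both ends toward the scan midpoint
            half = max(inc_px // 2, 1)
            new_lo, new_hi = lo + half, hi - half
            removed = [(lo, new_lo), (new_hi, hi)]
        if new_hi - new_lo < 1:
            break
        rm_si = []
        for a, b in removed:
            rm_si.append((si0 + a * step, si0 + b * step))
        has_centroid = any(
            np.any((si_vals >= a) & (si_vals < b)) for a, b in rm_si
        ) if len(si_vals) else False
        lo, hi = new_lo, new_hi
        if not has_centroid:
            continue
        sub_geom_s = ImageGeometry(si0 + lo * step, step, gs.t_origin,
                                   gs.t_step, "sagittal")
        gc = pair.geometry_coronal
        sub_geom_c = ImageGeometry(si0 + lo * step, step, gc.t_origin,
                                   gc.t_step, "coronal")
        ps, gs2 = pad_and_register(sag[lo:hi], sub_geom_s, canvas)
        pc, gc2 = pad_and_register(cor[lo:hi], sub_geom_c, canvas)
        keep = [
            nm for nm, si in zip(names, si_vals)
            if si0 + lo * step - step / 2 <= si <= si0 + (hi - 1) * step + step / 2
        ]
        sub_truth = truth.subset(keep)
        new_pair = CIPPair(ps, pc, pair.window, pair.w,
                           pair.anterior_constrained, gs2, gc2)
        out.append((new_pair, make_label_stack(new_pair, sub_truth, sigma)))
    return out
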