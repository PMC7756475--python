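"""Spinal-canal centerline extraction and the volume of interest (VOI).

The canal centerline is the per-axial-slice center of mass of a canal
mask, in mm.  The VOI is a per-slice square window (default 55 x 55 px)
tracking the centerline over the canal's slice range; its anterior-
constrained variant keeps only voxels anterior to (and including) each
slice's canal centroid, which removes posterior vertebral processes from
coronal projections.

The canal segmenter itself is pluggable: any callable slice -> mask will
do, and precomputed masks can be supplied instead.  A small reference
convolutional segmenter trained with Dice loss and Adam is provided for
self-contained runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import AX_AP, AX_LR, AX_SI, CTVolume


@dataclass
class Centerline:
    """Per-axial-slice canal centroid over a contiguous slice interval."""

    slice_start: int
    pos_mm: np.ndarray  # (n, 2): (AP, LR) mm per slice
    spacing: np.ndarray  # volume voxel spacing (SI, AP, LR) mm

    def __post_init__(self) -> None:
        self.pos_mm = np.asarray(self.pos_mm, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.pos_mm.ndim != 2 or self.pos_mm.shape[1] != 2:
            raise ValueError("centerline positions must be (n, 2) (AP, LR) mm")
        if not np.all(np.isfinite(self.pos_mm)):
            raise ValueError("centerline coordinates must be finite")

    @property
    def n_slices(self) -> int:
        return len(self.pos_mm)

    @property
    def slices(self) -> np.ndarray:
        return np.arange(self.slice_start, self.slice_start + self.n_slices)


def extract_centerline(canal_mask: np.ndarray, spacing) -> Centerline:
    """Per-slice center of mass of the mask, in mm.

    Slices with an empty mask between populated neighbours are filled by
    linear interpolation; the returned interval spans the first to the
    last populated slice (no extrapolation beyond them).
    """
    mask = np.asarray(canal_mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    counts = mask.sum(axis=(1, 2))
    populated = np.nonzero(counts)[0]
    if populated.size == 0:
        raise ValueError("canal mask is empty on every slice")
    lo, hi = populated[0], populated[-1]
    ap_idx = np.arange(mask.shape[AX_AP], dtype=float)
    lr_idx = np.arange(mask.shape[AX_LR], dtype=float)
    sub = mask[lo:hi + 1]
    cnt = sub.sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ap = np.einsum("sij,i->s", sub, ap_idx) / cnt
        lr = np.einsum("sij,j->s", sub, lr_idx) / cnt
    filled = cnt > 0
    s = np.arange(len(cnt), dtype=float)
    ap = np.interp(s, s[filled], ap[filled])
    lr = np.interp(s, s[filled], lr[filled])
    pos_mm = np.column_stack([ap * spacing[AX_AP], lr * spacing[AX_LR]])
    return Centerline(int(lo), pos_mm, spacing)


def centerline_from_truth(centerline_rows: np.ndarray, spacing) -> Centerline:
    """Adapt a phantom's analytic (slice, AP mm, LR mm) table."""
    rows = np.asarray(centerline_rows, dtype=float)
    if len(rows) == 0:
        raise ValueError("empty centerline table")
    return Centerline(int(rows[0, 0]), rows[:, 1:3], np.asarray(spacing, float))


@dataclass
class VOISpec:
    """Square per-slice window of ``cross_section_px`` pixels tracking the
    centerline; optionally constrained to the anterior half."""

    centerline: Centerline
    cross_section_px: int = 55
    anterior_constrained: bool = False

    def __post_init__(self) -> None:
        if self.cross_section_px < 1:
            raise ValueError("cross_section_px must be >= 1")

    def center_indices(self) -> np.ndarray:
        """(n, 2) nearest-voxel (AP, LR) centers per slice."""
        sp = self.centerline.spacing
        return np.rint(
            self.centerline.pos_mm / np.array([sp[AX_AP], sp[AX_LR]])
        ).astype(int)

    def windows(self, shape) -> np.ndarray:
        """(n, 4) half-open per-slice bounds (ap_lo, ap_hi, lr_lo, lr_hi),
        clipped to the volume shape.  A 55 px window spans 27 px each side
        of the center; an even remainder goes anterior / right."""
        n = self.cross_section_px
        c = self.center_indices()
        ap_lo = c[:, 0] - n // 2
        ap_hi = ap_lo + n
        lr_lo = c[:, 1] - (n - 1) // 2
        lr_hi = lr_lo + n
        if self.anterior_constrained:
            # keep the anterior half, boundary at the centroid inclusive
            ap_hi = np.minimum(ap_hi, c[:, 0] + 1)
        out = np.column_stack([ap_lo, ap_hi, lr_lo, lr_hi])
        out[:, 0:2] = np.clip(out[:, 0:2], 0, shape[AX_AP])
        out[:, 2:4] = np.clip(out[:, 2:4], 0, shape[AX_LR])
        return out

    def mask(self, shape) -> np.ndarray:
        """Realize the VOI as a boolean volume of the given shape."""
        m = np.zeros(shape, dtype=bool)
        cl = self.centerline
        wins = self.windows(shape)
        for s, (al, ah, ll, lh) in zip(cl.slices, wins):
            if 0 <= s < shape[AX_SI]:
                m[s, al:ah, ll:lh] = True
        return m


def build_voi(centerline: Centerline, cross_section_px: int = 55,
              anterior_constrained: bool = False) -> VOISpec:
    if centerline.n_slices == 0:
        raise ValueError("empty centerline")
    return VOISpec(centerline, cross_section_px, anterior_constrained)


def centroid_error(predicted: Centerline, truth: Centerline):
    """Per-slice 2D Euclidean distance (mm) over shared slices + summary.

    Symmetric in its arguments; zero iff the centerlines coincide on the
    shared interval.
    """
    lo = max(predicted.slice_start, truth.slice_start)
    hi = min(predicted.slice_start + predicted.n_slices,
             truth.slice_start + truth.n_slices)
    if hi <= lo:
        raise ValueError("centerlines have no overlapping slices")
    p = predicted.pos_mm[lo - predicted.slice_start:hi - predicted.slice_start]
    t = truth.pos_mm[lo - truth.slice_start:hi - truth.slice_start]
    d = np.linalg.norm(p - t, axis=1)
    return {
        "slices": np.arange(lo, hi),
        "distance_mm": d,
        "mean": float(d.mean()),
        "sd": float(d.std()),
    }


# ------------------------------------------------------- reference segmenter

class CanalSegmenter:
    """Small convolutional slice -> mask segmenter (reference implementation).

    Three 5x5 conv layers with PReLU and a sigmoid head; trained with Dice
    loss and Adam.  Predictions are thresholded at 0.5; an empty mask is a
    valid output (centerline interpolation covers such slices).
    """

    def __init__(self, channels: int = 8, seed: int = 0):
        from . import nn

        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv2d(1, channels, 5, rng)
        self.a1 = nn.PReLU(channels)
        self.c2 = nn.Conv2d(channels, channels, 5, rng)
        self.a2 = nn.PReLU(channels)
        self.c3 = nn.Conv2d(channels, 1, 5, rng)
        self.seed = seed
        self.history: list[float] = []

    def params(self):
        return (self.c1.params() + self.a1.params() + self.c2.params()
                + self.a2.params() + self.c3.params())

    def _forward(self, x):
        from . import nn

        h = self.a1(self.c1(x))
        h = self.a2(self.c2(h))
        return nn.sigmoid(self.c3(h))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Predict a boolean canal mask for one 2D slice (HU or normalized)."""
        from . import nn

        x = _normalize_slice(np.asarray(image, np.float32))
        with nn.no_grad():
            p = self._forward(nn.Tensor(x[None, None]))
        return p.data[0, 0] > 0.5


def _normalize_slice(img: np.ndarray) -> np.ndarray:
    return np.clip((img + 200.0) / 1200.0, 0.0, 1.0)


def train_canal_segmenter(slices, masks, epochs: int = 12, lr: float = 3e-3,
                          batch_size: int = 16, seed: int = 0,
                          channels: int = 8) -> CanalSegmenter:
    """Train the reference segmenter on paired 2D slices and masks.

    Dice loss, Adam optimizer, seeded and deterministic.  Contract: on
    held-out phantom slices the predicted-mask centroid should land within
    2 voxels (mean) of the true canal centroid.
    """
    from . import nn

    slices = [np.asarray(s, np.float32) for s in slices]
    masks = [np.asarray(m, bool) for m in masks]
    if len(slices) == 0 or len(slices) != len(masks):
        raise ValueError("need equally many training slices and masks")
    model = CanalSegmenter(channels=channels, seed=seed)
    x = np.stack([_normalize_slice(s) for s in slices])[:, None]
    y = np.stack(masks)[:, None].astype(np.float32)
    opt = nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed)
    n = len(slices)
    for _ in range(epochs):
        order = rng.permutation(n)
        ep = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = model._forward(nn.Tensor(x[idx]))
            loss = nn.soft_dice_loss(pred, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        model.history.append(float(np.mean(ep)))
    return model


def segment_volume(model, volume: CTVolume) -> np.ndarray:
    """Apply a slice segmenter to every axial slice of a volume."""
    return np.stack([model(volume.data[s]) for s in range(volume.shape[AX_SI])])
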