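"""Synthetic annotated CT spine phantoms.

Emulates the statistical and geometric structure of radiotherapy simulation
CT scans: ~1.17 mm in-plane pixels with 2.5 mm slices, variable scan
length, 24 vertebral bodies plus two sacral landmarks, intervertebral
spacing that widens from the cervical to the lumbar spine, optional
anomalous vertebral counts (L6, T13, four lumbar), titanium implants and
intravenous contrast.  Every phantom carries exact ground truth (centroid
coordinates, canal mask, canal centerline), so the whole labeling pipeline
is testable without any clinical data.

Nothing here aims at photorealism: vertebral bodies are bright cuboid
blocks separated by disc gaps along a curved canal, posterior processes are
smaller blocks behind the canal, soft tissue is ~40 HU inside an elliptical
body outline and air is -1000 HU outside it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .levels import (
    ANOMALOUS_NAMES,
    CHANNEL_OF,
    LEVEL_NAMES,
    CentroidSet,
    anatomical_order,
    validate_level_name,
)
from .volume import AX_AP, AX_LR, AX_SI, CTVolume

# Default center-to-center spacing (mm) per junction, keyed by the more
# superior level of the pair.  Loose cervical-to-lumbar widening trend:
# ~18 mm cervical rising to ~32 mm at the lumbosacral junction.
_REGION_SPACING = {"C": 18.0, "T": 24.0, "L": 31.0, "S": 25.0}


def default_junction_spacing(upper: str, lower: str) -> float:
    """Default mm gap for the junction between two adjacent levels."""
    if upper.startswith("C"):
        base = 18.0 if lower.startswith("C") else 19.0
    elif upper.startswith("T") or upper == "T13":
        if lower.startswith("T"):
            # thoracic ramp 20 -> 27 mm
            k = int(upper[1:]) if upper != "T13" else 13
            base = 20.0 + 7.0 * (k - 1) / 11.0
        else:
            base = 28.0
    elif upper.startswith("L") or upper == "L6":
        base = 31.0 if lower.startswith("L") else 32.0
    else:  # sacral
        base = 25.0
    return base


@dataclass
class PhantomConfig:
    """Stated world of one synthetic spine CT.

    Parameters
    ----------
    volume_shape
        Voxels per (SI, AP, LR) axis, or ``None`` to auto-size around the
        planned levels.
    voxel_spacing
        mm per (SI, AP, LR) axis; default (2.5, 1.17, 1.17), the cohort
        median slice thickness and pixel size.
    level_plan
        Ordered, anatomically contiguous list of level names.
    spacing_profile
        mm center-to-center gap per junction (``len(level_plan) - 1``
        values), a scalar applied to all junctions, or ``None`` for the
        default cervical->lumbar widening profile.
    curvature_amplitude
        mm of AP bowing of the canal over the scan (single arch).
    anomaly
        One of ``none | extra_lumbar_L6 | extra_thoracic_T13 | four_lumbar``.
        Applied via :func:`inject_anomaly`.
    implant_spec
        Optional list of ``((upper_level, lower_level), intensity_hu)``.
    contrast_spec
        Optional dict for the anterior bright tube, keys ``levels``
        (level-range tuple), ``hu``, ``radius_mm``, ``ap_offset_mm``.
    noise_sd
        Gaussian HU noise standard deviation.
    """

    volume_shape: tuple[int, int, int] | None = None
    voxel_spacing: tuple[float, float, float] = (2.5, 1.17, 1.17)
    level_plan: tuple[str, ...] = LEVEL_NAMES
    spacing_profile: object = None
    curvature_amplitude: float = 8.0
    anomaly: str = "none"
    implant_spec: list | None = None
    contrast_spec: dict | None = None
    noise_sd: float = 12.0
    seed: int = 0

    # rendering knobs (mm); defaults emulate adult anatomy coarsely
    body_halfsize_ap: float = 11.0
    body_halfsize_lr: float = 13.0
    body_ap_offset: float = 16.0  # body center anterior of canal center
    canal_radius: float = 4.0
    process_ap_offset: float = 9.0  # posterior of canal center

    def __post_init__(self) -> None:
        self.level_plan = tuple(self.level_plan)
        for name in self.level_plan:
            validate_level_name(name)
        orders = [anatomical_order(n) for n in self.level_plan]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValueError("level_plan must be in superior-to-inferior order")
        canonical = [n for n in self.level_plan if n in CHANNEL_OF]
        if canonical:
            idx = [CHANNEL_OF[n] for n in canonical]
            contiguous = idx == list(range(idx[0], idx[0] + len(idx)))
            # four-lumbar anatomy: L5 is anatomically absent between L4 and S1
            four_lumbar = (
                "L5" not in canonical
                and "L4" in canonical and "S1" in canonical
                and sorted(idx + [CHANNEL_OF["L5"]])
                == list(range(idx[0], idx[0] + len(idx) + 1))
            )
            if not contiguous and not four_lumbar:
                raise ValueError("level_plan must be anatomically contiguous")
        if np.any(np.asarray(self.voxel_spacing) <= 0):
            raise ValueError("voxel_spacing must be positive per axis")
        if np.any(self.junction_spacings() <= 0):
            raise ValueError("all junction spacings must be > 0")

    def junction_spacings(self) -> np.ndarray:
        """Resolved mm gap per junction of the level plan."""
        n = max(len(self.level_plan) - 1, 0)
        if self.spacing_profile is None:
            return np.array(
                [
                    default_junction_spacing(u, l)
                    for u, l in zip(self.level_plan, self.level_plan[1:])
                ]
            )
        prof = np.atleast_1d(np.asarray(self.spacing_profile, dtype=float))
        if prof.size == 1:
            return np.full(n, float(prof[0]))
        if prof.size != n:
            raise ValueError(
                f"spacing_profile needs {n} junction values, got {prof.size}"
            )
        return prof.copy()


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    centroids: CentroidSet
    canal_mask: np.ndarray  # bool, same grid as the volume
    canal_centerline: np.ndarray  # (n_slices, 3): slice index, AP mm, LR mm
    level_names: tuple[str, ...]


def _canal_ap_curve(si_mm: np.ndarray, si_extent: float, ap_center: float,
                    amplitude: float) -> np.ndarray:
    """AP position of the canal (mm) as a single smooth arch over SI."""
    if si_extent <= 0:
        return np.full_like(si_mm, ap_center)
    return ap_center + amplitude * np.sin(np.pi * si_mm / si_extent)


def _arc_positions(config: PhantomConfig, si_extent: float, ap_center: float,
                   margin: float) -> np.ndarray:
    """SI positions (mm) of the planned centroids, spaced along arc length.

    Consecutive centroids sit a configured gap apart measured along the
    (SI, AP) centroid curve, so 3D center-to-center distances reproduce the
    spacing profile.
    """
    gaps = config.junction_spacings()
    n = len(config.level_plan)
    if n == 0:
        return np.empty(0)
    fine = np.linspace(0.0, si_extent, max(int(si_extent * 4), 2))
    ap = _canal_ap_curve(fine, si_extent, ap_center, config.curvature_amplitude)
    seg = np.hypot(np.diff(fine), np.diff(ap))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = margin + np.concatenate([[0.0], np.cumsum(gaps)])
    if targets[-1] > arc[-1] - margin:
        # find first level that no longer fits
        fits = targets <= arc[-1] - margin
        first_bad = config.level_plan[int(np.argmin(fits))]
        raise ValueError(
            f"volume too small for level plan: level {first_bad} does not fit "
            f"(need {targets[-1] + margin:.0f} mm of arc, have {arc[-1]:.0f} mm)"
        )
    return np.interp(targets, arc, fine)


def _block(volume: np.ndarray, vol: CTVolume, center_mm: np.ndarray,
           half_mm: np.ndarray, value: float) -> None:
    """Paint a solid cuboid (world-mm center/half-size) into ``volume``."""
    lo = np.maximum(np.ceil(vol.world_to_index(center_mm - half_mm)).astype(int), 0)
    hi = np.minimum(
        np.floor(vol.world_to_index(center_mm + half_mm)).astype(int) + 1,
        np.asarray(vol.shape),
    )
    if np.any(lo >= hi):
        return
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = value


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, PhantomTruth]:
    """Render a synthetic spine CT and its exact ground truth.

    Deterministic for a fixed config (including seed).  Vertebral bodies are
    bright (300-1200 HU) blocks whose centers are the truth centroids; the
    canal is a soft-tissue tube behind them; posterior processes sit behind
    the canal.
    """
    rng = np.random.default_rng(config.seed)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    gaps = config.junction_spacings()
    margin = 25.0

    if config.volume_shape is None:
        si_mm = float(np.sum(gaps)) + 2 * margin if len(config.level_plan) else 100.0
        ap_mm = 2 * config.curvature_amplitude + 90.0
        lr_mm = 64.0
        shape = tuple(
            int(np.ceil(e / s)) + 1 for e, s in zip((si_mm, ap_mm, lr_mm), spacing)
        )
    else:
        shape = tuple(int(s) for s in config.volume_shape)

    vol = CTVolume(np.zeros(shape, dtype=np.float32), spacing)
    si_extent, ap_extent, lr_extent = vol.extent_mm()
    ap_center = 0.62 * ap_extent  # spine sits posterior of the body midline
    lr_center = 0.5 * lr_extent

    data = vol.data
    # body outline: elliptical cylinder of soft tissue in air
    jj, kk = np.meshgrid(
        np.arange(shape[AX_AP]) * spacing[AX_AP],
        np.arange(shape[AX_LR]) * spacing[AX_LR],
        indexing="ij",
    )
    body = (
        ((jj - 0.5 * ap_extent) / (0.5 * ap_extent + 1e-9)) ** 2
        + ((kk - lr_center) / (0.5 * lr_extent + 1e-9)) ** 2
    ) <= 1.0
    data[:] = -1000.0
    data[:, body] = 40.0

    levels = config.level_plan
    coords: dict[str, np.ndarray] = {}
    flags: dict[str, str] = {}
    canal_mask = np.zeros(shape, dtype=bool)
    canal_lo_slice, canal_hi_slice = 0, -1

    if levels:
        si_pos = _arc_positions(config, si_extent, ap_center, margin)
        ap_pos = _canal_ap_curve(si_pos, si_extent, ap_center,
                                 config.curvature_amplitude)
        heights = np.empty(len(levels))
        for i in range(len(levels)):
            near = []
            if i > 0:
                near.append(gaps[i - 1])
            if i < len(gaps):
                near.append(gaps[i])
            heights[i] = 0.62 * min(near) if near else 15.0

        for i, name in enumerate(levels):
            scale = {"C": 0.62, "T": 0.85, "L": 1.0, "S": 0.85}[name[0]]
            center = np.array(
                [si_pos[i], ap_pos[i] - config.body_ap_offset * scale, lr_center]
            )
            half = np.array(
                [
                    heights[i] / 2.0,
                    config.body_halfsize_ap * scale,
                    config.body_halfsize_lr * scale,
                ]
            )
            hu = rng.uniform(450.0, 900.0)
            _block(data, vol, center, half, hu)
            # posterior process block (behind the canal)
            _block(
                data,
                vol,
                np.array([si_pos[i], ap_pos[i] + config.process_ap_offset + 4.0,
                          lr_center]),
                np.array([heights[i] * 0.3, 5.0, 4.0 + 6.0 * scale]),
                500.0,
            )
            coords[name] = center
            if name in ANOMALOUS_NAMES:
                flags[name] = "anomaly"

        # canal: soft tube spanning all annotated levels
        canal_lo_slice = max(int(np.floor((si_pos[0] - heights[0] / 2) / spacing[0])), 0)
        canal_hi_slice = min(
            int(np.ceil((si_pos[-1] + heights[-1] / 2) / spacing[0])), shape[0] - 1
        )
        sl = np.arange(canal_lo_slice, canal_hi_slice + 1)
        ap_c = _canal_ap_curve(sl * spacing[0], si_extent, ap_center,
                               config.curvature_amplitude)
        for s, apc in zip(sl, ap_c):
            dj = jj - apc
            dk = kk - lr_center
            disk = dj * dj + dk * dk <= config.canal_radius**2
            canal_mask[s][disk] = True
            data[s][disk] = 10.0

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)

    sl = np.arange(canal_lo_slice, canal_hi_slice + 1) if levels else np.empty(0, int)
    centerline = np.column_stack(
        [
            sl,
            _canal_ap_curve(sl * spacing[0], si_extent, ap_center,
                            config.curvature_amplitude),
            np.full(sl.shape, lr_center),
        ]
    ) if levels else np.empty((0, 3))

    truth = PhantomTruth(
        centroids=CentroidSet(coords, flags=flags),
        canal_mask=canal_mask,
        canal_centerline=centerline,
        level_names=levels,
    )

    cfg_art = config
    if config.implant_spec or config.contrast_spec:
        volume = add_artifacts(vol, truth, cfg_art.implant_spec, cfg_art.contrast_spec)
        vol = volume
    return vol, truth


ANOMALY_KINDS = ("none", "extra_lumbar_L6", "extra_thoracic_T13", "four_lumbar")


def inject_anomaly(config: PhantomConfig, kind: str) -> PhantomConfig:
    """Return a config whose level plan carries the requested anomaly.

    The extra body keeps the adjacent standard name plus an anomaly flag in
    the generated truth (the network's label space is fixed at 26 levels,
    so anomalous bodies have no channel of their own).
    """
    if kind not in ANOMALY_KINDS:
        raise ValueError(f"unknown anomaly kind: {kind!r}")
    if kind == "none":
        return config
    plan = list(config.level_plan)
    gaps = list(config.junction_spacings())

    def insert_after(anchor: str, extra: str) -> None:
        if anchor not in plan:
            raise ValueError(f"anomaly {kind} incompatible with level plan "
                             f"(needs {anchor})")
        i = plan.index(anchor)
        plan.insert(i + 1, extra)
        gap = default_junction_spacing(anchor, extra)
        gaps.insert(i, gap) if i >= len(gaps) else gaps.insert(i + 1, gap)

    if kind == "extra_lumbar_L6":
        insert_after("L5", "L6")
    elif kind == "extra_thoracic_T13":
        insert_after("T12", "T13")
    elif kind == "four_lumbar":
        if "L5" not in plan:
            raise ValueError("four_lumbar anomaly needs L5 in the level plan")
        i = plan.index("L5")
        plan.pop(i)
        if i < len(gaps):
            gaps.pop(i)
        else:
            gaps.pop()
    out = copy.deepcopy(config)
    out.level_plan = tuple(plan)
    out.spacing_profile = np.asarray(gaps) if len(plan) > 1 else None
    out.anomaly = kind
    out.__post_init__()
    return out


def add_artifacts(volume: CTVolume, truth: PhantomTruth, implant_spec=None,
                  contrast_spec=None) -> CTVolume:
    """Overlay high-intensity implants and/or an anterior contrast tube.

    Implant voxels are set to >= 3000 HU within the named level span; the
    contrast tube is rendered strictly anterior to the canal centerline.
    Truth is unchanged.
    """
    if not implant_spec and not contrast_spec:
        return volume
    data = volume.data.copy()
    out = CTVolume(data, volume.spacing.copy(), volume.origin.copy())
    cents = truth.centroids

    def level_span(levels) -> tuple[float, float]:
        lo_name, hi_name = levels
        for nm in (lo_name, hi_name):
            if nm not in cents:
                raise ValueError(f"artifact spec names absent level: {nm!r}")
        si = sorted([cents[lo_name][0], cents[hi_name][0]])
        return si[0], si[1]

    if implant_spec:
        for (levels, hu) in implant_spec:
            if hu < 3000:
                raise ValueError("implant intensity must be >= 3000 HU")
            si_lo, si_hi = level_span(levels)
            names = [n for n in cents if si_lo <= cents[n][0] <= si_hi]
            pts = np.stack([cents[n] for n in names])
            # rod of radius 3 mm along the centroid chain
            for a, b in zip(pts, pts[1:]):
                for t in np.linspace(0, 1, max(int(np.linalg.norm(b - a)), 2)):
                    _block(data, out, a + t * (b - a), np.array([1.5, 3.0, 3.0]), hu)
            if len(pts) == 1:
                _block(data, out, pts[0], np.array([1.5, 3.0, 3.0]), hu)

    if contrast_spec:
        spec = dict(contrast_spec)
        si_lo, si_hi = level_span(spec.get("levels", (cents.names()[0],
                                                     cents.names()[-1])))
        hu = float(spec.get("hu", 350.0))
        radius = float(spec.get("radius_mm", 6.0))
        ap_off = float(spec.get("ap_offset_mm", -38.0))
        if ap_off >= 0:
            raise ValueError("contrast tube must sit anterior (ap_offset_mm < 0)")
        cl = truth.canal_centerline
        for s, ap_mm, lr_mm in cl:
            si_mm = s * volume.spacing[AX_SI]
            if not (si_lo <= si_mm <= si_hi):
                continue
            _block(data, out, np.array([si_mm, ap_mm + ap_off, lr_mm]),
                   np.array([volume.spacing[AX_SI] / 2, radius, radius]), hu)
    return out


def sample_cohort_configs(n: int, seed: int = 0,
                          level_plan=LEVEL_NAMES,
                          spacing_jitter: float = 0.08,
                          curvature_range=(0.0, 8.0),
                          **overrides) -> list[PhantomConfig]:
    """Draw ``n`` phantom configs emulating cohort variability.

    Junction spacings are jittered by ±``spacing_jitter`` (fractional)
    around the default widening profile and the canal curvature amplitude
    is drawn uniformly from ``curvature_range``; each phantom gets its own
    derived seed.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    base = PhantomConfig(level_plan=tuple(level_plan), **overrides)
    gaps = base.junction_spacings()
    configs = []
    for _ in range(n):
        cfg = copy.deepcopy(base)
        cfg.spacing_profile = gaps * rng.uniform(
            1 - spacing_jitter, 1 + spacing_jitter, size=gaps.shape
        )
        cfg.curvature_amplitude = float(rng.uniform(*curvature_range))
        cfg.seed = int(rng.integers(0, 2**31 - 1))
        configs.append(cfg)
    return configs


def emulate_fixed_channel_prediction(truth: PhantomTruth) -> CentroidSet:
    """Emulate how a fixed-26-channel labeler names an anomalous spine.

    The labeler anchors lumbar names to the sacrum and thoracic names to the
    thoracolumbar junction, so with an extra body one region runs out of
    names: its canonical names are assigned from the inferior end upward and
    the most superior body of that region is left unlabeled, leaving a
    junction that spans two physical gaps.  With a missing body (four
    lumbar) the names shift seamlessly and no gap appears.  Non-anomalous
    spines are returned unchanged.
    """
    cents = truth.centroids
    names = cents.names()
    if "L6" in names:
        region = [n for n in names if n.startswith("L")]
    elif "T13" in names:
        region = [n for n in names if n.startswith("T")]
    elif not any(n in ANOMALOUS_NAMES for n in names):
        if "L5" in names or "L1" not in names:
            return cents.subset(names)
        # four-lumbar: shift lumbar names inferior-ward; L1 name absorbs T12's
        # neighbor seamlessly -> just rename the 4 lumbar bodies L2..L5
        lumbar = [n for n in names if n.startswith("L")]
        canon = [f"L{i}" for i in range(6 - len(lumbar), 6)]
        out = {}
        for n in names:
            if n in lumbar:
                out[canon[lumbar.index(n)]] = cents[n]
            else:
                out[n] = cents[n]
        return CentroidSet(out)
    else:
        return cents.subset(names)

    canon = [n for n in region if n in CHANNEL_OF]
    if not canon:
        return cents.subset([n for n in names if n in CHANNEL_OF])
    # assign canonical names of this region from the inferior end upward
    pool = sorted(set(canon), key=anatomical_order)
    assigned: dict[str, np.ndarray] = {}
    bodies = region[::-1]  # inferior -> superior
    pool_rev = pool[::-1]
    for body, new_name in zip(bodies, pool_rev):
        assigned[new_name] = cents[body]
    out = {}
    for n in names:
        if n in region:
            continue
        if n in CHANNEL_OF:
            out[n] = cents[n]
    out.update(assigned)
    return CentroidSet(out)
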