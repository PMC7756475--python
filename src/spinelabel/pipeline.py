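"""End-to-end orchestration: canal -> VOI -> CIPs -> model(s) -> decode ->
ensemble -> metrics -> spacing QA, reproducible from a RunConfig + seeds."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import canal as canal_mod
from . import decode as decode_mod
from . import metrics as metrics_mod
from . import projection as proj
from . import spacing as spacing_mod
from .levels import CentroidSet
from .volume import CTVolume

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run, hashable for provenance."""

    target_slice_mm: float = 2.5
    cross_section_px: int = 55
    windows: tuple = proj.DEFAULT_WINDOWS
    anterior_window: tuple = proj.DEFAULT_WINDOWS[1]
    cip_weight: float = 2.0
    canvas: tuple[int, int] = proj.DEFAULT_CANVAS
    sigma_px: float = 2.0
    fusion_threshold: float = decode_mod.FUSION_THRESHOLD
    presence_min_mass: float = 1e-6
    qa_threshold_mm: float = spacing_mod.DELTA_THRESHOLD_MM
    qa_frames: tuple[str, ...] = ("sagittal",)
    dist_max_mm: float = metrics_mod.DIST_MAX_MM
    exclude_each_end: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key in ("windows",):
            if key in kw:
                kw[key] = tuple(tuple(w) for w in kw[key])
        for key in ("anterior_window", "canvas", "qa_frames"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_projections(volume: CTVolume, config: RunConfig,
                        canal_mask: np.ndarray | None = None,
                        centerline=None, segmenter=None):
    """Preprocess one scan into its three padded CIP pairs.

    Needs exactly one canal source: a mask, a centerline, or a slice
    segmenter to produce the mask.
    """
    volume = proj.resample_volume(volume, config.target_slice_mm)
    if centerline is None:
        if canal_mask is None:
            if segmenter is None:
                raise ValueError(
                    "preprocessing needs a canal mask, a centerline, or a "
                    "canal segmenter"
                )
            canal_mask = canal_mod.segment_volume(segmenter, volume)
        elif canal_mask.shape != volume.shape:
            raise ValueError("canal mask grid does not match resampled volume")
        centerline = canal_mod.extract_centerline(canal_mask, volume.spacing)
    voi = canal_mod.build_voi(centerline, config.cross_section_px)
    pairs = proj.select_cip_set(volume, voi, config.windows,
                                config.anterior_window, config.cip_weight)
    return [proj.pad_pair(p, config.canvas) for p in pairs], volume


def predict_patient(models, pairs, config: RunConfig):
    """Run models over the CIP variants and decode to 3D centroids.

    Returns ``(ensemble_or_single, per_model_predictions)``.
    """
    if not models:
        raise ValueError("no model checkpoints available")
    geom_s = pairs[0].geometry_sagittal
    geom_c = pairs[0].geometry_coronal
    per_model = []
    for model in models:
        outputs = [model.predict(p.sagittal, p.coronal) for p in pairs]
        per_model.append(
            decode_mod.predict_centroids(
                outputs, geom_s, geom_c,
                presence_min_mass=config.presence_min_mass,
                threshold=config.fusion_threshold,
            )
        )
    if len(per_model) == 1:
        return per_model[0], per_model
    return decode_mod.ensemble_predictions(per_model), per_model


def run_pipeline(volume: CTVolume, models, config: RunConfig | None = None,
                 canal_mask: np.ndarray | None = None, centerline=None,
                 segmenter=None, truth: CentroidSet | None = None) -> dict:
    """Full pipeline on one scan; returns predictions, optional score
    report, and spacing-QA flags, all stamped with the config hash."""
    config = config or RunConfig()
    stage = "preprocess"
    try:
        pairs, volume = prepare_projections(volume, config, canal_mask,
                                            centerline, segmenter)
        stage = "predict"
        prediction, per_model = predict_patient(models, pairs, config)
        stage = "spacing_qa"
        qa: dict = {"flagged": None, "offending": None, "error": None}
        try:
            profiles = spacing_mod.spacing_profiles(prediction)
            flagged, offending = spacing_mod.flag_irregular(
                profiles, config.qa_threshold_mm, config.qa_frames
            )
            qa = {"flagged": flagged, "offending": offending,
                  "profiles": profiles, "error": None}
        except ValueError as exc:  # < 3 levels predicted
            qa["error"] = str(exc)
        stage = "evaluate"
        report = None
        if truth is not None:
            report = metrics_mod.score_patient(prediction, truth,
                                               config.dist_max_mm)
    except Exception as exc:
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise
    return {
        "prediction": prediction,
        "per_model": per_model,
        "report": report,
        "qa": qa,
        "config_hash": config.config_hash(),
    }
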