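"""Analytic detection of irregularly spaced vertebral predictions.

For a set of predicted centroids, the intervertebral spacing S_i is the
distance between adjacent predicted bodies (in 3D mm or in a single
projection plane), and the rate of change of spacing is
delta_i = |S_{i+1} - S_i|.  A labeling failure — most notably the gap a
fixed-channel labeler leaves when the spine carries an extra lumbar or
thoracic body — shows up as a spacing that suddenly doubles, hence a
delta on the order of a full vertebral space.  A scan is flagged when any
delta in any gating frame exceeds a scalar threshold (default 10.1 mm,
gating on the sagittal frame); the operating point can be re-derived by
ROC analysis on a labeled cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .levels import LEVEL_NAMES, CentroidSet, anatomical_order
from .volume import AX_AP, AX_LR, AX_SI

DELTA_THRESHOLD_MM = 10.1
FRAMES = ("3d", "sagittal", "coronal")


@dataclass
class SpacingProfile:
    """Spacings and their rate of change along the predicted chain."""

    levels: tuple[str, ...]
    spacings: np.ndarray  # S_i, mm, len = levels - 1
    deltas: np.ndarray  # |S_{i+1} - S_i|, len = levels - 2
    frame: str
    gap_junctions: tuple[int, ...] = ()  # junctions spanning absent levels

    def junction_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in zip(self.levels, self.levels[1:])]


def _frame_coords(xyz: np.ndarray, frame: str) -> np.ndarray:
    if frame == "3d":
        return xyz
    if frame == "sagittal":
        return xyz[[AX_SI, AX_AP]]
    if frame == "coronal":
        return xyz[[AX_SI, AX_LR]]
    raise ValueError(f"unknown frame: {frame!r}")


def spacing_profile(pred: CentroidSet, frame: str = "3d") -> SpacingProfile:
    """Spacings over consecutive predicted levels in anatomical order.

    Junctions that span one or more absent intermediate channels are kept
    (the distance simply covers the gap) and reported in
    ``gap_junctions``.  Needs at least three predicted levels.
    """
    names = sorted(pred.names(), key=anatomical_order)
    if len(names) < 3:
        raise ValueError("spacing profile needs >= 3 predicted levels")
    pts = [_frame_coords(np.asarray(pred[n], float), frame) for n in names]
    spacings = np.array([
        float(np.linalg.norm(b - a)) for a, b in zip(pts, pts[1:])
    ])
    gaps = tuple(
        i for i, (a, b) in enumerate(zip(names, names[1:]))
        if a in LEVEL_NAMES and b in LEVEL_NAMES
        and LEVEL_NAMES.index(b) - LEVEL_NAMES.index(a) > 1
    )
    deltas = np.abs(np.diff(spacings))
    return SpacingProfile(tuple(names), spacings, deltas, frame, gaps)


def spacing_profiles(pred: CentroidSet) -> dict[str, SpacingProfile]:
    """All three coordinate frames (3D, sagittal plane, coronal plane)."""
    return {frame: spacing_profile(pred, frame) for frame in FRAMES}


def flag_irregular(profiles: dict[str, SpacingProfile],
                   threshold_mm: float = DELTA_THRESHOLD_MM,
                   frames_used=("sagittal",)):
    """Flag iff any delta in any gating frame strictly exceeds the
    threshold.  All supplied frames are reported; only ``frames_used``
    gate the flag (default: the sagittal plane)."""
    offending: dict[str, list[str]] = {}
    flagged = False
    for frame, prof in profiles.items():
        over = np.nonzero(prof.deltas > threshold_mm)[0]
        hits = [prof.junction_names()[i + 1] for i in over]
        offending[frame] = hits
        if frame in frames_used and hits:
            flagged = True
    return flagged, offending


def roc_analysis(cases, thresholds=None, frames_used=("sagittal",)):
    """ROC of the spacing flag over a labeled cohort.

    ``cases``: list of ``(profiles, failure_label)`` with profiles as from
    :func:`spacing_profiles`.  Sensitivity/specificity are evaluated with
    :func:`flag_irregular` at each threshold; AUC is the trapezoid over
    the (FPR, TPR) curve and the operating point maximizes Youden's J.
    """
    labels = np.array([bool(lab) for _, lab in cases])
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both failure and non-failure cases")
    scores = []
    for profiles, _ in cases:
        deltas = np.concatenate(
            [profiles[f].deltas for f in frames_used]
        ) if frames_used else np.zeros(1)
        scores.append(float(deltas.max()) if deltas.size else 0.0)
    scores = np.array(scores)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[-np.inf], scores, [np.inf]]))
    thresholds = np.asarray(thresholds, float)

    points = []
    for thr in thresholds:
        flag = scores > thr
        tp = int(np.sum(flag & labels))
        fp = int(np.sum(flag & ~labels))
        fn = int(np.sum(~flag & labels))
        tn = int(np.sum(~flag & ~labels))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        points.append((float(thr), sens, spec))

    tpr = np.array([p[1] for p in points])
    fpr = np.array([1.0 - p[2] for p in points])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    youden = np.array([p[1] + p[2] - 1.0 for p in points])
    best = int(np.argmax(youden))
    return {
        "thresholds": thresholds,
        "points": points,
        "auc": auc,
        "operating_point": points[best][0],
        "sensitivity": points[best][1],
        "specificity": points[best][2],
    }
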