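"""Desk-scale demonstration world: short-scan phantoms + the reduced net.

Clinical scans in the target cohort have variable length, and scans
covering only part of the spine are common; the desk-scale world mirrors
that with a ten-level cervicothoracic span (C1-T3) rendered onto a
96 x 32 canvas (240 mm of SI capacity at 2.5 mm/px) with a 25 px canal
window, so a full train-and-evaluate cycle of the reduced network runs in
minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np

from .canal import build_voi, centerline_from_truth
from .decode import predict_centroids
from .metrics import class_metrics, score_patient
from .phantom import generate_phantom, sample_cohort_configs
from .projection import make_label_stack, pad_pair, select_cip_set
from .xnet import XNetConfig, build_xnet, train_model

REDUCED_PLAN = tuple(f"C{i}" for i in range(1, 8)) + ("T1", "T2", "T3")
REDUCED_CANVAS = (96, 32)
REDUCED_CROSS_SECTION = 25


def phantom_sample(config, canvas=REDUCED_CANVAS,
                   cross_section_px=REDUCED_CROSS_SECTION):
    """One phantom -> (padded CIP pairs, label stacks, truth)."""
    vol, truth = generate_phantom(config)
    centerline = centerline_from_truth(truth.canal_centerline, vol.spacing)
    voi = build_voi(centerline, cross_section_px)
    pairs = [pad_pair(p, canvas) for p in select_cip_set(vol, voi)]
    stacks = [make_label_stack(p, truth.centroids) for p in pairs]
    return pairs, stacks, truth


def reduced_cohort(n: int, seed: int = 0):
    """``n`` desk-scale phantoms with cohort-like geometric variability."""
    configs = sample_cohort_configs(
        n, seed=seed, level_plan=REDUCED_PLAN, curvature_range=(0.0, 3.0)
    )
    return [phantom_sample(cfg) for cfg in configs]


def flatten_training_set(samples):
    """All projection variants of every phantom as training samples."""
    dataset = []
    for pairs, stacks, _ in samples:
        for p, s in zip(pairs, stacks):
            dataset.append(((p.sagittal, p.coronal), (s.sagittal, s.coronal)))
    return dataset


def train_reduced_model(train_samples, seed: int = 0, epochs: int = 30,
                        restart_every: int = 5):
    """Train a reduced network on phantom samples; returns (model, history).

    Adam is warm-restarted every ``restart_every`` epochs: on this preset
    the periodically reset second-moment estimate keeps effective step
    sizes large enough to sharpen the heatmaps, which plain single-run
    Adam at the same budget does not achieve.
    """
    from .xnet import TrainHistory

    model = build_xnet(XNetConfig.reduced_preset(seed=seed))
    dataset = flatten_training_set(train_samples)
    history = TrainHistory()
    done, chunk = 0, 0
    while done < epochs:
        n = min(restart_every, epochs - done)
        model, h = train_model(model, dataset, epochs=n, seed=seed + chunk)
        history.epoch_loss.extend(h.epoch_loss)
        done += n
        chunk += 1
    return model, history


def evaluate_model(model, test_samples, dist_max_mm: float = 20.0):
    """Score a model over held-out phantom samples.

    Returns ``(reports, class_metrics_dict)``.
    """
    reports = []
    for pairs, _, truth in test_samples:
        outputs = [model.predict(p.sagittal, p.coronal) for p in pairs]
        pred = predict_centroids(outputs, pairs[0].geometry_sagittal,
                                 pairs[0].geometry_coronal)
        reports.append(score_patient(pred, truth.centroids, dist_max_mm))
    return reports, class_metrics(reports)
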