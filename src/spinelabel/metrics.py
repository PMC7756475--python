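"""Scoring and evaluation metrics for vertebral labeling.

A predicted level is a true positive when (1) a prediction exists for the
level, (2) its 3D localization error is below 20 mm, and (3) among all
predictions it is the nearest one to that level's true centroid.
Predictions violating any criterion (or without a matching truth level)
are false positives; truths without a qualifying prediction are false
negatives; levels absent from both are true negatives (counted per absent
channel of the 26).

Patient metrics: accuracy A = TP/n, localization error E = mean over TPs,
precision P = TP/(TP+FP), sensitivity S = TP/(TP+FN), F1 = 2PS/(P+S)
(F1 := 0 when P+S = 0).  Class metrics: per-channel identification rate
IR_k over all patients whose truth contains the level, with region
summaries (cervical 1-7, thoracic 8-19, lumbar 20-24, sacral 25-26).
"%passing" is the fraction of patients with every level inside the
clinically viable region (truth order minus three levels at each end)
scored TP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .levels import LEVEL_NAMES, REGIONS, CentroidSet

DIST_MAX_MM = 20.0


@dataclass
class ScoreReport:
    """Per-level outcomes and errors for one patient."""

    outcomes: dict[str, str]  # level -> TP | FP | FN | TN
    errors_mm: dict[str, float]  # level -> 3D error (TPs, and FPs w/ truth)
    truth_levels: tuple[str, ...]
    metrics: dict = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return sum(1 for v in self.outcomes.values() if v == kind)


def score_patient(pred: CentroidSet, truth: CentroidSet,
                  dist_max: float = DIST_MAX_MM) -> ScoreReport:
    """Score one patient's predictions against truth.

    Anomalous truth levels (no channel of their own) are ignored; the 26
    canonical channels partition into TP/FP/FN/TN.  Nearest-prediction
    ties break toward the anatomically superior level (logged via the
    outcome dict order).
    """
    canon_truth = [n for n in truth.names() if n in LEVEL_NAMES]
    canon_pred = [n for n in pred.names() if n in LEVEL_NAMES]
    outcomes: dict[str, str] = {}
    errors: dict[str, float] = {}

    pred_arr = {n: pred[n] for n in canon_pred}
    for name in LEVEL_NAMES:
        has_p, has_t = name in pred_arr, name in canon_truth
        if not has_p and not has_t:
            outcomes[name] = "TN"
            continue
        if has_p and not has_t:
            outcomes[name] = "FP"
            continue
        if not has_p:
            outcomes[name] = "FN"
            continue
        err = float(np.linalg.norm(pred_arr[name] - truth[name]))
        errors[name] = err
        # criterion 2: this prediction must be the nearest of all
        # predictions to the truth centroid (ties -> superior level wins)
        dists = [
            (float(np.linalg.norm(pred_arr[p] - truth[name])), i)
            for i, p in enumerate(canon_pred)
        ]
        best = min(dists)
        nearest_is_self = canon_pred[best[1]] == name
        if err < dist_max and nearest_is_self:
            outcomes[name] = "TP"
        else:
            outcomes[name] = "FP"
    # truths whose prediction was disqualified are also missed detections:
    # the level has truth but no qualifying prediction -> count the FN
    for name in canon_truth:
        if outcomes[name] == "FP":
            outcomes[name] = "FP+FN"
    report = ScoreReport(outcomes, errors, tuple(canon_truth))
    report.metrics = patient_metrics(report)
    return report


def _counts(report: ScoreReport) -> dict[str, int]:
    c = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for v in report.outcomes.values():
        if v == "FP+FN":
            c["FP"] += 1
            c["FN"] += 1
        else:
            c[v] += 1
    return c


def patient_metrics(report: ScoreReport) -> dict:
    """A, E, P, S, F1 for one patient (E absent when there are no TPs)."""
    n = len(report.truth_levels)
    if n == 0:
        raise ValueError("patient has no truth levels")
    c = _counts(report)
    tp, fp, fn = c["TP"], c["FP"], c["FN"]
    tp_errors = [report.errors_mm[k] for k, v in report.outcomes.items()
                 if v == "TP"]
    a = tp / n
    p = tp / (tp + fp) if tp + fp else 0.0
    s = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * s / (p + s) if p + s else 0.0
    return {
        "A": a,
        "E": float(np.mean(tp_errors)) if tp_errors else None,
        "P": p,
        "S": s,
        "F1": f1,
        "n": n,
        **c,
    }


def class_metrics(cohort: list[ScoreReport]) -> dict:
    """Identification rate and localization error per channel and region.

    IR_k is computed over patients whose truth contains level k; levels
    never present in any truth are reported absent (None), not 0.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ir: dict[str, float | None] = {}
    err_mean: dict[str, float | None] = {}
    err_sd: dict[str, float | None] = {}
    for name in LEVEL_NAMES:
        m_k, tp_k, errs = 0, 0, []
        for rep in cohort:
            if name not in rep.truth_levels:
                continue
            m_k += 1
            if rep.outcomes.get(name) == "TP":
                tp_k += 1
                errs.append(rep.errors_mm[name])
        ir[name] = tp_k / m_k if m_k else None
        err_mean[name] = float(np.mean(errs)) if errs else None
        err_sd[name] = float(np.std(errs)) if errs else None

    regions = {}
    for region, names in list(REGIONS.items()) + [("all", LEVEL_NAMES)]:
        m, tp, errs = 0, 0, []
        for rep in cohort:
            for name in names:
                if name not in rep.truth_levels:
                    continue
                m += 1
                if rep.outcomes.get(name) == "TP":
                    tp += 1
                    errs.append(rep.errors_mm[name])
        regions[region] = {
            "IR": tp / m if m else None,
            "E_mean": float(np.mean(errs)) if errs else None,
            "E_sd": float(np.std(errs)) if errs else None,
            "m": m,
        }
    return {"per_level": {"IR": ir, "E_mean": err_mean, "E_sd": err_sd},
            "regions": regions}


def viable_region(truth_levels, exclude_each_end: int = 3) -> list[str]:
    """Truth levels minus the ``exclude_each_end`` most superior and most
    inferior ones (the clinically viable region)."""
    levels = list(truth_levels)
    if exclude_each_end == 0:
        return levels
    return levels[exclude_each_end:-exclude_each_end]


def percent_passing(cohort: list[ScoreReport], exclude_each_end: int = 3):
    """Fraction of patients with every viable-region level scored TP.

    Patients with fewer than ``2 * exclude_each_end + 1`` truth levels have
    an empty region and are excluded (with a warning flag).  A scan needs
    at least seven levels for the default region to be non-empty.
    """
    flags: list[bool | None] = []
    minimum = 2 * exclude_each_end + 1
    for rep in cohort:
        if len(rep.truth_levels) < minimum:
            flags.append(None)  # excluded: region empty
            continue
        region = viable_region(rep.truth_levels, exclude_each_end)
        flags.append(all(rep.outcomes.get(n) == "TP" for n in region))
    scored = [f for f in flags if f is not None]
    frac = float(np.mean(scored)) if scored else float("nan")
    return frac, flags
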