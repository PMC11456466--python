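"""Angle-error metrics (MAE/MSE/RMSE), detection metrics (precision/recall/
F1, AP/mAP) and the multi-method comparison harness.

Angle errors compare predicted tilt against the unsigned ground-truth tilt in
degrees.  Detection metrics are included for completeness of the evaluation
surface; the comparison harness itself only needs the angle metrics plus
posture-label accuracy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import baselines
from .errors import CabbageError, ConfigError
from .posture import PostureConfig, classify, predict_posture
from .scene_io import CabbageScene
from .synthetic import GroundTruth

__all__ = [
    "DetectionCounts",
    "MethodStats",
    "AngleErrorReport",
    "mae",
    "mse_rmse",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "compare_methods",
]


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MethodStats:
    """Aggregate angle-error statistics for one method."""

    mae_deg: float
    mse_deg2: float
    rmse_deg: float
    n: int
    label_accuracy: float | None = None
    failures: int = 0


@dataclass
class AngleErrorReport:
    methods: dict[str, MethodStats]
    n_scenes: int
    strata: dict[str, dict[str, MethodStats]] = field(default_factory=dict)
    records: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        def stats_d(s: MethodStats) -> dict[str, Any]:
            return {
                "mae_deg": s.mae_deg,
                "mse_deg2": s.mse_deg2,
                "rmse_deg": s.rmse_deg,
                "n": s.n,
                "label_accuracy": s.label_accuracy,
                "failures": s.failures,
            }

        return {
            "n_scenes": self.n_scenes,
            "methods": {m: stats_d(s) for m, s in self.methods.items()},
            "strata": {
                name: {m: stats_d(s) for m, s in block.items()}
                for name, block in self.strata.items()
            },
        }

    def write_csv(self, path: str | Path) -> None:
        """Per-scene records: scene_id, method, theta_pred, theta_true, ..."""
        fields = [
            "scene_id", "method", "theta_pred", "theta_true",
            "abs_err", "label_pred", "label_true", "stratum",
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for rec in self.records:
                writer.writerow({k: rec.get(k) for k in fields})


def _check_pair(truth: Sequence[float], pred: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.ndim != 1 or p.ndim != 1 or len(t) != len(p) or len(t) == 0:
        raise ValueError("truth and pred must be equal-length non-empty 1-D sequences")
    return t, p


def mae(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Mean absolute error (1/n) sum |y_r - y_p|."""
    t, p = _check_pair(truth, pred)
    return float(np.abs(t - p).mean())


def mse_rmse(truth: Sequence[float], pred: Sequence[float]) -> tuple[float, float]:
    """Mean squared error and its square root."""
    t, p = _check_pair(truth, pred)
    m = float(((t - p) ** 2).mean())
    return m, math.sqrt(m)


def precision_recall_f1(
    c: DetectionCounts,
) -> tuple[float | None, float | None, float | None]:
    """Precision tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R).

    A metric whose denominator is zero is returned as None (flagged
    undefined) rather than propagating NaN; if both denominators are zero
    there is nothing to evaluate and a domain error is raised.
    """
    det = c.tp + c.fp
    pos = c.tp + c.fn
    if det == 0 and pos == 0:
        raise CabbageError("no detections and no truths")
    precision = c.tp / det if det > 0 else None
    recall = c.tp / pos if pos > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def average_precision(pr_pairs: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal integral of precision over recall.

    ``pr_pairs`` is a list of (recall, precision) with non-decreasing recall
    in [0, 1].  The curve is extended flat to recall 0 with the first
    precision and padded to recall 1 with precision 0.
    """
    if not pr_pairs:
        raise ValueError("need at least one (recall, precision) pair")
    r = np.array([p[0] for p in pr_pairs], dtype=float)
    p = np.array([p[1] for p in pr_pairs], dtype=float)
    if np.any(np.diff(r) < 0):
        raise ValueError("recalls must be non-decreasing")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("recalls must lie in [0, 1]")
    if r[0] > 0:
        r = np.concatenate([[0.0], r])
        p = np.concatenate([[p[0]], p])
    if r[-1] < 1:
        r = np.concatenate([r, [1.0]])
        p = np.concatenate([p, [0.0]])
    return float(np.trapezoid(p, r))


def mean_average_precision(per_class_ap: Sequence[float]) -> float:
    """Mean of per-class APs."""
    if not per_class_ap:
        raise ValueError("need at least one class AP")
    return float(np.mean(per_class_ap))


def compare_methods(
    scenes: Sequence[tuple[CabbageScene, GroundTruth]],
    methods: Sequence[str] = ("bezier", "mer", "skeleton"),
    beta_deg: float = 10.0,
    config: PostureConfig | None = None,
) -> AngleErrorReport:
    """Run each tilt method on each scene and aggregate errors vs ground truth.

    The truth for every method is the unsigned true axis angle |alpha|;
    posture labels are derived from it with the same beta.  Scenes where a
    method fails are excluded from that method's aggregates and counted.
    """
    if not scenes:
        raise ConfigError("need at least one scene")
    methods = list(methods)
    if not methods:
        raise ConfigError("empty method list")
    valid = {"bezier", "mer", "skeleton"}
    unknown = set(methods) - valid
    if unknown:
        raise ConfigError(f"unknown methods {sorted(unknown)}; valid: {sorted(valid)}")
    cfg = config or PostureConfig(beta_deg=beta_deg)

    records: list[dict[str, Any]] = []
    for i, (scene, truth) in enumerate(scenes):
        theta_true = abs(truth.true_angle_deg)
        label_true = classify(theta_true, beta_deg).value
        stratum = truth.preset or scene.meta.get("preset", "unknown")
        for method in methods:
            rec: dict[str, Any] = {
                "scene_id": scene.meta.get("scene_index", i),
                "method": method,
                "theta_true": theta_true,
                "label_true": label_true,
                "stratum": stratum,
            }
            try:
                if method == "bezier":
                    theta = predict_posture(scene, beta_deg=beta_deg, config=cfg).theta_deg
                else:
                    theta = baselines.baseline_angle(scene.root, method)
            except CabbageError as exc:
                rec["error"] = str(exc)
                records.append(rec)
                continue
            rec["theta_pred"] = theta
            rec["abs_err"] = abs(theta - theta_true)
            rec["label_pred"] = classify(theta, beta_deg).value
            records.append(rec)

    def aggregate(recs: list[dict[str, Any]]) -> dict[str, MethodStats]:
        out: dict[str, MethodStats] = {}
        for method in methods:
            ok = [r for r in recs if r["method"] == method and "theta_pred" in r]
            failures = sum(1 for r in recs if r["method"] == method and "error" in r)
            if not ok:
                out[method] = MethodStats(
                    mae_deg=float("nan"), mse_deg2=float("nan"),
                    rmse_deg=float("nan"), n=0, failures=failures,
                )
                continue
            t = [r["theta_true"] for r in ok]
            p = [r["theta_pred"] for r in ok]
            m = mae(t, p)
            s, rm = mse_rmse(t, p)
            acc = sum(1 for r in ok if r["label_pred"] == r["label_true"]) / len(ok)
            out[method] = MethodStats(
                mae_deg=m, mse_deg2=s, rmse_deg=rm, n=len(ok),
                label_accuracy=acc, failures=failures,
            )
        return out

    report = AngleErrorReport(
        methods=aggregate(records),
        n_scenes=len(scenes),
        records=records,
    )
    for stratum in sorted({r["stratum"] for r in records}):
        block = [r for r in records if r["stratum"] == stratum]
        report.strata[stratum] = aggregate(block)
    return report
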