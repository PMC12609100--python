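"""Regression and threshold-swept detection metrics for severity estimates.

Severity estimation is scored with Pearson correlation, MAE and RMSE (plus a
per-bin calibration curve over true-severity bins 5-15%, ..., 85-95%).
Detection re-labels the cohort at a VSI *labeling threshold* (positive iff
true severity strictly exceeds it), calls a case positive when the predicted
severity exceeds the *decision threshold* (default: the same value), and
reports the confusion-matrix metrics; ROC and precision-recall curves sweep
the decision threshold over the predicted values. Multi-model aggregation
reports mean and sample (n-1) standard deviation across independently
trained models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import auc, precision_recall_curve, roc_curve

__all__ = [
    "RegressionReport",
    "DetectionReport",
    "regression_metrics",
    "detection_metrics",
    "threshold_sweep",
    "roc_prc",
    "aggregate_models",
    "LABELING_THRESHOLDS",
]

#: labeling cutoffs (% VSI) used in the robustness sweep
LABELING_THRESHOLDS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: true-severity calibration bins (% VSI): 5-15, 15-25, ..., 85-95
CALIBRATION_BINS = np.arange(5.0, 96.0, 10.0)


@dataclass
class RegressionReport:
    pearson_rho: float
    mae: float  # %VSI
    rmse: float  # %VSI
    n: int
    bin_centers: list[float] = field(default_factory=list)
    bin_mean_prediction: list[float] = field(default_factory=list)

    def as_dict(self):
        return asdict(self)


@dataclass
class DetectionReport:
    labeling_threshold: float
    decision_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    f1: float
    prevalence: float
    auc_roc: float | None = None
    auc_prc: float | None = None
    roc_points: list | None = None
    prc_points: list | None = None

    def as_dict(self):
        d = asdict(self)
        return d


def regression_metrics(predictions, references) -> RegressionReport:
    """Pearson rho, MAE, RMSE and the binned calibration curve."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.size < 2:
        raise ValueError("need >= 2 paired finite values")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite values in predictions/references")
    rho = float(pearsonr(p, r)[0]) if np.std(p) > 0 and np.std(r) > 0 else np.nan
    centers, means = [], []
    for lo, hi in zip(CALIBRATION_BINS[:-1], CALIBRATION_BINS[1:]):
        mask = (r >= lo) & (r < hi)
        if np.any(mask):
            centers.append(float((lo + hi) / 2))
            means.append(float(p[mask].mean()))
    return RegressionReport(
        pearson_rho=rho,
        mae=float(np.mean(np.abs(p - r))),
        rmse=float(np.sqrt(np.mean((p - r) ** 2))),
        n=int(p.size),
        bin_centers=centers,
        bin_mean_prediction=means,
    )


def _confusion(pred_pos: np.ndarray, truth_pos: np.ndarray):
    tp = int(np.sum(pred_pos & truth_pos))
    tn = int(np.sum(~pred_pos & ~truth_pos))
    fp = int(np.sum(pred_pos & ~truth_pos))
    fn = int(np.sum(~pred_pos & truth_pos))
    return tp, tn, fp, fn


def _safe(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def detection_metrics(predictions, references, labeling_threshold: float,
                      decision_threshold: float | None = None,
                      with_curves: bool = False) -> DetectionReport:
    """Confusion-matrix metrics at one labeling/decision threshold pair.

    Truth: ``reference > labeling_threshold``; call: ``prediction >
    decision_threshold`` (strictly greater in both cases, matching the
    labeling rule). When only one truth class is present the AUCs are
    undefined and flagged as NaN.
    """
    if not 0.0 < labeling_threshold < 100.0:
        raise ValueError("labeling threshold must lie in (0, 100)")
    if decision_threshold is None:
        decision_threshold = labeling_threshold
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    truth = r > labeling_threshold
    call = p > decision_threshold
    tp, tn, fp, fn = _confusion(call, truth)
    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    ppv = _safe(tp, tp + fp)
    npv = _safe(tn, tn + fn)
    f1 = _safe(2 * tp, 2 * tp + fp + fn)
    report = DetectionReport(
        labeling_threshold=float(labeling_threshold),
        decision_threshold=float(decision_threshold),
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / len(p),
        ppv=ppv,
        npv=npv,
        f1=f1,
        prevalence=float(truth.mean()),
    )
    if truth.all() or not truth.any():
        report.auc_roc = np.nan
        report.auc_prc = np.nan
        return report
    curves = roc_prc(p, r, labeling_threshold)
    report.auc_roc = curves["auc_roc"]
    report.auc_prc = curves["auc_prc"]
    if with_curves:
        report.roc_points = curves["roc_points"]
        report.prc_points = curves["prc_points"]
    return report


def roc_prc(predictions, references, labeling_threshold: float) -> dict:
    """ROC and precision-recall curves over the decision-threshold sweep.

    Areas are trapezoidal; the PRC baseline equals the positive prevalence.
    """
    p = np.asarray(predictions, dtype=float)
    truth = np.asarray(references, dtype=float) > labeling_threshold
    if truth.all() or not truth.any():
        raise ValueError("ROC/PRC undefined with a single truth class")
    fpr, tpr, _ = roc_curve(truth, p, drop_intermediate=False)
    prec, rec, _ = precision_recall_curve(truth, p)
    # integrate the PR curve in its native (decreasing-recall) order:
    # duplicate-recall vertices then contribute zero width
    auc_prc = float(abs(np.trapezoid(prec, rec)))
    return {
        "roc_points": np.column_stack([fpr, tpr]).tolist(),
        "prc_points": np.column_stack([rec, prec]).tolist(),
        "auc_roc": float(auc(fpr, tpr)),
        "auc_prc": auc_prc,
        "baseline_precision": float(truth.mean()),
    }


def threshold_sweep(predictions, references,
                    thresholds=LABELING_THRESHOLDS) -> pd.DataFrame:
    """One detection report per labeling cutoff (classifier threshold equal
    to the labeling threshold)."""
    rows = []
    for thr in thresholds:
        rep = detection_metrics(predictions, references, thr)
        rows.append(rep.as_dict())
    df = pd.DataFrame(rows)
    return df.drop(columns=["roc_points", "prc_points"])


def aggregate_models(reports: list) -> dict:
    """Element-wise mean +- sample SD across per-model reports.

    Accepts a list of RegressionReport/DetectionReport (or plain dicts);
    aggregation is permutation-invariant; a single model reports SD 0.
    """
    if not reports:
        raise ValueError("need at least one report")
    dicts = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in reports]
    out: dict[str, dict[str, float]] = {}
    for key in dicts[0]:
        vals = [d.get(key) for d in dicts]
        if all(isinstance(v, (int, float)) and v is not None for v in vals):
            arr = np.asarray(vals, dtype=float)
            sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
            out[key] = {"mean": float(np.mean(arr)), "sd": sd}
    # calibration curves averaged point-wise when bins agree across models
    if "bin_centers" in dicts[0] and dicts[0]["bin_centers"]:
        centers = dicts[0]["bin_centers"]
        if all(d.get("bin_centers") == centers for d in dicts):
            curves = np.asarray([d["bin_mean_prediction"] for d in dicts], dtype=float)
            out["calibration"] = {
                "bin_centers": centers,
                "mean": curves.mean(axis=0).tolist(),
                "sd": (curves.std(axis=0, ddof=1) if len(curves) > 1
                       else np.zeros(curves.shape[1])).tolist(),
            }
    return out


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
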