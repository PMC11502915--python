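"""Standalone performance evaluation: ROC/AUC, micro-averaging, bootstrap
confidence intervals, localization IoU and subgroup reports.

"Overall" metrics pool every (case, category) score/label pair into one
vector (micro-averaging) before computing the metric; sensitivity and
specificity pool the per-category binary determinations made at the frozen
per-category operating points. Confidence intervals are percentile bootstrap
over case resamples (all categories of a case move together), m = 1000 by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .synthdata import CATEGORIES

__all__ = [
    "roc_auc",
    "micro_average",
    "bootstrap_ci",
    "summed_iou",
    "iou_report",
    "subset_sensitivity",
    "EvalReport",
    "evaluate_standalone",
]


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC; equals the normalized Mann-Whitney U statistic
    with tied score pairs counted half."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined when only one class is present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def micro_average(per_category_scores: Mapping[str, np.ndarray],
                  per_category_labels: Mapping[str, np.ndarray],
                  per_category_determinations: Mapping[str, np.ndarray]
                  | None = None) -> dict:
    """Pool all (case, category) pairs; overall AUC plus pooled sens/spec.

    Sensitivity/specificity require ``per_category_determinations`` (binary
    device calls at the frozen per-category thresholds).
    """
    missing = set(CATEGORIES) - set(per_category_scores)
    if missing:
        raise ValueError(f"missing categories: {sorted(missing)}")
    scores = np.concatenate([np.asarray(per_category_scores[c], float)
                             for c in CATEGORIES])
    labels = np.concatenate([np.asarray(per_category_labels[c]).astype(int)
                             for c in CATEGORIES])
    out = {"auc": roc_auc(scores, labels), "n_pairs": int(scores.size)}
    if per_category_determinations is not None:
        det = np.concatenate([
            np.asarray(per_category_determinations[c]).astype(int)
            for c in CATEGORIES])
        pos, neg = labels == 1, labels == 0
        out["sensitivity"] = float(det[pos].mean()) if pos.any() else np.nan
        out["specificity"] = float(1 - det[neg].mean()) if neg.any() else np.nan
    return out


def bootstrap_ci(metric_fn: Callable[[np.ndarray], float], n_cases: int,
                 m: int = 1000, seed: int = 0, alpha: float = 0.05,
                 max_skip_frac: float = 0.2) -> tuple[float, float]:
    """Percentile bootstrap CI resampling whole cases.

    ``metric_fn`` receives an integer index array (a case resample, all
    categories of a case moving together) and returns the metric value.
    Replicates on which the metric is undefined (raises ``ValueError`` or
    returns NaN) are skipped, up to ``max_skip_frac`` of ``m``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    values = []
    skipped = 0
    for _ in range(m):
        idx = rng.integers(0, n_cases, size=n_cases)
        try:
            v = metric_fn(idx)
        except ValueError:
            v = np.nan
        if np.isnan(v):
            skipped += 1
            continue
        values.append(v)
    if skipped > max_skip_frac * m:
        raise ValueError(f"{skipped}/{m} bootstrap replicates were "
                         "degenerate (single-class resamples)")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _boxes_to_mask(boxes: Sequence, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for box in boxes:
        r0, c0, r1, c1 = box
        mask[max(r0, 0):r1, max(c0, 0):c1] = True
    return mask


def summed_iou(pred_boxes: Sequence, ref_boxes: Sequence,
               image_shape: tuple[int, int]) -> float:
    """Intersection-over-union of the pixel areas covered by two box sets.

    Overlapping boxes within one set are not double-counted: the covered
    pixel sets are formed first, then |P & R| / |P | R| is returned. Both
    sets empty is undefined (raises) — aggregation is over true positives.
    """
    if len(pred_boxes) == 0 and len(ref_boxes) == 0:
        raise ValueError("IoU undefined for two empty box sets")
    p = _boxes_to_mask(pred_boxes, image_shape)
    r = _boxes_to_mask(ref_boxes, image_shape)
    union = np.logical_or(p, r).sum()
    return float(np.logical_and(p, r).sum() / union)


def iou_report(pred_boxes: Sequence, ref_boxes: Sequence,
               image_shape: tuple[int, int]) -> dict:
    """Set-based IoU plus raw summed-area totals for transparency."""
    def _area(boxes):
        return int(sum((b[2] - b[0]) * (b[3] - b[1]) for b in boxes))

    return {
        "iou": summed_iou(pred_boxes, ref_boxes, image_shape),
        "summed_pred_area": _area(pred_boxes),
        "summed_ref_area": _area(ref_boxes),
    }


def subset_sensitivity(table: pd.DataFrame, subset_key: str,
                       metric: str = "sensitivity", min_cases: int = 20,
                       m: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-stratum sensitivity (or AUC) with bootstrap CIs.

    ``table`` has one row per (case, category) with columns ``reference``,
    ``determination`` (for sensitivity) or ``score`` (for AUC), a ``case_id``
    column, and the stratification column ``subset_key``. Strata with
    ``min_cases`` or fewer distinct cases are suppressed.
    """
    rows = []
    for stratum, grp in table.groupby(subset_key):
        n_stratum_cases = grp["case_id"].nunique()
        if n_stratum_cases <= min_cases:
            continue
        case_ids = grp["case_id"].unique()
        by_case = {cid: sub for cid, sub in grp.groupby("case_id")}

        def metric_on(idx):
            sub = pd.concat([by_case[case_ids[i]] for i in idx])
            return _table_metric(sub, metric)

        try:
            point = _table_metric(grp, metric)
        except ValueError:
            continue
        lo, hi = bootstrap_ci(metric_on, len(case_ids), m=m, seed=seed)
        rows.append({subset_key: stratum, "n_cases": int(n_stratum_cases),
                     metric: point, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _table_metric(table: pd.DataFrame, metric: str) -> float:
    if metric == "sensitivity":
        pos = table[table["reference"] == 1]
        if len(pos) == 0:
            raise ValueError("no positives in stratum")
        return float(pos["determination"].mean())
    if metric == "auc":
        return roc_auc(table["score"].to_numpy(),
                       table["reference"].to_numpy())
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class EvalReport:
    """Standalone evaluation report mirroring the per-category table layout
    (n positive, sensitivity, specificity, AUC, 95% CIs) plus overall
    micro-averaged metrics and per-category localization IoU."""

    per_category: pd.DataFrame
    overall: dict
    mean_iou: dict[str, float] = field(default_factory=dict)
    subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_category": self.per_category.to_dict(orient="records"),
            "overall": self.overall,
            "mean_iou": self.mean_iou,
            "subgroups": {k: v.to_dict(orient="records")
                          for k, v in self.subgroups.items()},
        }


def evaluate_standalone(scores: np.ndarray, reference: np.ndarray,
                        determinations: np.ndarray, m: int = 1000,
                        seed: int = 0,
                        iou_by_category: Mapping[str, Sequence[float]]
                        | None = None) -> EvalReport:
    """Per-category and overall AUC/sensitivity/specificity with bootstrap
    CIs over case resamples.

    ``scores``, ``reference`` and ``determinations`` are (n_cases, 8) arrays
    aligned with :data:`~cxrcad.synthdata.CATEGORIES`.
    """
    scores = np.asarray(scores, float)
    reference = np.asarray(reference).astype(int)
    determinations = np.asarray(determinations).astype(int)
    n_cases = scores.shape[0]
    rows = []
    for ci, cat in enumerate(CATEGORIES):
        s, y, d = scores[:, ci], reference[:, ci], determinations[:, ci]
        if y.min() == y.max():
            warnings.warn(f"category {cat!r} has one class only; skipped")
            continue
        pos, neg = y == 1, y == 0
        auc = roc_auc(s, y)
        sens = float(d[pos].mean())
        spec = float(1 - d[neg].mean())
        auc_ci = _ci_or_nan(
            lambda idx, ci=ci: _safe_auc(scores[idx, ci], reference[idx, ci]),
            n_cases, m, seed, cat)
        sens_ci = _ci_or_nan(
            lambda idx, ci=ci: _safe_rate(determinations[idx, ci],
                                          reference[idx, ci], 1),
            n_cases, m, seed + 1, cat)
        spec_ci = _ci_or_nan(
            lambda idx, ci=ci: _safe_rate(1 - determinations[idx, ci],
                                          reference[idx, ci], 0),
            n_cases, m, seed + 2, cat)
        rows.append({"category": cat, "n_pos": int(pos.sum()),
                     "sensitivity": sens, "sens_ci_low": sens_ci[0],
                     "sens_ci_high": sens_ci[1], "specificity": spec,
                     "spec_ci_low": spec_ci[0], "spec_ci_high": spec_ci[1],
                     "auc": auc, "auc_ci_low": auc_ci[0],
                     "auc_ci_high": auc_ci[1]})
    overall = micro_average(
        {c: scores[:, i] for i, c in enumerate(CATEGORIES)},
        {c: reference[:, i] for i, c in enumerate(CATEGORIES)},
        {c: determinations[:, i] for i, c in enumerate(CATEGORIES)})
    auc_ci = bootstrap_ci(
        lambda idx: _safe_auc(scores[idx].ravel(), reference[idx].ravel()),
        n_cases, m=m, seed=seed + 3)
    overall["auc_ci"] = auc_ci
    mean_iou = {}
    if iou_by_category:
        mean_iou = {c: float(np.mean(v)) for c, v in iou_by_category.items()
                    if len(v) > 0}
    return EvalReport(per_category=pd.DataFrame(rows), overall=overall,
                      mean_iou=mean_iou)


def _ci_or_nan(fn, n_cases, m, seed, cat):
    """Bootstrap CI, degrading to (nan, nan) when the class balance is too
    fragile for case resampling (small strata)."""
    try:
        return bootstrap_ci(fn, n_cases, m=m, seed=seed)
    except ValueError:
        warnings.warn(f"category {cat!r}: bootstrap CI undefined (too many "
                      "single-class resamples)")
        return (float("nan"), float("nan"))


def _safe_auc(s, y):
    y = np.asarray(y).astype(int)
    if y.min() == y.max():
        return np.nan
    return roc_auc(s, y)


def _safe_rate(calls, y, target):
    sel = np.asarray(y).astype(int) == target
    if not sel.any():
        return np.nan
    return float(np.asarray(calls)[sel].mean())
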