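"""Post-processing: operating points, binary determinations, bounding boxes.

The device emits two outputs per category: a binary abnormality-present
determination, obtained by comparing the beta-binomial posterior mean
against a category-specific decision threshold calibrated on a tuning set
to equalize sensitivity and specificity, and a set of bounding boxes placed
around high-probability regions of the (upsampled) localization map after
binarizing it at a category-specific map threshold. Thresholds are frozen
after calibration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .synthdata import CATEGORIES

__all__ = [
    "OperatingPoints",
    "BoundingBox",
    "point_estimate",
    "calibrate_thresholds",
    "calibrate_map_thresholds",
    "binary_determination",
    "extract_boxes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in image pixel coordinates, 0-based half-open."""

    row0: int
    col0: int
    row1: int
    col1: int
    category: str
    score: float

    def __post_init__(self):
        if not (self.row1 > self.row0 and self.col1 > self.col0):
            raise ValueError("bounding box must have positive area")

    @property
    def coords(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.row1, self.col1)

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass
class OperatingPoints:
    """Frozen per-category decision and map-binarization thresholds."""

    decision_threshold: dict[str, float]
    map_threshold: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in CATEGORIES})
    achieved: dict[str, tuple[float, float]] = field(default_factory=dict)
    calibration_fingerprint: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "decision_threshold": self.decision_threshold,
            "map_threshold": self.map_threshold,
            "achieved": {k: list(v) for k, v in self.achieved.items()},
            "calibration_fingerprint": self.calibration_fingerprint,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OperatingPoints":
        d = json.loads(Path(path).read_text())
        return cls(decision_threshold=d["decision_threshold"],
                   map_threshold=d["map_threshold"],
                   achieved={k: tuple(v) for k, v in d["achieved"].items()},
                   calibration_fingerprint=d["calibration_fingerprint"])


def point_estimate(alpha: float, beta: float) -> float:
    """Posterior-mean score of a beta-binomial category output."""
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be strictly positive")
    return alpha / (alpha + beta)


def _equal_sens_spec_threshold(scores: np.ndarray, reference: np.ndarray
                               ) -> tuple[float, float, float]:
    """Threshold minimizing |sens - spec| over midpoint candidates.

    Candidates are midpoints of adjacent sorted unique scores plus +-inf
    sentinels; ties break toward higher sensitivity (lower threshold).
    """
    scores = np.asarray(scores, float)
    reference = np.asarray(reference).astype(int)
    pos = scores[reference == 1]
    neg = scores[reference == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("calibration needs at least one positive and one "
                         "negative reference case")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, candidates, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, candidates, side="left") / neg.size
    gap = np.abs(sens - spec)
    best_gap = gap.min()
    tied = np.flatnonzero(gap == best_gap)
    best = tied[np.argmax(sens[tied])]  # higher sensitivity wins ties
    return float(candidates[best]), float(sens[best]), float(spec[best])


def calibrate_thresholds(tune_scores: Mapping[str, np.ndarray],
                         tune_reference: Mapping[str, np.ndarray],
                         fingerprint: Mapping | None = None
                         ) -> OperatingPoints:
    """Per-category decision thresholds equalizing sensitivity/specificity.

    ``tune_scores[cat]`` are posterior-mean scores on the tuning set and
    ``tune_reference[cat]`` the binary reference standard. The achieved
    (sensitivity, specificity) per category is recorded on the result.
    """
    thresholds, achieved = {}, {}
    for cat in tune_scores:
        thr, sens, spec = _equal_sens_spec_threshold(
            np.asarray(tune_scores[cat]), np.asarray(tune_reference[cat]))
        thresholds[cat] = thr
        achieved[cat] = (sens, spec)
    fp = dict(fingerprint or {})
    fp.setdefault("date", date.today().isoformat())
    fp.setdefault("n_tune_cases", int(len(next(iter(tune_scores.values())))))
    return OperatingPoints(decision_threshold=thresholds, achieved=achieved,
                           calibration_fingerprint=fp)


def calibrate_map_thresholds(operating_points: OperatingPoints,
                             upsampled_maps: Mapping[str, Sequence[np.ndarray]],
                             ref_boxes: Mapping[str, Sequence[list]],
                             grid: Sequence[float] = tuple(
                                 np.round(np.arange(0.05, 0.95, 0.05), 2)),
                             min_area_frac: float = 5e-4) -> OperatingPoints:
    """Pick per-category map-binarization thresholds maximizing mean IoU on a
    tuning set of (upsampled map, reference boxes) pairs; frozen thereafter."""
    from .evaluation import summed_iou

    for cat, maps in upsampled_maps.items():
        boxes_list = ref_boxes[cat]
        best_thr, best_iou = 0.5, -1.0
        for thr in grid:
            ious = []
            for m, refs in zip(maps, boxes_list):
                if not refs:
                    continue
                pred = extract_boxes(m, float(thr), cat,
                                     min_area_frac=min_area_frac)
                ious.append(summed_iou([b.coords for b in pred], refs,
                                       m.shape))
            if ious and float(np.mean(ious)) > best_iou:
                best_iou = float(np.mean(ious))
                best_thr = float(thr)
        operating_points.map_threshold[cat] = best_thr
    return operating_points


def binary_determination(score: float, operating_points: OperatingPoints,
                         category: str) -> str:
    """'present' iff the score lies on or above the decision threshold."""
    thr = operating_points.decision_threshold[category]
    return "present" if score >= thr else "absent"


def extract_boxes(probability_map: np.ndarray, map_threshold: float,
                  category: str, min_area_frac: float = 5e-4
                  ) -> list[BoundingBox]:
    """Boxes around high-probability regions of an image-resolution map.

    Binarizes the map at ``map_threshold``, finds 4-connected components,
    drops components smaller than ``min_area_frac`` of the image area, and
    returns each surviving component's tight bounding box with the maximum
    map value inside as its score.
    """
    probability_map = np.asarray(probability_map, float)
    mask = probability_map >= map_threshold
    if not mask.any():
        return []
    min_area = max(int(min_area_frac * probability_map.size), 1)
    labeled = cc_label(mask, connectivity=1)
    boxes = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        score = float(probability_map[labeled == region.label].max())
        boxes.append(BoundingBox(int(r0), int(c0), int(r1), int(c1),
                                 category=category, score=score))
    return boxes


def device_output(scores: Mapping[str, float],
                  upsampled_maps: Mapping[str, np.ndarray],
                  operating_points: OperatingPoints) -> dict:
    """The device's two outputs per category: determination plus boxes."""
    out = {}
    for cat, score in scores.items():
        det = binary_determination(score, operating_points, cat)
        boxes = extract_boxes(upsampled_maps[cat],
                              operating_points.map_threshold[cat], cat)
        if det == "present" and not boxes:
            warnings.warn(f"category {cat!r}: present determination with an "
                          "empty box list")
        out[cat] = {"present": det == "present", "score": float(score),
                    "boxes": [list(b.coords) for b in boxes]}
    return out
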