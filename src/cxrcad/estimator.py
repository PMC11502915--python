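"""Scikit-learn style front end for the CAD pipeline.

:class:`CadDetector` wraps standardization, network training, operating-point
calibration and box extraction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` estimator surface so the pipeline composes with sklearn
model selection. ``X`` is a sequence of cases (each a list of 1-2 grayscale
arrays, or a :class:`~cxrcad.synthdata.SyntheticCase`) and ``y`` a sequence
of :class:`~cxrcad.synthdata.CaseLabels`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, upsample_map
from .postprocess import calibrate_thresholds, extract_boxes
from .preprocess import (
    PreprocessConfig,
    preprocess_image,
    standardize_case_labels,
)
from .synthdata import CATEGORIES, CaseLabels, SyntheticCase
from .training import AugmentConfig, TrainingConfig, train

__all__ = ["CadDetector"]


def _case_images(case) -> list[np.ndarray]:
    if isinstance(case, SyntheticCase):
        return case.images
    return list(case)


class CadDetector(BaseEstimator):
    """Case-level abnormality detector with 8 category outputs.

    Parameters mirror the preprocessing, network and training configuration;
    after ``fit`` the estimator holds the trained network (best tuning
    epoch), the training history, and the frozen per-category operating
    points calibrated on an internal tuning split.

    Attributes
    ----------
    network_ : CadNetwork
        Trained analysis-stage network.
    history_ : pandas.DataFrame
        Per-epoch loss terms and tuning-set mean AUC.
    operating_points_ : OperatingPoints
        Frozen decision/map thresholds (equal sens/spec calibration).
    categories_ : tuple of str
        The 8 output categories, fixed.
    """

    def __init__(self, target_height: int = 64, target_width: int = 80,
                 channels: tuple = (16, 32, 64), image_feature_dim: int = 64,
                 case_feature_dim: int = 128, learning_rate: float = 2e-3,
                 weight_decay: float = 1e-4, batch_size: int = 16,
                 max_epochs: int = 30, patience: int = 10,
                 loc_loss_weight: float = 1.0, augment: bool = True,
                 tune_fraction: float = 0.2, random_state: int = 0):
        self.target_height = target_height
        self.target_width = target_width
        self.channels = channels
        self.image_feature_dim = image_feature_dim
        self.case_feature_dim = case_feature_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.loc_loss_weight = loc_loss_weight
        self.augment = augment
        self.tune_fraction = tune_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _preprocess_cfg(self) -> PreprocessConfig:
        return PreprocessConfig.test_profile(self.target_height,
                                             self.target_width)

    def _standardize_case(self, case) -> list[np.ndarray]:
        cfg = self._preprocess_cfg()
        return [preprocess_image(img, cfg) for img in _case_images(case)]

    def fit(self, X: Sequence, y: Sequence[CaseLabels],
            tune_X: Sequence | None = None,
            tune_y: Sequence[CaseLabels] | None = None) -> "CadDetector":
        """Train on cases ``X`` with k-of-n labels ``y``.

        A tuning set drives early stopping and operating-point calibration;
        if not supplied, a ``tune_fraction`` split is carved from ``X``.
        Labeler boxes in ``y`` are given in the raw image coordinates of
        ``X`` and are mapped to the standardized grid together with the
        images (inputs already at the target size are passed through, boxes
        assumed standardized).
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        cases = [self._as_case(c, f"fit-{i:05d}") for i, c in enumerate(X)]
        labels = list(y)
        if tune_X is None:
            rng = np.random.default_rng(self.random_state)
            n_tune = max(int(round(self.tune_fraction * len(cases))), 1)
            perm = rng.permutation(len(cases))
            tune_idx = set(perm[:n_tune].tolist())
            tune_cases = [cases[i] for i in sorted(tune_idx)]
            tune_labels = [labels[i] for i in sorted(tune_idx)]
            cases = [c for i, c in enumerate(cases) if i not in tune_idx]
            labels = [l for i, l in enumerate(labels) if i not in tune_idx]
        else:
            tune_cases = [self._as_case(c, f"tune-{i:05d}")
                          for i, c in enumerate(tune_X)]
            tune_labels = list(tune_y)

        cases, labels = self._standardize_pairs(cases, labels)
        tune_cases, tune_labels = self._standardize_pairs(tune_cases,
                                                          tune_labels)
        model_cfg = ModelConfig(
            input_shape=(self.target_height, self.target_width),
            channels=tuple(self.channels),
            image_feature_dim=self.image_feature_dim,
            case_feature_dim=self.case_feature_dim)
        train_cfg = TrainingConfig(
            batch_size_cases=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            loss_weight_localization=self.loc_loss_weight,
            max_epochs=self.max_epochs,
            early_stop_patience_epochs=self.patience,
            augment=AugmentConfig() if self.augment else None,
            seed=self.random_state)
        self.network_, self.history_ = train(cases, labels, tune_cases,
                                             tune_labels, train_cfg,
                                             model_config=model_cfg)
        scores = np.stack([self.network_.predict_case(c.images).scores()
                           for c in tune_cases])
        refs = np.stack([l.reference for l in tune_labels])
        tune_scores, tune_refs = {}, {}
        for ci, cat in enumerate(CATEGORIES):
            if refs[:, ci].min() != refs[:, ci].max():
                tune_scores[cat] = scores[:, ci]
                tune_refs[cat] = refs[:, ci]
        self.operating_points_ = calibrate_thresholds(
            tune_scores, tune_refs,
            fingerprint={"tune_set": f"{len(tune_cases)} cases"})
        for cat in CATEGORIES:  # categories uncalibratable on this tune set
            self.operating_points_.decision_threshold.setdefault(cat, 0.5)
        self.categories_ = CATEGORIES
        return self

    def _as_case(self, case, fallback_id: str) -> SyntheticCase:
        if isinstance(case, SyntheticCase):
            return case
        return SyntheticCase(case_id=fallback_id, images=list(case),
                             truths=[], patient_meta={})

    def _standardize_pairs(self, cases, labels):
        cfg = self._preprocess_cfg()
        target = (self.target_height, self.target_width)
        out_cases, out_labels = [], []
        for case, lab in zip(cases, labels):
            if all(img.shape == target for img in case.images):
                out_cases.append(case)
                out_labels.append(lab)
                continue
            shapes = [img.shape for img in case.images]
            out_cases.append(SyntheticCase(
                case_id=case.case_id,
                images=[preprocess_image(i, cfg) for i in case.images],
                truths=[], patient_meta=case.patient_meta))
            out_labels.append(standardize_case_labels(lab, shapes, cfg))
        return out_cases, out_labels

    # ------------------------------------------------------------------

    def predict_proba(self, X: Sequence) -> np.ndarray:
        """Posterior-mean abnormality score per case and category, (n, 8)."""
        check_is_fitted(self, "network_")
        return np.stack([
            self.network_.predict_case(self._standardize_case(c)).scores()
            for c in X])

    def predict(self, X: Sequence) -> np.ndarray:
        """Binary determinations at the frozen operating points, (n, 8)."""
        check_is_fitted(self, "operating_points_")
        proba = self.predict_proba(X)
        thr = np.array([self.operating_points_.decision_threshold[c]
                        for c in CATEGORIES])
        return (proba >= thr[None, :]).astype(int)

    def predict_boxes(self, X: Sequence) -> list[dict]:
        """Per-case, per-category bounding boxes in image pixel coordinates."""
        check_is_fitted(self, "operating_points_")
        out = []
        for case in X:
            imgs = self._standardize_case(case)
            pred = self.network_.predict_case(imgs)
            per_cat: dict = {}
            for ci, cat in enumerate(CATEGORIES):
                boxes = []
                for img_i, m in enumerate(pred.prob_maps):
                    up = upsample_map(m[ci], imgs[img_i].shape,
                                      self.network_.config.loc_upsample)
                    for b in extract_boxes(
                            up, self.operating_points_.map_threshold[cat],
                            cat):
                        boxes.append({"image_index": img_i,
                                      "box": list(b.coords),
                                      "score": b.score})
                per_cat[cat] = boxes
            out.append(per_cat)
        return out

    def score(self, X: Sequence, y: Sequence[CaseLabels]) -> float:
        """Micro-averaged AUC of posterior-mean scores against the
        majority-vote reference standard."""
        from .evaluation import roc_auc

        proba = self.predict_proba(X)
        refs = np.stack([l.reference for l in y])
        return roc_auc(proba.ravel(), refs.ravel())
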