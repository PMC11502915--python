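"""Supervised training: joint loss, augmentation, optimization, early stop.

The joint loss per case sums, over the 8 output categories, a localization
term and a classification term:

* localization — the across-radiograph average of the per-pixel binary
  cross-entropy between the predicted probability map and the ground-truth
  map (reference boxes rasterized at localization resolution);
* classification — the negative log-likelihood of the beta-binomial
  distribution for the observed k-of-n labeler counts,
  ``-log[ C(n,k) B(k+a, n-k+b) / B(a,b) ]``, weighted by a per-category
  factor (default 1).

Optimization is AdamW over randomized batches of cases; after each epoch the
across-category mean AUC on a tuning set (scored by the posterior mean
``a/(a+b)``) drives early stopping with a fixed patience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, gammaln
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .model import CadNetwork, ModelConfig
from .nn import AdamW, sigmoid
from .synthdata import CATEGORIES, CaseLabels, SyntheticCase

__all__ = [
    "TrainingConfig",
    "AugmentConfig",
    "beta_binomial_nll",
    "beta_binomial_nll_grad",
    "pixel_bce",
    "joint_loss",
    "ground_truth_masks",
    "augment",
    "EarlyStopper",
    "train",
    "tune_mean_auc",
]

_BCE_EPS = 1e-7


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _validate_kn(alpha, beta, k, n):
    alpha, beta = np.asarray(alpha, float), np.asarray(beta, float)
    k, n = np.asarray(k), np.asarray(n)
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("labels must satisfy 0 <= k <= n with n >= 1")
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("alpha and beta must be strictly positive")
    return alpha, beta, k, n


def beta_binomial_nll(alpha, beta, k, n):
    """Negative log-likelihood of k successes in n beta-binomial trials.

    Computed entirely in log space via log-gamma, so it is finite for all
    valid inputs. Broadcasts over array arguments.
    """
    alpha, beta, k, n = _validate_kn(alpha, beta, k, n)
    log_comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    ll = log_comb + betaln(k + alpha, n - k + beta) - betaln(alpha, beta)
    return -ll


def beta_binomial_nll_grad(alpha, beta, k, n):
    """Analytic (d/dalpha, d/dbeta) of ``beta_binomial_nll``."""
    alpha, beta, k, n = _validate_kn(alpha, beta, k, n)
    dab = digamma(alpha + beta)
    dnab = digamma(n + alpha + beta)
    da = -(digamma(k + alpha) - dnab - digamma(alpha) + dab)
    db = -(digamma(n - k + beta) - dnab - digamma(beta) + dab)
    return da, db


def pixel_bce(predicted_map: np.ndarray, truth_map: np.ndarray,
              eps: float = _BCE_EPS) -> float:
    """Mean per-pixel binary cross-entropy between a probability map and a
    binary ground-truth map (predictions epsilon-clipped)."""
    predicted_map = np.asarray(predicted_map, float)
    truth_map = np.asarray(truth_map, float)
    if predicted_map.shape != truth_map.shape:
        raise ValueError("prediction and truth maps must share a shape")
    p = np.clip(predicted_map, eps, 1.0 - eps)
    return float(-np.mean(truth_map * np.log(p)
                          + (1.0 - truth_map) * np.log(1.0 - p)))


def joint_loss(prediction, labels: CaseLabels,
               truth_maps: Sequence[np.ndarray],
               weights: Mapping[str, float] | float = 1.0) -> dict:
    """Per-case joint loss with a per-term breakdown.

    ``prediction`` is a :class:`~cxrcad.model.CasePrediction`;
    ``truth_maps`` holds one (K, h, w) binary array per image of the case.
    Returns ``{"total", "bce", "nll", "per_category"}``.
    """
    w = {c: (weights[c] if isinstance(weights, Mapping) else float(weights))
         for c in CATEGORIES}
    n_img = len(prediction.prob_maps)
    per_cat = {}
    total_bce = total_nll = 0.0
    for ci, cat in enumerate(CATEGORIES):
        bce = float(np.mean([pixel_bce(prediction.prob_maps[i][ci],
                                       truth_maps[i][ci])
                             for i in range(n_img)]))
        post = prediction.posteriors[cat]
        nll = float(beta_binomial_nll(post.alpha, post.beta,
                                      int(labels.k[ci]), int(labels.n[ci])))
        per_cat[cat] = {"bce": bce, "nll": nll,
                        "weighted": w[cat] * bce + nll}
        total_bce += w[cat] * bce
        total_nll += nll
    return {"total": total_bce + total_nll, "bce": total_bce,
            "nll": total_nll, "per_category": per_cat}


# ---------------------------------------------------------------------------
# ground-truth maps
# ---------------------------------------------------------------------------

def ground_truth_masks(labels: CaseLabels, image_shapes: Sequence[tuple],
                       ) -> list[np.ndarray]:
    """Rasterize reference boxes into per-image (K, H, W) binary masks."""
    masks = [np.zeros((len(CATEGORIES),) + tuple(s)) for s in image_shapes]
    for ci in range(len(CATEGORIES)):
        for img_idx, (r0, c0, r1, c1) in labels.boxes[ci]:
            masks[img_idx][ci, r0:r1, c0:c1] = 1.0
    return masks


def downsample_mask(mask: np.ndarray, map_shape: tuple[int, int]
                    ) -> np.ndarray:
    """Block-max downsample a (K, H, W) mask to localization resolution."""
    k, h, w = mask.shape
    mh, mw = map_shape
    if h % mh or w % mw:
        raise ValueError("image shape must be a multiple of the map shape")
    return mask.reshape(k, mh, h // mh, mw, w // mw).max(axis=(2, 4))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform application probabilities and ranges."""

    p_hflip: float = 0.5
    p_vflip: float = 0.2
    p_rotate: float = 0.5
    max_rotate_deg: float = 10.0
    p_gamma: float = 0.5
    gamma_range: tuple[float, float] = (0.8, 1.25)
    p_contrast: float = 0.5
    contrast_range: tuple[float, float] = (0.9, 1.1)
    p_crop: float = 0.3
    min_crop_area: float = 0.9

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_hflip=0, p_vflip=0, p_rotate=0, p_gamma=0,
                   p_contrast=0, p_crop=0)


def augment(image: np.ndarray, truth_masks: np.ndarray, seed,
            cfg: AugmentConfig = AugmentConfig()):
    """Randomly flip/rotate/crop an image with its (K, H, W) truth masks and
    gamma/contrast-adjust the image only. Geometric transforms are applied
    identically to image and masks; the output keeps the input shape."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img = np.asarray(image, float)
    masks = np.asarray(truth_masks, float)
    h, w = img.shape
    if rng.random() < cfg.p_hflip:
        img = img[:, ::-1]
        masks = masks[:, :, ::-1]
    if rng.random() < cfg.p_vflip:
        img = img[::-1]
        masks = masks[:, ::-1]
    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg)
        img = _sk_rotate(img, angle, order=1, mode="edge",
                         preserve_range=True)
        masks = np.stack([_sk_rotate(m, angle, order=0, mode="constant",
                                     preserve_range=True) for m in masks])
    if rng.random() < cfg.p_crop:
        frac = np.sqrt(rng.uniform(cfg.min_crop_area, 1.0))
        ch, cw = max(int(round(h * frac)), 1), max(int(round(w * frac)), 1)
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        img = _sk_resize(img[r0:r0 + ch, c0:c0 + cw], (h, w), order=1,
                         mode="edge", preserve_range=True, anti_aliasing=False)
        masks = np.stack([
            _sk_resize(m[r0:r0 + ch, c0:c0 + cw], (h, w), order=0,
                       mode="edge", preserve_range=True, anti_aliasing=False)
            for m in masks])
    if rng.random() < cfg.p_gamma:
        gamma = rng.uniform(*cfg.gamma_range)
        img = np.clip(img, 0.0, 1.0) ** gamma
    if rng.random() < cfg.p_contrast:
        scale = rng.uniform(*cfg.contrast_range)
        img = np.clip(0.5 + (img - 0.5) * scale, 0.0, 1.0)
    return np.ascontiguousarray(img), (masks > 0.5).astype(float)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    batch_size_cases: int = 16
    learning_rate: float = 2e-3
    weight_decay: float = 1e-4
    loss_weight_localization: Mapping[str, float] | float = 1.0
    max_epochs: int = 30
    early_stop_patience_epochs: int = 10
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size_cases < 1:
            raise ValueError("batch size must be >= 1")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")


class EarlyStopper:
    """Stop when the monitored metric has not improved for ``patience``
    consecutive epochs; tracks the best epoch seen."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_metric = -np.inf
        self.best_epoch = 0

    def update(self, epoch: int, metric: float) -> bool:
        """Record the epoch metric; returns True when training should stop."""
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def tune_mean_auc(network: CadNetwork, cases: Sequence[SyntheticCase],
                  labels: Sequence[CaseLabels],
                  preprocessed: Sequence[list[np.ndarray]] | None = None,
                  ) -> float:
    """Across-category mean AUC of posterior-mean scores on a tuning set.

    Categories without both classes in the reference standard are excluded
    from the mean (with a warning when all are excluded).
    """
    from .evaluation import roc_auc

    scores = np.stack([
        network.predict_case(preprocessed[i] if preprocessed is not None
                             else cases[i].images).scores()
        for i in range(len(cases))])
    refs = np.stack([lab.reference for lab in labels])
    aucs = []
    for ci in range(len(CATEGORIES)):
        y = refs[:, ci]
        if y.min() == y.max():
            continue
        aucs.append(roc_auc(scores[:, ci], y))
    if not aucs:
        import warnings

        warnings.warn("no category had both classes in the tuning set")
        return float("nan")
    return float(np.mean(aucs))


def _prepare_case(case, labels, map_shape, aug_cfg, rng):
    imgs, masks = [], []
    full_masks = ground_truth_masks(labels, [im.shape for im in case.images])
    for i, img in enumerate(case.images):
        m = full_masks[i]
        if aug_cfg is not None:
            img, m = augment(img, m, rng, aug_cfg)
        imgs.append(img)
        masks.append(downsample_mask(m, map_shape))
    return imgs, masks


def train(train_set: Sequence[SyntheticCase],
          train_labels: Sequence[CaseLabels],
          tune_set: Sequence[SyntheticCase],
          tune_labels: Sequence[CaseLabels],
          cfg: TrainingConfig,
          model_config: ModelConfig | None = None,
          ) -> tuple[CadNetwork, pd.DataFrame]:
    """Train the analysis network; returns (best-epoch network, history).

    Images are assumed standardized to ``model_config.input_shape``. History
    has one row per epoch: total/bce/nll training loss and tuning-set mean
    AUC. The returned network carries the weights of the best tuning epoch.
    """
    ids = {c.case_id for c in train_set} & {c.case_id for c in tune_set}
    if ids:
        raise ValueError(f"train and tune sets overlap: {sorted(ids)[:3]}")
    model_config = model_config or ModelConfig.test_profile(
        train_set[0].images[0].shape)
    seed_seq = np.random.SeedSequence(cfg.seed & 0x7FFFFFFF)
    init_seed, shuffle_seed, aug_seed = \
        (int(s) for s in seed_seq.generate_state(3) & 0x7FFFFFFF)
    network = CadNetwork(model_config, seed=init_seed)
    optimizer = AdamW(network.parameters(), lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    aug_rng = np.random.default_rng(aug_seed)
    weights = np.array([
        cfg.loss_weight_localization[c]
        if isinstance(cfg.loss_weight_localization, Mapping)
        else float(cfg.loss_weight_localization) for c in CATEGORIES])

    map_shape = model_config.map_shape
    stopper = EarlyStopper(cfg.early_stop_patience_epochs)
    best_weights = network.get_weights()
    history = []
    kcat = len(CATEGORIES)

    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_set))
        epoch_bce = epoch_nll = 0.0
        for start in range(0, len(order), cfg.batch_size_cases):
            batch_idx = order[start:start + cfg.batch_size_cases]
            images, case_index, masks = [], [], []
            kk = np.zeros((len(batch_idx), kcat))
            nn_ = np.zeros((len(batch_idx), kcat))
            for bi, ci in enumerate(batch_idx):
                imgs, ms = _prepare_case(train_set[ci], train_labels[ci],
                                         map_shape, cfg.augment, aug_rng)
                images.extend(imgs)
                masks.extend(ms)
                case_index.extend([bi] * len(imgs))
                kk[bi] = train_labels[ci].k
                nn_[bi] = train_labels[ci].n
            x = np.stack(images)[:, None]
            case_index = np.asarray(case_index)
            out = network.forward(x, case_index)

            b = len(batch_idx)
            # classification term and gradient
            nll = beta_binomial_nll(out["alpha"], out["beta"], kk, nn_)
            da, db = beta_binomial_nll_grad(out["alpha"], out["beta"],
                                            kk, nn_)
            dalpha = da / b
            dbeta = db / b
            # localization term: per-category pixel BCE averaged over the
            # case's radiographs, summed over categories, averaged over batch
            y = np.stack(masks)  # (n_images, K, h, w)
            p = np.clip(sigmoid(out["loc_logits"]), _BCE_EPS, 1 - _BCE_EPS)
            n_img_per_case = np.bincount(case_index, minlength=b)
            img_w = (1.0 / n_img_per_case)[case_index]
            npix = y.shape[2] * y.shape[3]
            bce_per_img = -(y * np.log(p) + (1 - y) * np.log(1 - p)
                            ).mean(axis=(2, 3))
            bce_total = float(((bce_per_img * weights[None, :]).sum(axis=1)
                               * img_w).sum() / b)
            dlogits = (p - y) * weights[None, :, None, None] \
                * img_w[:, None, None, None] / (npix * b)

            optimizer.zero_grad()
            network.backward(dalpha, dbeta, dlogits)
            optimizer.step()
            epoch_nll += float(nll.sum(axis=1).mean()) * b
            epoch_bce += bce_total * b

        mean_auc = tune_mean_auc(network, tune_set, tune_labels)
        history.append({"epoch": epoch,
                        "train_bce": epoch_bce / len(train_set),
                        "train_nll": epoch_nll / len(train_set),
                        "train_loss": (epoch_bce + epoch_nll) / len(train_set),
                        "tune_mean_auc": mean_auc})
        improved = mean_auc > stopper.best_metric
        stop = stopper.update(epoch, mean_auc)
        if improved:
            best_weights = network.get_weights()
        if stop:
            break

    network.set_weights(best_weights)
    return network, pd.DataFrame(history)
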