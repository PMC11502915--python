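"""The analysis-stage network: per-image encoder, case-level max pooling,
beta-binomial classification branch and convolutional localization branch.

Architecture (per case of 1-2 standardized radiographs):

1. each radiograph runs through a shared convolutional encoder producing
   spatial feature maps (the encoder's penultimate stage) and, after global
   average pooling plus a fully connected layer, one ``image_feature_dim``
   feature vector per radiograph;
2. each image feature vector passes through a shared fully connected layer
   to ``case_feature_dim`` and the per-image vectors are collapsed into a
   single case embedding by elementwise max pooling — the prediction is
   therefore invariant to image order and to duplicated images;
3. a fully connected classification head maps the case embedding to strictly
   positive ``(alpha, beta)`` pairs, one per category, parameterizing a
   beta-binomial distribution over how many of ``n`` expert labelers would
   call the category present;
4. a 1x1 convolutional localization head maps each image's penultimate
   feature maps to one per-category probability map (sigmoid), from which
   bounding boxes are extracted after upsampling to pixel coordinates.

The encoder depth/width is configurable: the desk-scale test profile is a
small 3-block CNN; the full-scale profile records the reference geometry
(512-dim image features, 1024-dim case embedding, 800x1024 inputs) behind
the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from . import nn
from .synthdata import CATEGORIES

__all__ = [
    "ModelConfig",
    "CategoryPosterior",
    "CasePrediction",
    "CadNetwork",
    "upsample_map",
]

_ALPHA_FLOOR = 1e-4  # keeps the Beta prior away from degeneracy


@dataclass(frozen=True)
class ModelConfig:
    """Network geometry; ``input_shape`` must match the preprocess target."""

    input_shape: tuple[int, int] = (64, 80)
    channels: tuple[int, ...] = (16, 32, 64)
    image_feature_dim: int = 64
    case_feature_dim: int = 128
    n_categories: int = len(CATEGORIES)
    loc_upsample: str = "bilinear"  # or "nearest"
    #: spatial pooling for the image feature vector; "max" retains small
    #: localized signals through a shallow encoder, "avg" suits deep ones
    feature_pooling: str = "max"

    def __post_init__(self):
        if self.n_categories != len(CATEGORIES):
            raise ValueError("the device defines exactly 8 output categories")
        stride = 2 ** len(self.channels)
        if self.input_shape[0] % stride or self.input_shape[1] % stride:
            raise ValueError(
                f"input shape must be divisible by encoder stride {stride}")

    @property
    def encoder_stride(self) -> int:
        return 2 ** len(self.channels)

    @property
    def loc_stride(self) -> int:
        # localization taps the penultimate encoder block (one pool fewer)
        return 2 ** (len(self.channels) - 1)

    @property
    def map_shape(self) -> tuple[int, int]:
        s = self.loc_stride
        return self.input_shape[0] // s, self.input_shape[1] // s

    @classmethod
    def test_profile(cls, input_shape=(64, 80)) -> "ModelConfig":
        return cls(input_shape=input_shape)

    @classmethod
    def full_profile(cls) -> "ModelConfig":
        """Reference geometry of the full-scale system (residual encoder,
        512-dim image features, 1024-dim case embedding)."""
        return cls(input_shape=(800, 1024), channels=(64, 128, 256, 512),
                   image_feature_dim=512, case_feature_dim=1024,
                   feature_pooling="avg")


@dataclass(frozen=True)
class CategoryPosterior:
    """Beta-binomial parameters for one category; mean = alpha/(alpha+beta)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be strictly positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class CasePrediction:
    """Model outputs for one case: per-category posteriors and per-image
    per-category probability maps at localization resolution."""

    posteriors: dict[str, CategoryPosterior]
    prob_maps: list[np.ndarray]  # one (K, h, w) array per image
    model_version: str = "cxrcad-0.1"

    def scores(self) -> np.ndarray:
        return np.array([self.posteriors[c].mean for c in CATEGORIES])


class CadNetwork:
    """Case-level CNN with classification and localization branches."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        ch = (1,) + tuple(config.channels)
        self.blocks = []
        for i in range(len(config.channels)):
            self.blocks.append((nn.Conv2d(ch[i], ch[i + 1], 3, padding=1,
                                          rng=rng),
                                nn.ReLU(), nn.MaxPool2d()))
        self.gap = (nn.GlobalMaxPool() if config.feature_pooling == "max"
                    else nn.GlobalAvgPool())
        self.feat = nn.Linear(config.channels[-1], config.image_feature_dim,
                              rng=rng)
        self.proj = nn.Linear(config.image_feature_dim,
                              config.case_feature_dim, rng=rng)
        self.cls = nn.Linear(config.case_feature_dim,
                             2 * config.n_categories, rng=rng)
        # localization branch: one 3x3 conv on the penultimate block's maps
        self.loc = nn.Conv2d(config.channels[-2] if len(config.channels) > 1
                             else config.channels[-1],
                             config.n_categories, 3, padding=1, rng=rng)
        self._cache = None

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        params = []
        for conv, _, _ in self.blocks:
            params.extend(conv.parameters())
        for layer in (self.feat, self.proj, self.cls, self.loc):
            params.extend(layer.parameters())
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data[...] = w

    # -- forward ------------------------------------------------------------

    def _check_input(self, images: np.ndarray) -> None:
        if images.ndim != 4 or images.shape[1] != 1 or \
                images.shape[2:] != self.config.input_shape:
            raise ValueError(
                f"expected images of shape (N, 1, {self.config.input_shape[0]},"
                f" {self.config.input_shape[1]}), got {images.shape}")

    def forward(self, images: np.ndarray, case_index: np.ndarray) -> dict:
        """Forward pass over a batch of images grouped into cases.

        ``images``: (n_images, 1, H, W); ``case_index``: (n_images,)
        non-decreasing case ids in [0, n_cases). Returns alpha/beta of shape
        (n_cases, K), localization logits (n_images, K, h, w) and caches for
        ``backward``.
        """
        images = np.asarray(images, dtype=np.float64)
        self._check_input(images)
        case_index = np.asarray(case_index)
        if np.any(np.diff(case_index) < 0):
            raise ValueError("case_index must be grouped and non-decreasing")
        n_cases = int(case_index[-1]) + 1

        x = images
        for conv, relu, pool in self.blocks[:-1]:
            x = pool.forward(relu.forward(conv.forward(x)))
        maps = x  # penultimate-stage feature maps, (n_images, C, h, w)
        conv, relu, pool = self.blocks[-1]
        top = pool.forward(relu.forward(conv.forward(maps)))
        g = self.gap.forward(top)
        f = self.feat.forward(g)
        p = self.proj.forward(f)

        k = self.config.case_feature_dim
        emb = np.full((n_cases, k), -np.inf)
        np.maximum.at(emb, case_index, p)
        # winner image per (case, dim) for max-pool backward; first winner on ties
        winner = np.full((n_cases, k), -1, dtype=int)
        for i in range(len(case_index) - 1, -1, -1):
            c = case_index[i]
            winner[c][p[i] == emb[c]] = i

        raw = self.cls.forward(emb)
        kcat = self.config.n_categories
        alpha = nn.softplus(raw[:, :kcat]) + _ALPHA_FLOOR
        beta = nn.softplus(raw[:, kcat:]) + _ALPHA_FLOOR
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise FloatingPointError(
                "non-finite activations in the classification head")
        loc_logits = self.loc.forward(maps)

        self._cache = {"raw": raw, "winner": winner, "n_images": len(images),
                       "case_index": case_index}
        return {"alpha": alpha, "beta": beta, "loc_logits": loc_logits,
                "loc_maps": nn.sigmoid(loc_logits)}

    def backward(self, dalpha: np.ndarray, dbeta: np.ndarray,
                 dloc_logits: np.ndarray) -> None:
        """Accumulate parameter gradients for the given output gradients."""
        cache = self._cache
        raw, winner = cache["raw"], cache["winner"]
        kcat = self.config.n_categories
        draw = np.concatenate([dalpha * nn.sigmoid(raw[:, :kcat]),
                               dbeta * nn.sigmoid(raw[:, kcat:])], axis=1)
        demb = self.cls.backward(draw)
        dp = np.zeros((cache["n_images"], self.config.case_feature_dim))
        rows = np.repeat(np.arange(winner.shape[0]), winner.shape[1])
        cols = np.tile(np.arange(winner.shape[1]), winner.shape[0])
        np.add.at(dp, (winner.ravel(), cols), demb[rows, cols])
        df = self.proj.backward(dp)
        dg = self.feat.backward(df)
        conv, relu, pool = self.blocks[-1]
        dx = conv.backward(relu.backward(pool.backward(
            self.gap.backward(dg))))
        dx = dx + self.loc.backward(dloc_logits)  # branch junction
        for conv, relu, pool in reversed(self.blocks[:-1]):
            dx = conv.backward(relu.backward(pool.backward(dx)))

    # -- spec-level operations ---------------------------------------------

    def encode_image(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Encode one standardized radiograph.

        Returns the pooled ``image_feature_dim`` feature vector and the
        penultimate spatial feature maps used by the localization branch.
        """
        out_maps, f = self._encode_batch(image[None, None])
        return f[0], out_maps[0]

    def _encode_batch(self, images: np.ndarray):
        self._check_input(images)
        x = images.astype(np.float64)
        for conv, relu, pool in self.blocks[:-1]:
            x = pool.forward(relu.forward(conv.forward(x)))
        maps = x
        conv, relu, pool = self.blocks[-1]
        top = pool.forward(relu.forward(conv.forward(maps)))
        return maps, self.feat.forward(self.gap.forward(top))

    def case_embedding(self, feature_vectors: Sequence[np.ndarray]
                       ) -> np.ndarray:
        """Project image feature vectors to case dimension and max-pool."""
        if len(feature_vectors) == 0:
            raise ValueError("a case must contain at least one image")
        p = self.proj.forward(np.stack(feature_vectors))
        return p.max(axis=0)

    def classification_head(self, case_vector: np.ndarray
                            ) -> list[CategoryPosterior]:
        raw = self.cls.forward(case_vector[None])[0]
        if not np.all(np.isfinite(raw)):
            raise FloatingPointError("non-finite classification activations")
        kcat = self.config.n_categories
        alpha = nn.softplus(raw[:kcat]) + _ALPHA_FLOOR
        beta = nn.softplus(raw[kcat:]) + _ALPHA_FLOOR
        return [CategoryPosterior(float(a), float(b))
                for a, b in zip(alpha, beta)]

    def localization_head(self, feature_maps: np.ndarray) -> np.ndarray:
        """Per-category probability maps (sigmoid of a convolution applied
        to the encoder's penultimate-stage feature maps)."""
        return nn.sigmoid(self.loc.forward(feature_maps[None]))[0]

    def predict_case(self, images: Sequence[np.ndarray]) -> CasePrediction:
        """Full inference for one case of 1-2 standardized images."""
        if not 1 <= len(images) <= 2:
            raise ValueError("a case must contain 1 or 2 images")
        batch = np.stack(images)[:, None]
        out = self.forward(batch, np.zeros(len(images), dtype=int))
        posteriors = {c: CategoryPosterior(float(out["alpha"][0, i]),
                                           float(out["beta"][0, i]))
                      for i, c in enumerate(CATEGORIES)}
        return CasePrediction(posteriors=posteriors,
                              prob_maps=[m for m in out["loc_maps"]])

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p.data for i, p in enumerate(self.parameters())})
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "CadNetwork":
        path = Path(path)
        cfg_dict = json.loads(path.with_suffix(".json").read_text())
        for key in ("input_shape", "channels"):
            cfg_dict[key] = tuple(cfg_dict[key])

        net = cls(ModelConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz")) as data:
            net.set_weights([data[f"p{i}"]
                             for i in range(len(net.parameters()))])
        return net


def upsample_map(prob_map: np.ndarray, image_shape: tuple[int, int],
                 method: str = "bilinear") -> np.ndarray:
    """Upsample a localization-resolution map to image pixel coordinates."""
    order = 1 if method == "bilinear" else 0
    return resize(prob_map, image_shape, order=order, mode="edge",
                  preserve_range=True, anti_aliasing=False)
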