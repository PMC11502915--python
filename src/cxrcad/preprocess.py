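"""Radiograph standardization: black-padding crop, aspect-preserving resize.

Input radiographs vary in size and framing; the analysis network expects a
fixed ``target_height x target_width`` grid. Standardization crops away the
black padding that collimation leaves around the exposed field, rescales the
image (anti-aliased bilinear when downscaling) so its height matches the
target, and then symmetrically zero-pads or center-crops the width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

__all__ = [
    "PreprocessConfig",
    "crop_black_padding",
    "standardize",
    "preprocess_image",
    "read_image",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Geometry of the standardization stage.

    The full-scale profile requires high-resolution inputs (height over
    1440 px) and standardizes to 800 x 1024; the test-scale profile drops the
    resolution gate and uses a small grid so the whole pipeline runs on a
    laptop CPU.
    """

    min_input_height_px: int = 1440
    target_height_px: int = 800
    target_width_px: int = 1024
    black_threshold: float = 0.0
    enforce_min_height: bool = True

    def __post_init__(self):
        if self.target_height_px <= 0 or self.target_width_px <= 0:
            raise ValueError("target dimensions must be positive")
        if self.enforce_min_height and \
                self.min_input_height_px < self.target_height_px:
            raise ValueError("min_input_height must be >= target_height")

    @classmethod
    def full_profile(cls) -> "PreprocessConfig":
        return cls()

    @classmethod
    def test_profile(cls, target_height_px: int = 64,
                     target_width_px: int = 80) -> "PreprocessConfig":
        return cls(min_input_height_px=0, target_height_px=target_height_px,
                   target_width_px=target_width_px, enforce_min_height=False)


class ResolutionTooLowError(ValueError):
    """Input radiograph is below the minimum supported resolution."""


def crop_black_padding(image: np.ndarray,
                       black_threshold: float = 0.0) -> np.ndarray:
    """Crop to the minimal window containing all non-black rows/columns.

    A row or column counts as content when its maximum intensity exceeds
    ``black_threshold``. An all-black image is returned unchanged with a
    warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    rows = np.flatnonzero(image.max(axis=1) > black_threshold)
    cols = np.flatnonzero(image.max(axis=0) > black_threshold)
    if rows.size == 0 or cols.size == 0:
        warnings.warn("image is entirely black; returning input unchanged")
        return image
    return image[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def standardize(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Resize to target height preserving aspect ratio, then pad/crop width.

    Downscaling uses anti-aliased bilinear interpolation; upscaling (only
    possible under the test profile) uses plain bilinear. Width is brought to
    ``target_width_px`` by symmetric zero padding (extra pixel on the right)
    or a symmetric center crop.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    h, w = image.shape
    if cfg.enforce_min_height and h < cfg.min_input_height_px:
        raise ResolutionTooLowError(
            f"input height {h} below required {cfg.min_input_height_px} px")
    th, tw = cfg.target_height_px, cfg.target_width_px
    scale = th / h
    new_w = max(int(round(w * scale)), 1)
    if (th, new_w) != (h, w):
        image = resize(image, (th, new_w), order=1, mode="edge",
                       anti_aliasing=(scale < 1.0), preserve_range=True)
    if new_w < tw:
        pad = tw - new_w
        left = pad // 2
        image = np.pad(image, ((0, 0), (left, pad - left)))
    elif new_w > tw:
        extra = new_w - tw
        left = extra // 2
        image = image[:, left:left + tw]
    return image


def preprocess_image(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Full pre-processing: black-padding crop followed by standardization."""
    return standardize(crop_black_padding(image, cfg.black_threshold), cfg)


def transform_box(box: tuple[int, int, int, int],
                  image_shape: tuple[int, int],
                  cfg: PreprocessConfig,
                  crop_offset: tuple[int, int] = (0, 0)
                  ) -> tuple[int, int, int, int]:
    """Map a half-open box from raw to standardized pixel coordinates.

    Applies the same geometry as :func:`standardize`: scale both axes by
    ``target_height / cropped_height``, then shift columns by the symmetric
    width pad (or crop). ``image_shape`` is the black-cropped input shape and
    ``crop_offset`` the (row, col) origin of the crop window in the raw
    image. The result is clipped to the target grid with area >= 1 px.
    """
    h, w = image_shape
    th, tw = cfg.target_height_px, cfg.target_width_px
    scale = th / h
    new_w = max(int(round(w * scale)), 1)
    left = (tw - new_w) // 2  # negative when the width is center-cropped
    r0, c0, r1, c1 = box
    r0 = (r0 - crop_offset[0]) * scale
    r1 = (r1 - crop_offset[0]) * scale
    c0 = (c0 - crop_offset[1]) * scale + left
    c1 = (c1 - crop_offset[1]) * scale + left
    r0 = int(np.clip(np.floor(r0), 0, th - 1))
    c0 = int(np.clip(np.floor(c0), 0, tw - 1))
    r1 = int(np.clip(np.ceil(r1), r0 + 1, th))
    c1 = int(np.clip(np.ceil(c1), c0 + 1, tw))
    return r0, c0, r1, c1


def standardize_case_labels(labels, image_shapes, cfg: PreprocessConfig):
    """Return a copy of :class:`~cxrcad.synthdata.CaseLabels` with every
    labeler box mapped into standardized coordinates (images assumed already
    black-cropped, as the phantom generator produces them)."""
    from .synthdata import CaseLabels

    new_boxes = [[(ii, transform_box(b, image_shapes[ii], cfg))
                  for ii, b in cat_boxes] for cat_boxes in labels.boxes]
    return CaseLabels(k=labels.k.copy(), n=labels.n.copy(), boxes=new_boxes)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale radiograph from PNG or single-frame DICOM.

    Returns a float array scaled to [0, 1]. DICOM pixel data is linearly
    rescaled (RescaleSlope/Intercept) and MONOCHROME1 images are inverted to
    the MONOCHROME2 convention (higher value = brighter).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=float)
        return arr / 255.0
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise ValueError("multi-frame DICOM is not supported")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == \
                "MONOCHROME1":
            arr = 1.0 - arr
        return arr
    raise ValueError(f"unsupported image format: {path.name}")
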