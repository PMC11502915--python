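"""Synthetic phantom cases, simulated labeler panels and reader-study tables.

The generator emulates the data a chest-X-ray CAD system is developed and
evaluated on, at desk scale:

* 1-2-image grayscale "radiograph" phantoms: a smoothed random field plus a
  coarse thorax-like intensity gradient, with zero or more planted
  abnormality shapes.  Each of the 8 clinical output categories owns a
  distinct visual signature (one of four parametric shape families, bright
  or dark), so a small CNN can learn to separate them.
* a panel of ``n`` simulated labelers with configurable per-category
  sensitivity/specificity, producing the k-of-n counts the beta-binomial
  likelihood models, plus a majority-vote reference standard;
* crossover reader-study tables (reader x case x session x condition x
  category confidence scores and read times) with controllable aided-vs-
  unaided effect sizes, for exercising the MRMC statistics.

All generators are deterministic for a fixed (config, seed) pair.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

__all__ = [
    "CATEGORIES",
    "CATEGORY_SIGNATURES",
    "PlantedAbnormality",
    "SyntheticCase",
    "CaseLabels",
    "GeneratorConfig",
    "LabelerPanelConfig",
    "StudyDesignConfig",
    "generate_case",
    "generate_cases",
    "simulate_labels",
    "labels_for_cases",
    "reference_standard",
    "generate_reader_study",
    "write_case_directory",
]

#: The eight mutually exclusive clinical output categories.
CATEGORIES: tuple[str, ...] = (
    "Cardiac",
    "Mediastinum/Hila",
    "Lungs",
    "Pleura",
    "Bones",
    "Soft Tissues",
    "Hardware",
    "Other",
)

SHAPE_KINDS = ("blob", "line", "ring", "grid-texture")

#: Visual signature per category: (shape family, polarity). Polarity +1 draws
#: the shape brighter than the background, -1 darker. Four families times two
#: polarities give eight separable appearances.
CATEGORY_SIGNATURES: dict[str, tuple[str, int]] = {
    "Cardiac": ("blob", +1),
    "Pleura": ("blob", -1),
    "Mediastinum/Hila": ("ring", +1),
    "Hardware": ("ring", -1),
    "Bones": ("line", +1),
    "Soft Tissues": ("line", -1),
    "Lungs": ("grid-texture", +1),
    "Other": ("grid-texture", -1),
}

SPECIALTIES = ("radiology", "internal", "family", "emergency")

AGE_GROUPS = ("22-44", "45-64", "65-74", "75+")


@dataclass(frozen=True)
class PlantedAbnormality:
    """Ground truth for one planted abnormality shape.

    ``box`` is 0-based, half-open ``(row0, col0, row1, col1)`` in the pixel
    grid of ``images[image_index]``.
    """

    category: str
    image_index: int
    box: tuple[int, int, int, int]
    shape_kind: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")
        r0, c0, r1, c1 = self.box
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"box {self.box} has nonpositive area")


@dataclass
class SyntheticCase:
    """A phantom chest-X-ray case: 1-2 images plus planted truth."""

    case_id: str
    images: list[np.ndarray]
    truths: list[PlantedAbnormality]
    patient_meta: dict

    def __post_init__(self):
        if not 1 <= len(self.images) <= 2:
            raise ValueError("a case must contain 1 or 2 images")
        for t in self.truths:
            h, w = self.images[t.image_index].shape
            r0, c0, r1, c1 = t.box
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"truth box {t.box} outside image bounds")

    def positive_categories(self) -> set[str]:
        return {t.category for t in self.truths}


@dataclass
class CaseLabels:
    """k-of-n labels for one case: per-category counts plus labeler boxes.

    ``k[i]`` of ``n[i]`` panel members called category ``CATEGORIES[i]``
    present; ``boxes[i]`` holds the positive labelers' (jittered) boxes as
    ``(image_index, (r0, c0, r1, c1))`` tuples. ``reference[i]`` is the
    majority-vote reference standard.
    """

    k: np.ndarray
    n: np.ndarray
    boxes: list[list[tuple[int, tuple[int, int, int, int]]]]

    @property
    def reference(self) -> np.ndarray:
        return np.array([reference_standard(int(k), int(n))
                         for k, n in zip(self.k, self.n)], dtype=int)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the phantom-case generator.

    Defaults target desk-scale learnability: 96x120 raw images (standardized
    downstream), per-category prevalence 0.12 so a few hundred cases yield
    tens of positives per category, and shape contrast well above the
    background texture.
    """

    image_height: int = 96
    image_width: int = 120
    prevalence: Mapping[str, float] | float = 0.12
    two_image_prob: float = 0.3
    min_shape_px: int = 14
    max_shape_px: int = 30
    contrast_range: tuple[float, float] = (0.28, 0.45)
    background_level: float = 0.42
    background_noise: float = 0.06
    noise_smoothing_px: float = 3.0

    def prevalence_of(self, category: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence.get(category, 0.0))
        return float(self.prevalence)

    def validate(self) -> None:
        if min(self.image_height, self.image_width) < self.min_shape_px + 4:
            raise ValueError(
                "image size too small to host the smallest abnormality shape"
            )
        if self.max_shape_px < self.min_shape_px:
            raise ValueError("max_shape_px < min_shape_px")


@dataclass(frozen=True)
class LabelerPanelConfig:
    """A panel of independent simulated labelers.

    ``sensitivity``/``specificity`` may be scalars or per-category mappings,
    each in (0, 1]. ``box_jitter`` is the maximum relative shift/scale a
    positive labeler applies to the truth box.
    """

    n_labelers: int = 3
    sensitivity: Mapping[str, float] | float = 0.9
    specificity: Mapping[str, float] | float = 0.95
    box_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_labelers < 1:
            raise ValueError("n_labelers must be >= 1")
        for p in (*_as_catmap(self.sensitivity).values(),
                  *_as_catmap(self.specificity).values()):
            if not 0.0 < p <= 1.0:
                raise ValueError("sensitivity/specificity must lie in (0, 1]")

    def sens_of(self, category: str) -> float:
        return _as_catmap(self.sensitivity)[category]

    def spec_of(self, category: str) -> float:
        return _as_catmap(self.specificity)[category]


def _as_catmap(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {c: float(value[c]) for c in CATEGORIES}
    return {c: float(value) for c in CATEGORIES}


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    """Deterministic per-case stream keyed on (seed, case_id)."""
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  zlib.crc32(case_id.encode())])


# ---------------------------------------------------------------------------
# phantom image synthesis
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    rr = (np.arange(h)[:, None] - h / 2) / (h / 2)
    cc = (np.arange(w)[None, :] - w / 2) / (w / 2)
    # coarse "thorax": brighter central column (mediastinum), darker flanks
    grad = 0.18 * np.exp(-(cc ** 2) / 0.25) - 0.08 * rr ** 2
    noise = rng.standard_normal((h, w))
    noise = ndimage.gaussian_filter(noise, cfg.noise_smoothing_px)
    noise *= cfg.background_noise / max(noise.std(), 1e-12)
    return np.clip(cfg.background_level + grad + noise, 0.0, 1.0)


def _soft_ellipse(h, w, cy, cx, ry, rx, sharp=2.5):
    rr = (np.arange(h)[:, None] - cy) / ry
    cc = (np.arange(w)[None, :] - cx) / rx
    d = np.sqrt(rr ** 2 + cc ** 2)
    return np.clip(1.0 - (d - 1.0) * sharp, 0.0, 1.0) * (d < 1.0 + 1.0 / sharp)


def _draw_shape(rng, cfg: GeneratorConfig, kind: str):
    """Render one shape on its own (h, w) canvas; returns (weight map, mask)."""
    h, w = cfg.image_height, cfg.image_width
    size = rng.integers(cfg.min_shape_px, cfg.max_shape_px + 1)
    margin = size // 2 + 2
    cy = rng.integers(margin, h - margin)
    cx = rng.integers(margin, w - margin)
    canvas = np.zeros((h, w))
    if kind == "blob":
        ry = size / 2.0
        rx = ry * rng.uniform(0.7, 1.3)
        canvas = _soft_ellipse(h, w, cy, cx, ry, rx)
    elif kind == "ring":
        r_out = size / 2.0
        r_in = r_out * rng.uniform(0.45, 0.6)
        canvas = _soft_ellipse(h, w, cy, cx, r_out, r_out) \
            - _soft_ellipse(h, w, cy, cx, r_in, r_in)
        canvas = np.clip(canvas, 0.0, 1.0)
    elif kind == "line":
        length = max(size, 10)
        thickness = rng.uniform(1.2, 2.2)
        theta = rng.uniform(-0.5, 0.5) + (0.0 if rng.random() < 0.5 else np.pi / 2)
        rr = np.arange(h)[:, None] - cy
        cc = np.arange(w)[None, :] - cx
        along = rr * np.sin(theta) + cc * np.cos(theta)
        across = -rr * np.cos(theta) + cc * np.sin(theta)
        canvas = (np.abs(along) < length / 2) * np.clip(
            1.5 - np.abs(across) / thickness, 0.0, 1.0)
    elif kind == "grid-texture":
        ry = size / 2.0
        rx = ry * rng.uniform(0.8, 1.2)
        mask = _soft_ellipse(h, w, cy, cx, ry, rx)
        period = rng.uniform(3.0, 4.5)
        phase = rng.uniform(0, 2 * np.pi)
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        tex = 0.5 + 0.5 * np.sin(2 * np.pi * rr / period + phase) \
            * np.sin(2 * np.pi * cc / period + phase)
        canvas = mask * tex
    else:  # pragma: no cover - guarded by PlantedAbnormality
        raise ValueError(kind)
    support = canvas > 0.08
    return canvas, support


def _tight_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def generate_case(gen_config: GeneratorConfig, seed: int,
                  case_id: str | None = None) -> SyntheticCase:
    """Generate one phantom case (possibly normal) deterministically.

    Each category is planted independently with its configured prevalence; a
    planted category contributes one shape on one image of the case. Cases
    with no planted category are normal.
    """
    gen_config.validate()
    case_id = case_id if case_id is not None else f"case-{seed:08d}"
    rng = _case_rng(seed, case_id)
    n_images = 2 if rng.random() < gen_config.two_image_prob else 1
    images = [_background(rng, gen_config) for _ in range(n_images)]
    truths: list[PlantedAbnormality] = []
    for category in CATEGORIES:
        if rng.random() >= gen_config.prevalence_of(category):
            continue
        kind, polarity = CATEGORY_SIGNATURES[category]
        img_idx = int(rng.integers(n_images))
        canvas, support = _draw_shape(rng, gen_config, kind)
        contrast = rng.uniform(*gen_config.contrast_range)
        images[img_idx] = np.clip(
            images[img_idx] + polarity * contrast * canvas, 0.0, 1.0)
        truths.append(PlantedAbnormality(
            category=category, image_index=img_idx,
            box=_tight_box(support), shape_kind=kind))
    meta = {
        "sex": "F" if rng.random() < 0.5 else "M",
        "age_group": AGE_GROUPS[rng.integers(len(AGE_GROUPS))],
    }
    return SyntheticCase(case_id=case_id, images=images, truths=truths,
                         patient_meta=meta)


def generate_cases(gen_config: GeneratorConfig, n_cases: int,
                   seed: int) -> list[SyntheticCase]:
    """Generate ``n_cases`` independent phantom cases from one master seed."""
    child = np.random.SeedSequence(seed).generate_state(n_cases) & 0x7FFFFFFF
    return [generate_case(gen_config, int(child[i]), case_id=f"case-{i:05d}")
            for i in range(n_cases)]


# ---------------------------------------------------------------------------
# simulated labeling panel
# ---------------------------------------------------------------------------

def _jitter_box(rng, box, shape, jitter):
    r0, c0, r1, c1 = box
    hh, ww = r1 - r0, c1 - c0
    dr = rng.uniform(-jitter, jitter) * hh
    dc = rng.uniform(-jitter, jitter) * ww
    sr = 1.0 + rng.uniform(-jitter, jitter)
    sc = 1.0 + rng.uniform(-jitter, jitter)
    cy, cx = (r0 + r1) / 2 + dr, (c0 + c1) / 2 + dc
    nh, nw = max(hh * sr, 2.0), max(ww * sc, 2.0)
    nr0 = int(np.clip(round(cy - nh / 2), 0, shape[0] - 2))
    nc0 = int(np.clip(round(cx - nw / 2), 0, shape[1] - 2))
    nr1 = int(np.clip(round(cy + nh / 2), nr0 + 1, shape[0]))
    nc1 = int(np.clip(round(cx + nw / 2), nc0 + 1, shape[1]))
    return nr0, nc0, nr1, nc1


def simulate_labels(case: SyntheticCase,
                    panel: LabelerPanelConfig) -> CaseLabels:
    """Draw independent k-of-n labels for one case from the panel model.

    Each labeler marks a truly present category with probability equal to
    the panel sensitivity and a truly absent one with probability
    ``1 - specificity``; positive labelers on a present category also emit a
    jittered copy of the truth box.
    """
    rng = _case_rng(panel.seed, case.case_id)
    truth_by_cat = {t.category: t for t in case.truths}
    k = np.zeros(len(CATEGORIES), dtype=int)
    n = np.full(len(CATEGORIES), panel.n_labelers, dtype=int)
    boxes: list[list[tuple[int, tuple[int, int, int, int]]]] = []
    for ci, category in enumerate(CATEGORIES):
        present = category in truth_by_cat
        p = panel.sens_of(category) if present else 1.0 - panel.spec_of(category)
        calls = rng.random(panel.n_labelers) < p
        k[ci] = int(calls.sum())
        cat_boxes = []
        if present:
            t = truth_by_cat[category]
            shape = case.images[t.image_index].shape
            for pos in range(int(calls.sum())):
                cat_boxes.append((t.image_index,
                                  _jitter_box(rng, t.box, shape,
                                              panel.box_jitter)))
        boxes.append(cat_boxes)
    return CaseLabels(k=k, n=n, boxes=boxes)


def labels_for_cases(cases: Sequence[SyntheticCase],
                     panel: LabelerPanelConfig) -> list[CaseLabels]:
    return [simulate_labels(case, panel) for case in cases]


def reference_standard(k: int, n: int) -> int:
    """Majority-vote reference standard: positive iff a strict majority of
    the ``n`` labelers called the category present (k >= 2 for n = 3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"invalid label count k={k} for n={n}")
    return int(2 * k > n)


# ---------------------------------------------------------------------------
# reader-study tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesignConfig:
    """Crossover MRMC study design and aided/unaided effect sizes.

    Defaults mirror a 24-reader (6 per specialty), 238-case (190 abnormal,
    48 normal), 8-category, two-session fully-crossed design. Reading
    accuracy is a binormal latent model: for reader group g and condition c
    the latent score of a (case, category) pair is
    ``a[g][c] * y + eta_case + eps`` with ``eta ~ N(0, tau^2)`` shared across
    readers/conditions (within-case correlation) and ``eps ~ N(0, 1)`` per
    read; confidence = 100 * logistic(latent) is rank-preserving, so the
    configured AUC targets hold exactly in law.
    """

    readers_per_specialty: Mapping[str, int] = field(
        default_factory=lambda: {s: 6 for s in SPECIALTIES})
    n_cases: int = 238
    n_abnormal: int = 190
    categories: tuple[str, ...] = CATEGORIES
    unaided_auc: Mapping[str, float] | float = field(
        default_factory=lambda: {"radiology": 0.865, "internal": 0.800,
                                 "family": 0.740, "emergency": 0.740})
    aided_auc: Mapping[str, float] | float = field(
        default_factory=lambda: {"radiology": 0.900, "internal": 0.895,
                                 "family": 0.860, "emergency": 0.860})
    #: optional sensitivity targets at the confidence-50 threshold; when set
    #: they override the positive-class separation implied by the AUC target.
    unaided_sensitivity: float | None = None
    aided_sensitivity: float | None = None
    case_effect_sd: float = 0.5
    reader_ability_sd: float = 0.05
    category_positive_prob: float = 0.25
    #: median read time in seconds per (specialty, condition)
    read_time_medians: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "radiology": (69.5, 67.5),
            "internal": (107.0, 98.5),
            "family": (107.0, 98.5),
            "emergency": (107.0, 98.5),
        })
    read_time_log_sd: float = 0.35
    reader_time_log_sd: float = 0.15

    def auc_of(self, specialty: str, condition: str) -> float:
        src = self.unaided_auc if condition == "unaided" else self.aided_auc
        if isinstance(src, Mapping):
            return float(src[specialty])
        return float(src)

    def validate(self) -> None:
        if sum(self.readers_per_specialty.values()) < 1:
            raise ValueError("study design needs at least one reader")
        if self.n_cases < 2:
            raise ValueError("study design needs at least two cases")
        if not 0 <= self.n_abnormal <= self.n_cases:
            raise ValueError("n_abnormal out of range")


def _separation(auc: float, total_sd: float) -> float:
    """Positive-class latent mean giving the target binormal AUC."""
    return float(norm.ppf(auc) * np.sqrt(2.0) * total_sd)


def generate_reader_study(design: StudyDesignConfig,
                          seed: int) -> pd.DataFrame:
    """Simulate a fully-crossed two-session crossover reader study.

    Returns a long-format table with one row per (reader, case, session,
    category): columns ``reader_id, specialty, case_id, session, condition,
    category, confidence, read_time_s, reference``. Each (reader, case)
    appears exactly once aided and once unaided, with the session-1
    aided/unaided split stratified on case positivity.
    """
    from .readerstudy import assign_conditions  # local import: no cycle at load

    design.validate()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    n_cat = len(design.categories)
    tau = design.case_effect_sd
    total_sd = float(np.sqrt(1.0 + tau ** 2))

    # case truth: abnormal cases positive in >= 1 category
    case_ids = [f"S{i:04d}" for i in range(design.n_cases)]
    truth = np.zeros((design.n_cases, n_cat), dtype=int)
    for i in range(design.n_abnormal):
        row = rng.random(n_cat) < design.category_positive_prob
        if not row.any():
            row[rng.integers(n_cat)] = True
        truth[i] = row
    order = rng.permutation(design.n_cases)
    truth = truth[order]
    case_positive = truth.any(axis=1).astype(int)

    eta = rng.normal(0.0, tau, size=(design.n_cases, n_cat))

    readers = []
    for spec in design.readers_per_specialty:
        for j in range(design.readers_per_specialty[spec]):
            readers.append((f"{spec[:3]}-{j:02d}", spec))
    reader_ids = [r for r, _ in readers]

    assignment = assign_conditions(case_ids, reader_ids,
                                   seed=int(rng.integers(2 ** 31)),
                                   strata=dict(zip(case_ids, case_positive)))
    cond_lookup = {(row.reader_id, row.case_id, row.session): row.condition
                   for row in assignment.itertuples()}

    sep = {}
    for spec in design.readers_per_specialty:
        for cond in ("unaided", "aided"):
            a = _separation(design.auc_of(spec, cond), total_sd)
            sens_target = (design.unaided_sensitivity if cond == "unaided"
                           else design.aided_sensitivity)
            if sens_target is not None:
                # threshold 0 corresponds to confidence 50
                a = float(total_sd * norm.ppf(sens_target))
            sep[(spec, cond)] = a

    rows = []
    for reader_id, spec in readers:
        ability = 1.0 + rng.normal(0.0, design.reader_ability_sd)
        time_shift = rng.normal(0.0, design.reader_time_log_sd)
        for session in (1, 2):
            for i, case_id in enumerate(case_ids):
                cond = cond_lookup[(reader_id, case_id, session)]
                a = sep[(spec, cond)] * ability
                eps = rng.standard_normal(n_cat)
                z = a * truth[i] + eta[i] + eps
                conf = 100.0 / (1.0 + np.exp(-z))
                med_u, med_a = design.read_time_medians[spec]
                med = med_u if cond == "unaided" else med_a
                t = float(np.exp(np.log(med) + time_shift
                                 + rng.normal(0.0, design.read_time_log_sd)))
                for ci, cat in enumerate(design.categories):
                    rows.append((reader_id, spec, case_id, session, cond,
                                 cat, conf[ci], t, truth[i, ci]))
    return pd.DataFrame(rows, columns=[
        "reader_id", "specialty", "case_id", "session", "condition",
        "category", "confidence", "read_time_s", "reference"])


# ---------------------------------------------------------------------------
# on-disk artifacts
# ---------------------------------------------------------------------------

def write_case_directory(cases: Sequence[SyntheticCase],
                         labels: Sequence[CaseLabels],
                         out_dir: str | Path) -> Path:
    """Write cases as 8-bit PNGs plus a JSON manifest; returns manifest path."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for case, lab in zip(cases, labels):
        paths = []
        for i, img in enumerate(case.images):
            p = out_dir / f"{case.case_id}_{i}.png"
            Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8)
                            ).save(p)
            paths.append(p.name)
        per_cat = {}
        for ci, cat in enumerate(CATEGORIES):
            per_cat[cat] = {
                "k": int(lab.k[ci]),
                "n": int(lab.n[ci]),
                "reference": int(lab.reference[ci]),
                "boxes": [[int(ii), list(map(int, b))]
                          for ii, b in lab.boxes[ci]],
            }
        entries.append({
            "case_id": case.case_id,
            "image_paths": paths,
            "patient_meta": case.patient_meta,
            "labels": per_cat,
            "truths": [{"category": t.category, "image_index": t.image_index,
                        "box": list(t.box), "shape_kind": t.shape_kind}
                       for t in case.truths],
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"cases": entries}, indent=1))
    return manifest
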