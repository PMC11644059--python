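"""Synthetic ultrasound-phantom generator.

Produces seeded grayscale phantoms that emulate the nine fetal
standard-plane categories with category-discriminative geometry and
ultrasound-like multiplicative speckle, so that the data pipeline, the
training recipe, and GradCAM can all be exercised without any image
download. The four brain categories share one ellipse-rim construction and
differ only in the structures drawn inside the rim, mirroring how the real
trans-ventricular / trans-thalamic / trans-cerebellum planes differ only in
their visible midline anatomy.

Geometry (at zero speckle):

==================  ======================================================
category            structure on a dark background
==================  ======================================================
abdomen             bright-rim disc, moderate interior, one dark blob
trans_ventricular   ellipse rim + single off-axis bright slit
trans_thalamic      ellipse rim + paired central bright blobs
trans_cerebellum    ellipse rim + posterior dumbbell (two joined blobs)
other_brain         ellipse rim only
femur               bright elongated bar at a jittered angle
thorax              disc with an interior cross pattern
maternal_cervix     bright wedge-shaped band
other               speckled background only
==================  ======================================================

Speckle is multiplicative Gaussian: ``pixel <- clip(pixel * (1 + s*eta),
0, 1)`` with per-pixel standard-normal ``eta`` — the key statistical
property of ultrasound speckle (signal-dependent noise) without a physical
scattering model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CATEGORIES_9",
    "CATEGORIES_6",
    "PRESET_COUNTS",
    "PhantomSpec",
    "generate_image",
    "generate_dataset",
    "generate_array_dataset",
]

CATEGORIES_9 = (
    "abdomen",
    "trans_ventricular",
    "trans_thalamic",
    "trans_cerebellum",
    "other_brain",
    "femur",
    "thorax",
    "maternal_cervix",
    "other",
)

CATEGORIES_6 = (
    "abdomen",
    "brain",
    "femur",
    "thorax",
    "maternal_cervix",
    "other",
)

_BRAIN_VARIANTS = ("trans_ventricular", "trans_thalamic",
                   "trans_cerebellum", "other_brain")

# Scaled-down (1/10, rounded) per-category totals of the public
# Burgos-Artizzu fetal-plane dataset, preserving its class imbalance
# (e.g. other_brain : other of roughly 14 : 421 in the nine-class profile).
PRESET_COUNTS = {
    "table1": {"abdomen": 71, "brain": 309, "femur": 104, "thorax": 172,
               "maternal_cervix": 163, "other": 421},
    "table2": {"abdomen": 71, "trans_ventricular": 60, "trans_thalamic": 164,
               "trans_cerebellum": 71, "other_brain": 14, "femur": 104,
               "thorax": 172, "maternal_cervix": 163, "other": 421},
    "tiny": {c: 8 for c in CATEGORIES_9},
}

_BG = 0.08          # background level
_RIM = 0.9          # rim intensity
_INTERIOR = 0.38    # fill inside rims/discs
_FEATURE = 0.8      # bright interior structures
_DARK = 0.16        # dark interior structures


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines one phantom image."""

    category: str
    image_size: tuple = (64, 64)          # (H, W)
    center_jitter: float = 0.06           # max offset, fraction of size
    scale_jitter: float = 0.12            # max relative size change
    rotation_jitter: float = 20.0         # max |rotation| of the figure, deg
    speckle: float = 0.1                  # multiplicative noise strength
    seed: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES_9 and \
                self.category not in CATEGORIES_6:
            raise ValueError(f"unknown category {self.category!r}")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.speckle < 0:
            raise ValueError("speckle strength must be >= 0")


def _grids(h, w, cy, cx, angle_deg):
    """Rotated, centered coordinate grids (units: pixels)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    yy -= cy
    xx -= cx
    a = np.deg2rad(angle_deg)
    u = np.cos(a) * xx + np.sin(a) * yy   # along the figure's major axis
    v = -np.sin(a) * xx + np.cos(a) * yy
    return u, v


def _ellipse_masks(u, v, ra, rb, rim_frac=0.14):
    """(rim mask, interior mask) of an ellipse with semi-axes ra, rb."""
    r2 = (u / ra) ** 2 + (v / rb) ** 2
    inner = (1.0 - rim_frac) ** 2
    return (r2 <= 1.0) & (r2 >= inner), r2 < inner


def _blob(u, v, du, dv, r):
    return ((u - du) ** 2 + (v - dv) ** 2) <= r * r


def generate_image(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom; deterministic given the spec (incl. its seed).

    Returns a float array in [0, 1] of shape ``spec.image_size``.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)

    # Jitter parameters are drawn first, in a fixed order, so that two
    # categories sharing a construction (the brain family) consume the rng
    # identically and differ only in their interior structures.
    cy = h / 2 + rng.uniform(-1, 1) * spec.center_jitter * h
    cx = w / 2 + rng.uniform(-1, 1) * spec.center_jitter * w
    scale = 1.0 + rng.uniform(-1, 1) * spec.scale_jitter
    angle = rng.uniform(-1, 1) * spec.rotation_jitter

    category = spec.category
    if category == "brain":
        # six-class scheme: any of the brain sub-plane geometries
        category = _BRAIN_VARIANTS[rng.integers(len(_BRAIN_VARIANTS))]

    img = np.full((h, w), _BG, dtype=np.float64)
    u, v = _grids(h, w, cy, cx, angle)
    s = min(h, w) * scale

    if category == "abdomen":
        rim, interior = _ellipse_masks(u, v, 0.36 * s, 0.33 * s)
        img[interior] = _INTERIOR
        img[rim] = _RIM
        img[_blob(u, v, -0.12 * s, 0.08 * s, 0.07 * s) & interior] = _DARK
    elif category in _BRAIN_VARIANTS:
        rim, interior = _ellipse_masks(u, v, 0.40 * s, 0.27 * s)
        img[interior] = _INTERIOR
        img[rim] = _RIM
        if category == "trans_ventricular":
            slit = (np.abs(v - 0.10 * s) < 0.025 * s) & \
                   (np.abs(u + 0.08 * s) < 0.16 * s)
            img[slit & interior] = _FEATURE
        elif category == "trans_thalamic":
            pair = (_blob(u, v, -0.07 * s, 0.0, 0.05 * s)
                    | _blob(u, v, 0.07 * s, 0.0, 0.05 * s))
            img[pair & interior] = _FEATURE
        elif category == "trans_cerebellum":
            dumbbell = (_blob(u, v, 0.16 * s, -0.06 * s, 0.055 * s)
                        | _blob(u, v, 0.16 * s, 0.06 * s, 0.055 * s)
                        | ((np.abs(u - 0.16 * s) < 0.035 * s)
                           & (np.abs(v) < 0.06 * s)))
            img[dumbbell & interior] = _FEATURE
        # other_brain: rim only
    elif category == "femur":
        bar = (np.abs(u) < 0.32 * s) & (np.abs(v) < 0.045 * s)
        img[bar] = 0.95
    elif category == "thorax":
        rim, interior = _ellipse_masks(u, v, 0.35 * s, 0.35 * s)
        img[interior] = 0.5
        img[rim] = _RIM
        cross = ((np.abs(u) < 0.035 * s) | (np.abs(v) < 0.035 * s)) & \
            ((np.abs(u) < 0.24 * s) & (np.abs(v) < 0.24 * s))
        img[cross & interior] = _FEATURE
    elif category == "maternal_cervix":
        band = (np.abs(v - 0.25 * u) < (0.06 + 0.05 * np.abs(u) / s) * s) & \
               (np.abs(u) < 0.42 * s)
        img[band] = 0.85
    elif category == "other":
        pass  # speckle only
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise ValueError(f"unknown category {category!r}")

    if spec.speckle > 0:
        eta = rng.standard_normal((h, w))
        img = img * (1.0 + spec.speckle * eta)
    return np.clip(img, 0.0, 1.0)


def generate_array_dataset(counts: dict, image_size=(64, 64),
                           speckle: float = 0.1, seed: int = 0,
                           **spec_kwargs):
    """In-memory variant of :func:`generate_dataset`.

    Returns ``(images, labels, categories)`` with images stacked as
    (N, H, W) float64 in [0, 1] and integer labels indexing ``categories``
    (the sorted-by-scheme category list actually present in ``counts``).
    Uses the same per-image seed derivation as :func:`generate_dataset`.
    """
    order = [c for c in list(CATEGORIES_9) + ["brain"] if c in counts]
    unknown = set(counts) - set(order)
    if unknown:
        raise ValueError(f"unknown categories in counts: {sorted(unknown)}")
    images, labels = [], []
    for li, cat in enumerate(order):
        cat_idx = (list(CATEGORIES_9) + ["brain"]).index(cat)
        for i in range(int(counts[cat])):
            spec = PhantomSpec(category=cat, image_size=tuple(image_size),
                               speckle=speckle,
                               seed=_child_seed(seed, cat_idx, i),
                               **spec_kwargs)
            images.append(generate_image(spec))
            labels.append(li)
    x = (np.stack(images) if images
         else np.empty((0,) + tuple(image_size)))
    return x, np.asarray(labels, dtype=np.int64), tuple(order)


def _child_seed(seed: int, cat_idx: int, i: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cat_idx, i))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(counts: dict, out_dir, image_size=(64, 64),
                     speckle: float = 0.1, seed: int = 0,
                     write_images: bool = True, **spec_kwargs
                     ) -> pd.DataFrame:
    """Generate a phantom dataset and its manifest.

    ``counts`` maps category -> number of images. Per-image seeds are
    derived from ``seed`` and the (category, index) pair, so the dataset is
    a pure function of its arguments. Returns the manifest as a DataFrame
    with columns ``path, category, split, provenance`` (split left empty,
    to be filled by the split planner); images are written as 8-bit
    grayscale PNG unless ``write_images`` is false.
    """
    out_dir = Path(out_dir)
    if write_images:
        out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    order = [c for c in list(CATEGORIES_9) + ["brain"] if c in counts]
    unknown = set(counts) - set(order)
    if unknown:
        raise ValueError(f"unknown categories in counts: {sorted(unknown)}")
    for cat in order:
        n = int(counts[cat])
        if n < 0:
            raise ValueError("counts must be >= 0")
        cat_idx = (list(CATEGORIES_9) + ["brain"]).index(cat)
        for i in range(n):
            spec = PhantomSpec(category=cat, image_size=tuple(image_size),
                               speckle=speckle,
                               seed=_child_seed(seed, cat_idx, i),
                               **spec_kwargs)
            rel = f"{cat}_{i:04d}.png"
            if write_images:
                img = generate_image(spec)
                arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out_dir / rel)
            records.append({"path": str(out_dir / rel), "category": cat,
                            "split": "", "provenance": "original"})
    return pd.DataFrame.from_records(
        records, columns=["path", "category", "split", "provenance"])
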