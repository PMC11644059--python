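"""Split and imbalance-correcting augmentation pipeline.

A dataset is represented by a *manifest* — a CSV/DataFrame with columns
``path, category, split, provenance`` — which is the single source of truth
for split membership and augmentation bookkeeping. The pipeline:

1. :func:`make_split` partitions each category 8:1:1 (train/val/test) with a
   seeded shuffle, or takes an explicit per-category count table verbatim.
2. :func:`plan_augmentation` assigns, per category, exactly
   ``target - n_original`` augmentation jobs to training images,
   round-robin, each job carrying a seeded :class:`TransformSpec` from the
   families flip / rotation / brightness / contrast / Gaussian blur.
3. :func:`execute_plan` applies the transforms and writes the augmented
   images; validation and test splits are never touched.

Per-category targets are configuration, not a formula: the shipped defaults
(:data:`SIX_CLASS_TARGETS`, :data:`NINE_CLASS_TARGETS`) are the
after-augmentation training counts used for the public Burgos-Artizzu
fetal-plane dataset, which follow no single multiplication rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "SIX_CLASS_COUNTS",
    "NINE_CLASS_COUNTS",
    "SIX_CLASS_TARGETS",
    "NINE_CLASS_TARGETS",
    "TransformSpec",
    "SplitPlan",
    "AugmentationPlan",
    "read_manifest",
    "write_manifest",
    "make_split",
    "plan_augmentation",
    "apply_transform",
    "apply_plan_to_manifest",
    "execute_plan",
]

MANIFEST_COLUMNS = ["path", "category", "split", "provenance"]
SPLITS = ("train", "val", "test")

# Explicit per-category (train, val, test) counts of the public
# Burgos-Artizzu fetal-plane dataset, six- and nine-class schemes.
SIX_CLASS_COUNTS = {
    "abdomen": (568, 72, 71),
    "brain": (2472, 310, 310),
    "femur": (832, 104, 104),
    "thorax": (1374, 172, 172),
    "maternal_cervix": (1300, 163, 163),
    "other": (3370, 422, 421),
}
NINE_CLASS_COUNTS = {
    "abdomen": (568, 72, 71),
    "trans_ventricular": (477, 60, 60),
    "trans_thalamic": (1310, 164, 164),
    "trans_cerebellum": (571, 72, 71),
    "other_brain": (114, 14, 15),
    "femur": (832, 104, 104),
    "thorax": (1374, 172, 172),
    "maternal_cervix": (1300, 163, 163),
    "other": (3370, 422, 421),
}

# After-augmentation training-set targets (configuration defaults).
SIX_CLASS_TARGETS = {
    "abdomen": 2840, "brain": 2472, "femur": 2496, "thorax": 2748,
    "maternal_cervix": 2522, "other": 3370,
}
NINE_CLASS_TARGETS = {
    "abdomen": 1300, "trans_ventricular": 1300, "trans_thalamic": 1310,
    "trans_cerebellum": 1300, "other_brain": 1368, "femur": 1300,
    "thorax": 1374, "maternal_cervix": 1300, "other": 3370,
}

# Pinned, label-preserving transform parameter ranges.
ANGLE_RANGE = (-15.0, 15.0)        # degrees, counter-clockwise
FACTOR_RANGE = (0.7, 1.3)          # brightness / contrast factors
SIGMA_RANGE = (0.5, 1.5)           # Gaussian blur, pixels

_KINDS = ("hflip", "rotate", "brightness", "contrast", "gaussian_blur")


class ManifestError(ValueError):
    """Raised for malformed manifests or inconsistent split/target tables."""


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation transform with its parameter (None for hflip)."""

    kind: str
    param: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ManifestError(f"unknown transform kind {self.kind!r}")
        if self.kind == "hflip":
            if self.param is not None:
                raise ManifestError("hflip takes no parameter")
            return
        lo, hi = {"rotate": ANGLE_RANGE, "brightness": FACTOR_RANGE,
                  "contrast": FACTOR_RANGE,
                  "gaussian_blur": SIGMA_RANGE}[self.kind]
        if self.param is None or not (lo <= self.param <= hi):
            raise ManifestError(
                f"{self.kind} parameter {self.param} outside [{lo}, {hi}]")

    @property
    def tag(self) -> str:
        if self.kind == "hflip":
            return "hflip"
        return f"{self.kind}{self.param:+.4f}"


@dataclass(frozen=True)
class SplitPlan:
    per_category: dict      # category -> (n_train, n_val, n_test)
    ratios: tuple
    seed: int


@dataclass(frozen=True)
class AugmentationPlan:
    targets: dict           # category -> target train count
    jobs: tuple             # ordered (source path, category, TransformSpec)
    seed: int


# ---------------------------------------------------------------------------
# manifest I/O

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns {sorted(missing)}")
    return df[MANIFEST_COLUMNS]

def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splitting

def _split_counts(n: int, ratios: tuple) -> tuple:
    """Train gets floor(n * r_train / total); of the remainder, val gets the
    ceiling of its proportional share (so val >= test for 1:1 tails)."""
    r_train, r_val, r_test = ratios
    total = r_train + r_val + r_test
    n_train = int(np.floor(n * r_train / total))
    rem = n - n_train
    n_val = int(np.ceil(rem * r_val / (r_val + r_test)))
    return n_train, n_val, rem - n_val


def make_split(manifest: pd.DataFrame, ratios=(8, 1, 1), seed: int = 0,
               counts_table: dict | None = None):
    """Assign every record to train/val/test, per category.

    Returns ``(plan, manifest)`` where the manifest is a copy with the
    ``split`` column filled. With ``counts_table`` (category ->
    (train, val, test)) the given counts are used verbatim; otherwise the
    ratio rule above applies. Assignment within a category is a seeded
    shuffle, so the partition is deterministic given the seed.
    """
    if any(r <= 0 for r in ratios):
        raise ManifestError("ratios must be positive")
    bad = manifest["category"].astype(str).str.strip() == ""
    if bad.any():
        raise ManifestError(f"{int(bad.sum())} records lack a category")
    out = manifest.copy().reset_index(drop=True)
    out["split"] = ""
    rng = np.random.default_rng(seed)
    per_category = {}
    for cat in sorted(out["category"].unique()):
        idx = out.index[out["category"] == cat].to_numpy()
        n = len(idx)
        if counts_table is not None:
            if cat not in counts_table:
                raise ManifestError(f"no counts for category {cat!r}")
            n_train, n_val, n_test = counts_table[cat]
            if n_train + n_val + n_test != n:
                raise ManifestError(
                    f"counts for {cat!r} sum to {n_train + n_val + n_test}, "
                    f"but the category has {n} records")
        else:
            n_train, n_val, n_test = _split_counts(n, ratios)
        perm = rng.permutation(n)
        out.loc[idx[perm[:n_train]], "split"] = "train"
        out.loc[idx[perm[n_train:n_train + n_val]], "split"] = "val"
        out.loc[idx[perm[n_train + n_val:]], "split"] = "test"
        per_category[cat] = (n_train, n_val, n_test)
    return SplitPlan(per_category, tuple(ratios), seed), out


# ---------------------------------------------------------------------------
# augmentation planning

def _sample_spec(rng: np.random.Generator, used: set) -> TransformSpec:
    """Draw a transform spec, excluding identity parameters and any spec
    already assigned to the same source image."""
    for _ in range(1000):
        kind = _KINDS[rng.integers(len(_KINDS))]
        if kind == "hflip":
            spec = TransformSpec("hflip")
        elif kind == "rotate":
            a = rng.uniform(*ANGLE_RANGE)
            if a == 0.0:
                continue
            spec = TransformSpec("rotate", float(a))
        elif kind in ("brightness", "contrast"):
            f = rng.uniform(*FACTOR_RANGE)
            if f == 1.0:
                continue
            spec = TransformSpec(kind, float(f))
        else:
            spec = TransformSpec("gaussian_blur",
                                 float(rng.uniform(*SIGMA_RANGE)))
        if spec not in used:
            used.add(spec)
            return spec
    raise RuntimeError("could not draw a fresh transform spec")


def plan_augmentation(manifest: pd.DataFrame, targets: dict,
                      seed: int = 0) -> AugmentationPlan:
    """Plan exactly ``target - n_original`` jobs per category.

    Only train-split originals are eligible sources. Jobs are distributed
    round-robin over the sources in seeded order: with deficit ``d`` over
    ``n`` sources, each source gets ``d // n`` jobs and the first ``d % n``
    sources (in that order) one extra. The plan is a pure function of
    (manifest, targets, seed).
    """
    rng = np.random.default_rng(seed)
    train = manifest[(manifest["split"] == "train")
                     & (manifest["provenance"] == "original")]
    jobs = []
    for cat in sorted(targets):
        target = int(targets[cat])
        paths = train.loc[train["category"] == cat, "path"].tolist()
        n = len(paths)
        if target < n:
            raise ManifestError(
                f"target {target} for category {cat!r} is below its "
                f"{n} original training images")
        if n == 0:
            if target > 0:
                raise ManifestError(
                    f"category {cat!r} has no training images to augment")
            continue
        d = target - n
        order = [paths[i] for i in rng.permutation(n)]
        per_source = {p: d // n + (1 if i < d % n else 0)
                      for i, p in enumerate(order)}
        for p in order:
            used: set = set()
            for _ in range(per_source[p]):
                jobs.append((p, cat, _sample_spec(rng, used)))
    return AugmentationPlan(targets=dict(targets), jobs=tuple(jobs),
                            seed=seed)


# ---------------------------------------------------------------------------
# transforms

def apply_transform(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply one transform to a grayscale image with values in [0, 1].

    Output has the same shape and range. Rotation is counter-clockwise
    about the center (origin top-left, (row, column) axes) and fills
    exposed corners with 0; blur uses a normalized Gaussian kernel, so
    constant images are preserved.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ManifestError("expected a 2-D grayscale image")
    if spec.kind == "hflip":
        return img[:, ::-1].copy()
    if spec.kind == "rotate":
        if spec.param == 0.0:
            return img.copy()
        out = ndimage.rotate(img, spec.param, reshape=False, order=1,
                             mode="constant", cval=0.0)
        return np.clip(out, 0.0, 1.0)
    if spec.kind == "brightness":
        return np.clip(img * spec.param, 0.0, 1.0)
    if spec.kind == "contrast":
        m = img.mean()
        return np.clip((img - m) * spec.param + m, 0.0, 1.0)
    if spec.kind == "gaussian_blur":
        out = ndimage.gaussian_filter(img, sigma=spec.param, mode="nearest")
        return np.clip(out, 0.0, 1.0)
    raise ManifestError(f"unknown transform kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# execution

def _augmented_records(plan: AugmentationPlan, out_dir: Path | None):
    counters: dict = {}
    for src, cat, spec in plan.jobs:
        stem = Path(src).stem
        j = counters.get(src, 0)
        counters[src] = j + 1
        name = f"{stem}_aug{j:03d}_{spec.kind}.png"
        path = str((out_dir / name) if out_dir is not None else name)
        yield src, cat, spec, path


def apply_plan_to_manifest(manifest: pd.DataFrame, plan: AugmentationPlan,
                           out_dir=None) -> pd.DataFrame:
    """Append the plan's augmented records to the manifest (no image I/O).

    Augmented records land in the train split with provenance
    ``augmented:<source stem>:<transform tag>``.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    rows = [{"path": path, "category": cat, "split": "train",
             "provenance": f"augmented:{Path(src).stem}:{spec.tag}"}
            for src, cat, spec, path in _augmented_records(plan, out_dir)]
    return pd.concat([manifest, pd.DataFrame(rows, columns=MANIFEST_COLUMNS)],
                     ignore_index=True)


def execute_plan(manifest: pd.DataFrame, plan: AugmentationPlan,
                 out_dir) -> pd.DataFrame:
    """Apply every job and write the augmented images as 8-bit PNG.

    Originals and the val/test splits are untouched; per-category train
    counts in the returned manifest equal the plan's targets exactly.
    File names derive from the source stem, the per-source job index, and
    the transform kind, so re-running with the same seed is byte-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for src, cat, spec, path in _augmented_records(plan, out_dir):
            arr = np.asarray(Image.open(src).convert("L"),
                             dtype=np.float64) / 255.0
            out = apply_transform(arr, spec)
            img8 = np.clip(np.round(out * 255), 0, 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(path)
            written.append(path)
    except OSError as exc:
        raise OSError(
            f"augmentation aborted after writing {len(written)} of "
            f"{len(plan.jobs)} images: {exc}") from exc
    return apply_plan_to_manifest(manifest, plan, out_dir)
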