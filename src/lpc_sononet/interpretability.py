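"""GradCAM attribution for the fully convolutional classifiers.

For a chosen feature stage with activations A (C x h x w) and a target
class logit y_c, the channel weights are the spatial means of dy_c/dA;
the raw map is the rectified weighted channel sum, which is upsampled
bilinearly to the input size and max-normalized to [0, 1]. An identically
zero raw map (e.g. the logit does not depend on the stage) is returned as
zeros rather than divided by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

__all__ = ["Heatmap", "gradcam", "gradcam_from_arrays", "overlay"]

DEFAULT_STAGE = "block4"  # deepest spatial stage before the head


@dataclass
class Heatmap:
    values: np.ndarray      # H x W in [0, 1]
    target_class: int
    layer_id: str


def gradcam_from_arrays(features: np.ndarray,
                        gradients: np.ndarray) -> np.ndarray:
    """Raw (un-upsampled) GradCAM map from a feature tensor and the
    gradient of the target logit w.r.t. it, both (C, h, w)."""
    feats = np.asarray(features, dtype=np.float64)
    grads = np.asarray(gradients, dtype=np.float64)
    weights = grads.mean(axis=(1, 2))
    return np.maximum((weights[:, None, None] * feats).sum(axis=0), 0.0)


def _normalize(raw: np.ndarray) -> np.ndarray:
    peak = raw.max()
    if peak <= 0:
        return np.zeros_like(raw)
    return raw / peak


def gradcam(model, image: np.ndarray, target_class: int,
            layer_id: str = DEFAULT_STAGE,
            upsample: bool = True) -> Heatmap:
    """Attribution heatmap of ``target_class`` for one grayscale image.

    ``image`` is (H, W) or (1, H, W), already preprocessed the way the
    model expects. ``layer_id`` names one of the model's stages (see
    ``model.stage_names()``); with ``upsample`` false the map stays at the
    feature resolution, which is convenient for testing.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a single grayscale image")
    h, w = x.shape[-2:]
    logits, feat = model.forward_features(x[None], layer_id, train=False)
    k = logits.shape[1]
    if not 0 <= target_class < k:
        raise ValueError(f"target class {target_class} outside [0, {k})")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.backward_to(layer_id, dlogits)
    raw = gradcam_from_arrays(feat[0], grad[0])
    if upsample and raw.shape != (h, w):
        raw = resize(raw, (h, w), order=1, anti_aliasing=False)
        raw = np.maximum(raw, 0.0)
    return Heatmap(values=_normalize(raw), target_class=int(target_class),
                   layer_id=layer_id)


def overlay(heatmap: Heatmap, image: np.ndarray,
            colormap: str = "jet", alpha: float = 0.4) -> np.ndarray:
    """Blend a heatmap over a grayscale image; returns H x W x 3 in [0, 1].

    The warm-color contribution is proportional to the heatmap value, so a
    zero heatmap yields the plain (dimmed) grayscale image.
    """
    img = np.asarray(image, dtype=np.float64)
    hm = np.asarray(heatmap.values, dtype=np.float64)
    if img.shape != hm.shape:
        raise ValueError(
            f"heatmap {hm.shape} and image {img.shape} dimensions differ")
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    colors = colormaps[colormap](hm)[..., :3]
    out = (1 - alpha) * gray[..., None] + alpha * hm[..., None] * colors
    return np.clip(out, 0.0, 1.0)
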