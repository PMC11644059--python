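"""Shared fixtures: tiny phantom datasets and a small trained model."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from lpc_sononet.architectures import build_lpc_sononet
from lpc_sononet.synthetic_data import (
    CATEGORIES_9,
    generate_array_dataset,
)
from lpc_sononet.training import TrainConfig, _standardize, train


def standardize_stack(images: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance, stacked as (N, 1, H, W) float32."""
    return np.stack([_standardize(i) for i in images]).astype(
        np.float32)[:, None]


@pytest.fixture(scope="session")
def phantom_train_val():
    """Small in-memory 9-class phantom set (32x32, speckle 0.1)."""
    xtr, ytr, cats = generate_array_dataset(
        {c: 40 for c in CATEGORIES_9}, (32, 32), 0.1, seed=7)
    xva, yva, _ = generate_array_dataset(
        {c: 8 for c in CATEGORIES_9}, (32, 32), 0.1, seed=8)
    return (standardize_stack(xtr), ytr), (standardize_stack(xva), yva), cats


@pytest.fixture(scope="session")
def trained_model(phantom_train_val):
    """LPC-SonoNet trained briefly on the small phantom set.

    Used by tests that need a model whose predictions are meaningful
    (GradCAM localization); convergence itself is checked elsewhere at a
    larger scale.
    """
    (tr, va, cats) = phantom_train_val
    cfg = TrainConfig(epochs=5, initial_lr=1e-3, decay_factor=10,
                      decay_every=3, batch_size=32, input_size=(32, 32),
                      seed=11)
    model, history = train(build_lpc_sononet(9), None, None, cfg, cats,
                           data=(tr, va))
    return model, history, cats


def write_tiny_png(path, rng, size=(16, 16)):
    """Write a small random grayscale PNG (pipeline plumbing tests)."""
    arr = rng.integers(0, 256, size=size, dtype=np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return str(path)


def make_manifest(tmp_path, counts: dict, rng, split="train",
                  size=(16, 16)) -> pd.DataFrame:
    """A manifest of freshly written tiny PNGs, one split."""
    rows = []
    for cat, n in counts.items():
        for i in range(n):
            p = write_tiny_png(tmp_path / f"{cat}_{i:03d}.png", rng, size)
            rows.append({"path": p, "category": cat, "split": split,
                         "provenance": "original"})
    return pd.DataFrame(rows,
                        columns=["path", "category", "split", "provenance"])
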