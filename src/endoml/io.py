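"""Disk formats: 8-bit PNG images/masks, feature CSVs, JSON records.

Images are stored as 8-bit PNG and scaled to/from the internal [0, 1]
float representation; feature tables use the ``f0..f{D-1},label``
CSV convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_features",
    "load_features",
    "save_json",
    "load_json",
    "load_image_dir",
]


def save_image(path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def load_image(path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)), dtype=float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr / 255.0


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_features(path, features: np.ndarray, labels: np.ndarray) -> None:
    features = np.asarray(features, dtype=float)
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df["label"] = np.asarray(labels)
    df.to_csv(Path(path), index=False)


def load_features(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(Path(path))
    if "label" not in df.columns:
        raise ValueError("feature table must have a 'label' column")
    labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), labels


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())


def load_image_dir(directory) -> tuple[np.ndarray, list[str]]:
    """Load every PNG/JPEG in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not paths:
        raise FileNotFoundError(f"no images found in {directory}")
    return np.stack([load_image(p) for p in paths]), [p.name for p in paths]
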