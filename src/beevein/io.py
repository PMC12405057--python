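"""File interfaces: images, masks, and the 45-feature table schema."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "read_feature_table",
    "write_feature_table",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as a float grayscale image in [0, 1]; RGB(A) is
    converted with the 0.299/0.587/0.114 luma weights."""
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def save_image(img: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


_EXPECTED_COLUMNS = ["image_id", *FEATURE_NAMES]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table (image_id + 45 features) as CSV with full
    float precision."""
    _validate_schema(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _validate_schema(table)
    return table


def _validate_schema(table: pd.DataFrame) -> None:
    cols = list(table.columns)
    extra = [c for c in cols if c not in _EXPECTED_COLUMNS]
    missing = [c for c in _EXPECTED_COLUMNS if c not in cols]
    if extra:
        raise ValueError(f"unexpected feature-table column(s): {extra}")
    if missing:
        raise ValueError(f"missing feature-table column(s): {missing}")
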