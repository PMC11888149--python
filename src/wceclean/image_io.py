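"""Image and mask I/O for capsule-endoscopy frames.

Frames are 8-bit RGB PNGs; ground-truth masks are binary PNGs where white
(255) marks clean mucosa and black (0) marks contaminated regions.  A
manifest CSV (columns ``image_path``, ``mask_path``, ``split``) pairs them.

Images are kept as 8-bit integers throughout I/O; conversion to real-valued
intensities happens only inside the computation modules.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("wceclean")

MIN_SIDE = 8  # smallest frame side accepted anywhere in the pipeline

__all__ = [
    "ImageFormatError",
    "DimensionError",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "circular_fov",
    "validate_image",
    "validate_mask",
    "read_manifest",
    "write_manifest",
]


class ImageFormatError(ValueError):
    """Raised when a file decodes but violates the 8-bit RGB contract."""


class DimensionError(ValueError):
    """Raised when image/mask shapes violate size or pairing contracts."""


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Validate an H x W x 3 uint8 frame and return it unchanged.

    Raises :class:`DimensionError` for frames smaller than 8 x 8 and
    :class:`ImageFormatError` for anything that is not 3-channel uint8.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ImageFormatError(f"expected H x W x 3 array, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise ImageFormatError(f"expected uint8 pixels, got {pixels.dtype}")
    h, w = pixels.shape[:2]
    if h < MIN_SIDE or w < MIN_SIDE:
        raise DimensionError(f"frame {h}x{w} smaller than minimum {MIN_SIDE}x{MIN_SIDE}")
    return pixels


def validate_mask(values: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate an H x W boolean mask, optionally against a paired shape."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise DimensionError(f"expected H x W mask, got shape {values.shape}")
    if values.dtype != np.bool_:
        raise ImageFormatError(f"expected boolean mask, got {values.dtype}")
    if shape is not None and values.shape != tuple(shape):
        raise DimensionError(f"mask shape {values.shape} does not match image {tuple(shape)}")
    return values


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image as an H x W x 3 uint8 array.

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped.  Non-8-bit files raise :class:`ImageFormatError`.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: expected 8-bit depth, got {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: unsupported channel layout {arr.shape}")
    return validate_image(np.ascontiguousarray(arr))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary ground-truth mask; values > 127 map to True (clean).

    The >127 threshold lets anti-aliased freehand annotations degrade
    gracefully; genuinely non-binary content is accepted with a warning.
    RGB masks must have identical channels and are reduced to the first.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if not (arr == arr[:, :, :1]).all():
            raise ImageFormatError(f"{path}: RGB mask channels differ; not a binary mask")
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: unsupported mask layout {arr.shape}")
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 255)).all():
        logger.warning("mask %s has non-binary values %s; thresholding at >127", path, uniq[:8])
    return arr > 127


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an H x W x 3 uint8 frame as PNG."""
    iio.imwrite(Path(path), validate_image(image))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG (True -> 255)."""
    mask = validate_mask(mask)
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def circular_fov(height: int, width: int, margin_fraction: float = 0.0) -> np.ndarray:
    """Boolean mask of the circular imaging field of view.

    Capsule frames carry dark, non-informative corners; this mask is True
    inside the centred circle of radius ``min(H, W) / 2 * (1 - margin_fraction)``.

    Parameters
    ----------
    height, width
        Frame dimensions in pixels.
    margin_fraction
        Fraction of the radius trimmed from the rim, in [0, 0.5).
    """
    if not 0.0 <= margin_fraction < 0.5:
        raise ValueError(f"margin_fraction must be in [0, 0.5), got {margin_fraction}")
    radius = min(height, width) / 2.0 * (1.0 - margin_fraction)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.ogrid[:height, :width]
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    if not fov.any():
        raise ValueError("field-of-view mask is empty")
    return fov


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an image/mask pairing manifest CSV.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"image_path", "mask_path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    root = path.parent
    for col in ("image_path", "mask_path"):
        df[col] = [str(p) if Path(p).is_absolute() else str(root / p) for p in df[col]]
    if "split" not in df.columns:
        df["split"] = "all"
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)
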