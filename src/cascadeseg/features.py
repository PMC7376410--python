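"""Intensity preprocessing and per-pixel feature extraction.

Each pixel is represented by the triplet (grayscale, windowed mean, windowed
median) computed over an odd ``window``×``window`` neighborhood (default 5)
with reflect padding at the borders.  Intensity standardization is a z-score
over the nonzero (brain) pixels, leaving the zero background — common in
skull-stripped MRI — untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import ImageVolume, LabelMap

__all__ = ["FeatureConfig", "PixelFeatureTable", "normalize_intensity", "pixel_features",
           "augment_with_labels"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    """Feature-extraction tunables: neighborhood size and normalization toggle."""

    window: int = 5
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd positive integer, got {self.window}")


@dataclass
class PixelFeatureTable:
    """Per-pixel feature rows in row-major scan order.

    ``coords`` is an (n, ndim) integer array of pixel coordinates into the
    source grid; ``features`` an (n, k) float array whose columns are named in
    ``columns``.
    """

    coords: np.ndarray
    features: np.ndarray
    columns: List[str] = field(default_factory=list)
    shape: tuple = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.coords.shape[0] != self.features.shape[0]:
            raise ValueError("one feature row per coordinate required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature values must be finite")
        if not self.columns:
            self.columns = [f"f{i}" for i in range(self.features.shape[1])]


def normalize_intensity(volume: ImageVolume) -> ImageVolume:
    """Z-score intensities over nonzero pixels; exact zeros stay zero.

    After normalization the nonzero pixels have mean 0 and standard deviation
    1.  A constant nonzero image has zero variance: it is centered to zero
    mean but the unit-scale step is skipped (logged).
    """
    data = volume.data.copy()
    mask = data != 0
    if not mask.any():
        return ImageVolume(data=data, modality=volume.modality, spacing=volume.spacing)
    vals = data[mask]
    mean = vals.mean()
    sd = vals.std()
    if sd == 0:
        logger.warning("constant nonzero image: centered only, unit scaling skipped")
        data[mask] = vals - mean
    else:
        data[mask] = (vals - mean) / sd
    return ImageVolume(data=data, modality=volume.modality, spacing=volume.spacing)


def pixel_features(image: ImageVolume, config: Optional[FeatureConfig] = None) -> PixelFeatureTable:
    """Compute the (grayscale, windowed mean, windowed median) triplet per pixel.

    The mean and median are taken over the ``window``-sized square (cube in
    3-D) neighborhood, with reflect padding at the borders; rows are emitted
    in row-major scan order.
    """
    config = config or FeatureConfig()
    data = image.data
    if config.window > min(data.shape):
        raise ValueError(
            f"window {config.window} exceeds smallest image dimension {min(data.shape)}"
        )
    half = config.window // 2
    padded = np.pad(data, half, mode="reflect") if half else data
    # contiguous copy so each window reduces in the same memory order as a
    # stand-alone window array (keeps the statistics bit-reproducible)
    win = np.ascontiguousarray(sliding_window_view(padded, (config.window,) * data.ndim))
    reduce_axes = tuple(range(data.ndim, 2 * data.ndim))
    mean = win.mean(axis=reduce_axes)
    median = np.median(win, axis=reduce_axes)
    coords = np.indices(data.shape).reshape(data.ndim, -1).T
    features = np.column_stack([data.ravel(), mean.ravel(), median.ravel()])
    return PixelFeatureTable(coords=coords, features=features,
                             columns=["gray", "mean", "median"], shape=data.shape)


def augment_with_labels(table: PixelFeatureTable, labels: LabelMap) -> PixelFeatureTable:
    """Append the label value at each row's coordinate as an extra feature column.

    This is how the presegmentation enters the SVM stage: the refinement
    classifier sees the intensity features *and* the current label guess.
    Applying the function twice appends two label columns; that is documented
    behavior, not an error.
    """
    if table.shape and tuple(table.shape) != tuple(labels.shape):
        raise ValueError(f"label map shape {labels.shape} != table source shape {table.shape}")
    idx = tuple(table.coords.T)
    label_col = labels.data[idx].astype(np.float64)
    n_existing = sum(1 for c in table.columns if c.startswith("label"))
    name = "label" if n_existing == 0 else f"label{n_existing + 1}"
    return PixelFeatureTable(
        coords=table.coords,
        features=np.column_stack([table.features, label_col]),
        columns=table.columns + [name],
        shape=table.shape,
    )
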