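"""FISH channel quantification: puncta and percent of tissue area stained.

A probe channel (e.g. Csf1r, Csf1, Il34) is summarized in two ways: a
count of punctate dots found by blob detection at the dot scale, and the
stained-area fraction of the tissue, reported in percent.  Both a
tissue-within-ROI and a whole-ROI denominator are emitted, because the
normalization convention varies between studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .ihc import RoiRegion
from .stacks import otsu_with_floor

__all__ = [
    "FishChannel",
    "AreaStainedResult",
    "detect_puncta",
    "stain_mask_from_channel",
    "tissue_mask_from_dapi",
    "percent_area_stained",
]


@dataclass
class FishChannel:
    """A single fluorescence channel with its probe label and pixel size."""

    pixels: np.ndarray
    channel_name: str
    mpp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass(frozen=True)
class AreaStainedResult:
    """Percent of tissue area stained within an ROI, plus puncta count."""

    roi: str
    channel: str
    percent_area: float  # stain / (tissue AND roi), in %
    percent_of_roi: float  # stain / roi, in %
    n_puncta: int


def detect_puncta(
    channel: FishChannel,
    spot_sigma: float = 1.0,
    threshold: float = 0.05,
) -> np.ndarray:
    """Detect punctate dots; returns an (n, 3) array of (row, col, area_px).

    Band-pass blob detection (Laplacian of Gaussian) at the physical dot
    scale ``spot_sigma`` (um); ``threshold`` is the LoG response cutoff on
    the unit-normalized image.  A blank channel yields an empty array.
    """
    if spot_sigma <= 0:
        raise ValueError("spot_sigma must be positive")
    img = channel.pixels
    rng_ = img.max() - img.min()
    if rng_ == 0:
        return np.empty((0, 3))
    norm = (img - img.min()) / rng_
    sigma_px = spot_sigma / channel.mpp
    blobs = blob_log(
        norm,
        min_sigma=0.6 * sigma_px,
        max_sigma=1.8 * sigma_px,
        num_sigma=5,
        threshold=threshold,
    )
    if blobs.size == 0:
        return np.empty((0, 3))
    radii = blobs[:, 2] * np.sqrt(2.0)
    return np.column_stack([blobs[:, 0], blobs[:, 1], np.pi * radii**2])


def stain_mask_from_channel(
    channel: FishChannel,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a probe channel into a boolean stain mask."""
    img = channel.pixels
    if method == "fixed":
        if threshold is None:
            raise ValueError("threshold required for fixed method")
        thr = float(threshold)
    else:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        # floored Otsu: a blank channel must yield an empty mask, not a
        # bisection of its noise
        thr = otsu_with_floor(img)
    return img > thr


def tissue_mask_from_dapi(
    dapi: FishChannel, smooth_sigma: float = 2.0, closing_iterations: int = 3
) -> np.ndarray:
    """Tissue mask from the nuclear channel: smooth, Otsu, close, fill."""
    img = ndimage.gaussian_filter(dapi.pixels, smooth_sigma / dapi.mpp)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_closing(mask, iterations=closing_iterations)
    return ndimage.binary_fill_holes(mask)


def percent_area_stained(
    stain_mask: np.ndarray,
    tissue_mask: np.ndarray,
    roi: RoiRegion,
    channel_name: str = "",
    n_puncta: int = 0,
) -> AreaStainedResult:
    """Percent of tissue area stained within an ROI.

    ``percent_area = 100 x |stain AND tissue AND roi| / |tissue AND roi|``;
    an empty tissue-within-ROI denominator is an error.  The whole-ROI
    denominator is also reported as ``percent_of_roi``.
    """
    if stain_mask.shape != tissue_mask.shape or stain_mask.shape != roi.mask.shape:
        raise ValueError("masks and ROI must share a shape")
    tissue_in_roi = tissue_mask & roi.mask
    denom = int(tissue_in_roi.sum())
    if denom == 0:
        raise ValueError(f"ROI {roi.name!r} contains no tissue: denominator undefined")
    stained = int((stain_mask & tissue_in_roi).sum())
    roi_px = int(roi.mask.sum())
    return AreaStainedResult(
        roi=roi.name,
        channel=channel_name,
        percent_area=100.0 * stained / denom,
        percent_of_roi=100.0 * (stain_mask & roi.mask).sum() / roi_px,
        n_puncta=n_puncta,
    )
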