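"""Core raster containers shared across the pipeline.

A grey-scale muscle image is modelled as a grid ``f(m, n)`` of integer grey
levels, quantized to ``G`` levels; tissue masks assign each pixel to
background, muscle or fibrous tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tissue label codes used throughout the package.
LABEL_BACKGROUND = 0
LABEL_MUSCLE = 1
LABEL_FIBROUS = 2

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_MUSCLE: "muscle",
    LABEL_FIBROUS: "fibrous",
}


@dataclass(frozen=True)
class GreyImage:
    """A 2-D grey-scale image with a declared number of grey levels.

    Parameters
    ----------
    pixels
        2-D integer array of grey levels, every value in ``[0, levels - 1]``.
    levels
        Number of grey levels ``G`` the image is quantized to (256 for raw
        8-bit images).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("pixel values must be integral grey levels")
            px = px.astype(np.int64)
        if self.levels < 2:
            raise ValueError("an image needs at least 2 grey levels")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TissueMask:
    """Per-pixel tissue labels (0 = background, 1 = muscle, 2 = fibrous)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        if not np.isin(lab, (LABEL_BACKGROUND, LABEL_MUSCLE, LABEL_FIBROUS)).all():
            raise ValueError("labels must be 0 (background), 1 (muscle) or 2 (fibrous)")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def background_count(self) -> int:
        return int(np.count_nonzero(self.labels == LABEL_BACKGROUND))

    @property
    def muscle_count(self) -> int:
        return int(np.count_nonzero(self.labels == LABEL_MUSCLE))

    @property
    def fibrous_count(self) -> int:
        return int(np.count_nonzero(self.labels == LABEL_FIBROUS))

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of the non-background (ROI) pixels."""
        return self.labels != LABEL_BACKGROUND

    def counts(self) -> dict[str, int]:
        return {
            "background": self.background_count,
            "muscle": self.muscle_count,
            "fibrous": self.fibrous_count,
        }


def quantize(
    pixels: np.ndarray | GreyImage,
    levels: int,
    roi: np.ndarray | None = None,
) -> GreyImage:
    """Min–max quantize an image to ``levels`` grey levels.

    The scaling window is taken from the ROI (or the whole image if no ROI
    is given); pixels outside the window are clipped into range.  No gamma
    correction or histogram equalization is applied anywhere.
    """
    if isinstance(pixels, GreyImage):
        pixels = pixels.pixels
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    if levels < 2:
        raise ValueError("need at least 2 quantization levels")
    sample = arr if roi is None else arr[np.asarray(roi, dtype=bool)]
    if sample.size == 0:
        raise ValueError("ROI is empty; nothing to quantize")
    lo, hi = float(sample.min()), float(sample.max())
    if hi <= lo:
        q = np.zeros(arr.shape, dtype=np.int64)
    else:
        q = np.floor((arr - lo) / (hi - lo) * levels).astype(np.int64)
        np.clip(q, 0, levels - 1, out=q)
    return GreyImage(pixels=q, levels=levels)
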