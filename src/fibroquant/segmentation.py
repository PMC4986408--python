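"""Edge-driven two-tissue segmentation.

The segmentation rests on the distinct grey-level contrast between fibrous
and muscle tissue.  Edge strength from the Sobel operator highlights the
transition zones between the two tissues; grey-level co-occurrences of
adjacent pixels, weighted up at those transitions, form an *edge
co-occurrence matrix* whose leading diagonal concentrates the within-tissue
grey levels.  The two dominant diagonal peaks define the muscle (darker) and
fibrous (brighter) classes; labelling every grey level by its side of the
inter-peak valley turns the matrix into a look-up table (LUT) that segments
any ROI pixel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .images import (
    GreyImage,
    LABEL_BACKGROUND,
    LABEL_FIBROUS,
    LABEL_MUSCLE,
    TissueMask,
    quantize,
)

#: The Sobel edge operator E (horizontal-gradient form); its transpose
#: responds to the orthogonal direction.
SOBEL_KERNEL = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)


class SinglePeakFallbackWarning(UserWarning):
    """Fewer than two diagonal peaks: fell back to a single-threshold split."""


@dataclass(frozen=True)
class EdgeStrengthImage:
    """Per-pixel gradient magnitude ``sqrt(Gx^2 + Gy^2)``."""

    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitudes, dtype=np.float64)
        if mag.ndim != 2:
            raise ValueError("magnitudes must be 2-D")
        if (mag < 0).any():
            raise ValueError("edge strengths must be non-negative")
        object.__setattr__(self, "magnitudes", mag)

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape


@dataclass(frozen=True)
class EdgeCooccurrenceMatrix:
    """Symmetric co-occurrence counts of adjacent grey levels, edge-weighted.

    ``label_map`` (filled by :func:`label_leading_diagonal`) assigns every
    grey level to a tissue class and is the segmentation LUT;
    ``diagonal_peaks`` holds the grey levels of the retained diagonal modes.
    """

    counts: np.ndarray
    levels: int
    label_map: np.ndarray | None = None
    diagonal_peaks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.shape != (self.levels, self.levels):
            raise ValueError("counts must be a G x G matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def diagonal_profile(self) -> np.ndarray:
        return np.diag(self.counts).copy()


def sobel_edge_strength(image: GreyImage | np.ndarray) -> EdgeStrengthImage:
    """Convolve the Sobel operator pair with the image.

    ``Gx`` uses the kernel as printed, ``Gy`` its transpose; borders are
    reflect-padded.  A constant image yields identically zero magnitudes.
    """
    arr = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    arr = arr.astype(np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    gx = ndimage.correlate(arr, SOBEL_KERNEL, mode="reflect")
    gy = ndimage.correlate(arr, SOBEL_KERNEL.T, mode="reflect")
    return EdgeStrengthImage(magnitudes=np.hypot(gx, gy))


def edge_cooccurrence_matrix(
    image: GreyImage,
    edges: EdgeStrengthImage,
    roi: np.ndarray | None = None,
) -> EdgeCooccurrenceMatrix:
    """Accumulate edge-weighted co-occurrences of adjacent grey levels.

    Every horizontally or vertically adjacent pixel pair (both endpoints
    inside the ROI) contributes with weight ``1 + s`` where ``s`` is the
    mean of the two endpoints' edge strengths normalized to [0, 1], so
    transition zones are emphasized while the zero-edge limit is plain grey
    co-occurrence.  Accumulation is symmetric: counts[i, j] == counts[j, i].
    """
    if not isinstance(image, GreyImage):
        raise TypeError("image must be a quantized GreyImage")
    if image.shape != edges.shape:
        raise ValueError("image and edge image dimensions differ")
    G = image.levels
    if G < 2:
        raise ValueError("need at least 2 grey levels")
    q = image.pixels
    mag = edges.magnitudes
    peak = mag.max()
    norm = mag / peak if peak > 0 else np.zeros_like(mag)
    mask = (
        np.ones(image.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)
    )

    counts = np.zeros(G * G, dtype=np.float64)
    for dy, dx in ((0, 1), (1, 0)):
        a = q[: q.shape[0] - dy, : q.shape[1] - dx]
        b = q[dy:, dx:]
        wa = norm[: q.shape[0] - dy, : q.shape[1] - dx]
        wb = norm[dy:, dx:]
        valid = mask[: q.shape[0] - dy, : q.shape[1] - dx] & mask[dy:, dx:]
        w = 1.0 + 0.5 * (wa[valid] + wb[valid])
        i = a[valid].astype(np.int64)
        j = b[valid].astype(np.int64)
        counts += np.bincount(i * G + j, weights=w, minlength=G * G)
        counts += np.bincount(j * G + i, weights=w, minlength=G * G)
    return EdgeCooccurrenceMatrix(counts=counts.reshape(G, G), levels=G)


def _smooth_profile(profile: np.ndarray, levels: int) -> np.ndarray:
    window = max(3, levels // 16)
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    # reflect-pad so mass near the ends is not attenuated
    pad = window // 2
    padded = np.pad(profile, pad, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def label_leading_diagonal(ecm: EdgeCooccurrenceMatrix) -> EdgeCooccurrenceMatrix:
    """Label grey levels from the modes of the leading-diagonal profile.

    The diagonal profile is smoothed with a moving average (window G/16,
    minimum 3, forced odd) and its local maxima ranked by smoothed height.
    The tallest peak is paired with the tallest other peak that is
    separated from it by a genuine valley — one whose smoothed minimum
    drops below half the lower of the two peak heights — so that noise
    wiggles riding on a single tissue cluster are never mistaken for a
    second tissue class.  The pair becomes muscle (lower grey) and fibrous
    (higher grey); the midpoint of the minimal valley plateau between them
    is the class boundary, with the boundary level itself assigned to
    muscle.

    With no valley-separated second peak the image is treated as single
    tissue: every grey level is labelled muscle and a
    :class:`SinglePeakFallbackWarning` is emitted.
    """
    if ecm.counts.sum() <= 0:
        raise ValueError("empty co-occurrence matrix")
    G = ecm.levels
    profile = ecm.diagonal_profile
    smooth = _smooth_profile(profile, G)

    # sentinel padding lets modes at grey 0 or G-1 register as peaks
    padded = np.concatenate(([-1.0], smooth, [-1.0]))
    peak_idx, _ = signal.find_peaks(padded)
    peak_idx = peak_idx - 1
    peak_idx = peak_idx[smooth[peak_idx] > 0]

    label_map = np.full(G, LABEL_MUSCLE, dtype=np.uint8)
    pair: tuple[int, int] | None = None
    if len(peak_idx) >= 2:
        by_height = peak_idx[np.argsort(smooth[peak_idx], kind="stable")][::-1]
        p1 = int(by_height[0])
        # a candidate second class must carry at least 1% of the dominant
        # peak's height (detection limit for very sparse tissue) and be
        # separated from it by a genuine valley
        floor = 0.01 * smooth[p1]
        for cand in by_height[1:]:
            if smooth[cand] < floor:
                break  # candidates are height-sorted; the rest are smaller
            lo, hi = sorted((p1, int(cand)))
            valley_min = smooth[lo : hi + 1].min()
            if valley_min < 0.5 * min(smooth[lo], smooth[hi]):
                pair = (lo, hi)
                break

    if pair is None:
        peaks: tuple[int, ...] = (int(peak_idx[0]),) if len(peak_idx) else ()
        warnings.warn(
            "no valley-separated second diagonal peak; treating the ROI as "
            "single tissue (all muscle)",
            SinglePeakFallbackWarning,
            stacklevel=2,
        )
    else:
        lo, hi = pair
        seg = smooth[lo : hi + 1]
        flat = np.flatnonzero(seg == seg.min())
        boundary = lo + int(flat[len(flat) // 2])
        label_map[boundary + 1 :] = LABEL_FIBROUS
        peaks = (lo, hi)
    return replace(ecm, label_map=label_map, diagonal_peaks=peaks)


def lut_segment(
    image: GreyImage,
    ecm: EdgeCooccurrenceMatrix,
    roi: np.ndarray | None = None,
) -> TissueMask:
    """Apply the labelled matrix as a LUT over the ROI.

    Each ROI pixel gets the tissue class of its grey level; pixels outside
    the ROI are background.
    """
    if ecm.label_map is None:
        raise ValueError("ecm has no label_map; run label_leading_diagonal first")
    if not isinstance(image, GreyImage):
        raise TypeError("image must be a quantized GreyImage")
    if image.levels != ecm.levels:
        raise ValueError("image and LUT grey-level counts differ")
    mask = (
        np.ones(image.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)
    )
    if mask.shape != image.shape:
        raise ValueError("ROI and image dimensions differ")
    if not mask.any():
        raise ValueError("empty ROI")
    labels = np.full(image.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[mask] = ecm.label_map[image.pixels[mask]]
    return TissueMask(labels=labels)


def fibrous_muscle_ratio(mask: TissueMask) -> float:
    """Fibrous pixel count divided by muscle pixel count."""
    muscle = mask.muscle_count
    if muscle == 0:
        raise ValueError("ratio undefined: no muscle pixels in mask")
    return mask.fibrous_count / muscle


def bilateral_average(left: float, right: float) -> float:
    """Average a bilateral pair of measurements."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise ValueError("bilateral values must be finite")
    if left < 0 or right < 0:
        raise ValueError("bilateral values must be non-negative")
    return 0.5 * (left + right)


def segment_image(
    pixels: np.ndarray | GreyImage,
    roi: np.ndarray | None = None,
    levels: int = 64,
) -> tuple[TissueMask, EdgeCooccurrenceMatrix]:
    """Full edge-driven segmentation of one grey-scale slice.

    Quantizes the ROI to ``levels`` grey levels (min-max, no gamma change),
    computes Sobel edge strength on the raw image, builds and labels the
    edge co-occurrence matrix, and applies the LUT.  Returns the tissue
    mask together with the labelled matrix.
    """
    raw = pixels.pixels if isinstance(pixels, GreyImage) else np.asarray(pixels)
    q = quantize(raw, levels, roi=roi)
    edges = sobel_edge_strength(raw)
    ecm = edge_cooccurrence_matrix(q, edges, roi=roi)
    ecm = label_leading_diagonal(ecm)
    return lut_segment(q, ecm, roi=roi), ecm
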