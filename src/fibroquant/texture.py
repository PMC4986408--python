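"""Second-order (GLCM) texture statistics.

The grey-level co-occurrence matrix P(i, j | dx, dy) holds the relative
frequency with which two pixels separated by the displacement (dx, dy) carry
grey levels i and j.  From it we derive the three features used to
characterize muscle heterogeneity: the pixel correlation, the co-occurrence
entropy and the angular second moment (ASM).

Conventions
-----------
* dx runs rightward along samples (columns), dy downward along lines (rows);
  a polar offset (d, theta) maps to ``dx = d cos(theta)``,
  ``dy = -d sin(theta)``, rounded to integers.
* P = W * Q where Q is the raw pair-count matrix and W = 1 / (total count).
* Entropy is reported in bits (base-2 logarithm) by default; the base is
  configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .images import GreyImage, quantize


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined when a marginal has zero variance."""


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence probabilities with their offset."""

    P: np.ndarray
    offset: tuple[int, int]
    levels: int
    normalization: float  # W = 1 / total raw count

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.shape != (self.levels, self.levels):
            raise ValueError("P must be G x G")
        if (P < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class GLCMMarginals:
    """Marginals Px, Py of a GLCM with their means and standard deviations."""

    Px: np.ndarray
    Py: np.ndarray
    mean: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


@dataclass(frozen=True)
class TextureFeatureSet:
    """Orientation-averaged texture features of one ROI."""

    correlation: float
    entropy: float  # bits
    asm: float


def offset_from_polar(distance: int, theta_deg: float) -> tuple[int, int]:
    """Map a (d, theta) displacement to integer (dx, dy)."""
    rad = math.radians(theta_deg)
    return (
        int(round(distance * math.cos(rad))),
        int(round(-distance * math.sin(rad))),
    )


def compute_glcm(
    image: GreyImage | np.ndarray,
    roi: np.ndarray | None = None,
    *,
    offset: tuple[int, int] = (1, 0),
    levels: int | None = None,
    symmetric: bool = False,
) -> GLCM:
    """Accumulate the co-occurrence matrix for one displacement.

    Ordered pixel pairs (p, p + offset) with both endpoints inside the ROI
    are counted into Q(i, j); with ``symmetric=True`` the reversed pair is
    counted as well.  P = W * Q with W the reciprocal total count.
    """
    if isinstance(image, GreyImage):
        q = image.pixels
        G = image.levels if levels is None else levels
    else:
        q = np.asarray(image)
        if not np.issubdtype(q.dtype, np.integer):
            raise TypeError("a plain-array image must hold integer grey levels")
        G = levels if levels is not None else int(q.max()) + 1
    if q.max() >= G:
        raise ValueError(f"grey levels exceed G={G}")
    dx, dy = offset
    if dx == 0 and dy == 0:
        raise ValueError("offset must be nonzero")
    H, W_ = q.shape
    mask = np.ones(q.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)

    r0, r1 = max(0, -dy), H - max(0, dy)
    c0, c1 = max(0, -dx), W_ - max(0, dx)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("offset larger than the image")
    a = q[r0:r1, c0:c1]
    b = q[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    i = a[valid].astype(np.int64)
    j = b[valid].astype(np.int64)
    Q = np.bincount(i * G + j, minlength=G * G).astype(np.float64)
    if symmetric:
        Q += np.bincount(j * G + i, minlength=G * G)
    total = Q.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at this offset inside the ROI")
    W_norm = 1.0 / total
    return GLCM(P=(Q * W_norm).reshape(G, G), offset=(dx, dy), levels=G,
                normalization=W_norm)


def glcm_marginals(glcm: GLCM) -> GLCMMarginals:
    """Marginal distributions and their moments.

    Px(i) sums P(i, j) over j (rows), Py(j) over i (columns); mu_x, mu_y,
    sigma_x, sigma_y are the means and standard deviations of Px and Py.
    """
    P = glcm.P
    Px = P.sum(axis=1)
    Py = P.sum(axis=0)
    levels = np.arange(glcm.levels, dtype=np.float64)
    mu_x = float(levels @ Px)
    mu_y = float(levels @ Py)
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2) @ Px))
    sigma_y = float(np.sqrt(((levels - mu_y) ** 2) @ Py))
    return GLCMMarginals(
        Px=Px,
        Py=Py,
        mean=float(P.mean()),
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
    )


def glcm_correlation(glcm: GLCM, marg: GLCMMarginals | None = None) -> float:
    """Pixel correlation: cov(i, j) under P divided by sigma_x * sigma_y.

    Lies in [-1, 1]; raises :class:`UndefinedCorrelationError` when either
    marginal is degenerate (zero variance).
    """
    if marg is None:
        marg = glcm_marginals(glcm)
    if marg.sigma_x == 0 or marg.sigma_y == 0:
        raise UndefinedCorrelationError(
            "undefined correlation: a marginal distribution has zero variance"
        )
    levels = np.arange(glcm.levels, dtype=np.float64)
    di = levels - marg.mu_x
    dj = levels - marg.mu_y
    cov = float(di @ glcm.P @ dj)
    corr = cov / (marg.sigma_x * marg.sigma_y)
    if abs(corr) > 1.0:
        if abs(corr) - 1.0 > 1e-9:
            raise FloatingPointError(f"correlation overshoot: {corr}")
        corr = math.copysign(1.0, corr)
    return corr


def glcm_entropy(glcm: GLCM, base: float = 2.0) -> float:
    """Co-occurrence entropy ``-sum P log P`` (zero entries contribute 0)."""
    P = glcm.P[glcm.P > 0]
    return float(-(P * (np.log(P) / np.log(base))).sum())


def glcm_asm(glcm: GLCM) -> float:
    """Angular second moment ``sum P^2`` — high for homogeneous regions."""
    return float((glcm.P**2).sum())


#: The four standard orientations at which GLCMs are averaged.
ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)


def texture_profile(
    image: GreyImage | np.ndarray,
    roi: np.ndarray | None = None,
    levels: int = 64,
    distance: int = 1,
    entropy_base: float = 2.0,
) -> TextureFeatureSet:
    """Orientation-averaged correlation, entropy and ASM of one ROI.

    The raw image is min-max quantized to ``levels`` grey levels over the
    ROI; symmetric GLCMs are computed at the given pixel distance for
    theta in {0, 45, 90, 135} degrees and each feature is averaged across
    the four orientations.
    """
    raw = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    q = quantize(raw, levels, roi=roi)
    corrs, ents, asms = [], [], []
    for theta in ORIENTATIONS_DEG:
        glcm = compute_glcm(
            q, roi, offset=offset_from_polar(distance, theta), symmetric=True
        )
        marg = glcm_marginals(glcm)
        corrs.append(glcm_correlation(glcm, marg))
        ents.append(glcm_entropy(glcm, base=entropy_base))
        asms.append(glcm_asm(glcm))
    return TextureFeatureSet(
        correlation=float(np.mean(corrs)),
        entropy=float(np.mean(ents)),
        asm=float(np.mean(asms)),
    )
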