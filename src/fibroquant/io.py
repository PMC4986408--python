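"""Reading and writing images, masks and tables.

Grey images and label maps travel as TIFF, PNG or NIfTI (.nii / .nii.gz);
cohort tables and ratio tables as CSV.  Format is dispatched on the file
suffix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .images import GreyImage, TissueMask

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_PNG_SUFFIXES = (".png",)


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grey-scale image (NIfTI, TIFF or PNG) as an array."""
    path = Path(path)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
    elif sfx in _TIFF_SUFFIXES:
        import tifffile

        arr = tifffile.imread(str(path))
    elif sfx in _PNG_SUFFIXES:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse RGB(A) to grey
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path.name} is not a 2-D image (shape {arr.shape})")
    return arr


def write_image(path: str | Path, pixels: np.ndarray | GreyImage) -> Path:
    """Write a 2-D image; 16-bit for TIFF/PNG, native dtype for NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = pixels.pixels if isinstance(pixels, GreyImage) else np.asarray(pixels)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr.astype(np.int16), np.eye(4)), str(path))
    elif sfx in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(str(path), arr.astype(np.uint16))
    elif sfx in _PNG_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr.astype(np.uint16))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return path


def read_roi_mask(path: str | Path) -> np.ndarray:
    """Read an ROI mask (any image format); nonzero pixels are the ROI."""
    return read_image(path) != 0


def write_mask(path: str | Path, mask: TissueMask) -> Path:
    """Write a tissue label map (0=background, 1=muscle, 2=fibrous).

    PNG output is 8-bit indexed; TIFF and NIfTI keep integer labels.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sfx = _suffix(path)
    if sfx in _PNG_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(str(path), mask.labels.astype(np.uint8))
    elif sfx in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(str(path), mask.labels.astype(np.uint8))
    elif sfx in _NIFTI_SUFFIXES:
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    return path


def read_mask(path: str | Path) -> TissueMask:
    """Read a tissue label map written by :func:`write_mask`."""
    return TissueMask(labels=read_image(path).astype(np.uint8))
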