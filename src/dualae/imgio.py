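"""Reading and writing 2D grayscale images and masks.

Supported formats: PNG (8/16-bit integer, via imageio), TIFF (integer or
float, via tifffile) and NIfTI single-slice volumes (via nibabel). Integer
intensities are rescaled to [0, 1] by the dtype maximum; floats are taken
as-is and clipped.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .phantom import Image2D

__all__ = ["read_image", "read_mask", "write_image", "write_mask", "write_nifti"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_image(path, brain_mask_path=None) -> Image2D:
    """Read one grayscale slice; raises a ValueError naming the file when it
    cannot be read."""
    path = Path(path)
    try:
        if _is_nifti(path):
            data = np.asanyarray(nib.load(path).dataobj)
            data = np.squeeze(data)
            if data.ndim == 3:  # take the middle slice of a thin volume
                data = data[:, :, data.shape[2] // 2]
            lo, hi = float(data.min()), float(data.max())
            arr = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
        elif path.suffix.lower() in (".tif", ".tiff"):
            arr = _to_unit_float(tifffile.imread(path))
        else:
            arr = _to_unit_float(iio.imread(path))
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"cannot read image {path}: not a single 2D slice")
    mask = read_mask(brain_mask_path) if brain_mask_path is not None else None
    return Image2D(np.asarray(arr, dtype=np.float64), brain_mask=mask)


def read_mask(path) -> np.ndarray:
    path = Path(path)
    try:
        if _is_nifti(path):
            arr = np.squeeze(np.asanyarray(nib.load(path).dataobj))
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_image(path, image: Image2D) -> None:
    """16-bit PNG or float TIFF depending on the suffix."""
    path = Path(path)
    pix = np.clip(image.pixels, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pix.astype(np.float32))
    else:
        iio.imwrite(path, np.round(pix * 65535).astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    """8-bit PNG, 0/255."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_nifti(path, image: Image2D) -> None:
    """Single-slice NIfTI volume (identity affine)."""
    data = image.pixels.astype(np.float32)[:, :, np.newaxis]
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(Path(path)))
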