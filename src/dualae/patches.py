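"""Directional patch extraction, normalization, and overlap-mean reassembly.

Horizontal patches are 16x64 windows and vertical patches 64x16 windows,
flattened row-major to length-1024 vectors. Both orientations share one
nominal anchor grid (stride 16 by default) so that row k of the horizontal
patch matrix and row k of the vertical patch matrix describe the same image
neighbourhood and can be paired in latent space. Windows that would cross
the image border are clamped inward per orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateDataError
from .phantom import Image2D

__all__ = [
    "HORIZONTAL", "VERTICAL", "PATCH_SHAPES", "PATCH_LEN",
    "PatchGrid", "PatchSet", "NormStats",
    "build_grid", "extract", "fit_norm", "normalize", "denormalize",
    "reassemble", "save_patch_set", "load_patch_set",
]

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
#: window shape (rows, cols) per orientation
PATCH_SHAPES: dict[str, tuple[int, int]] = {HORIZONTAL: (16, 64), VERTICAL: (64, 16)}
PATCH_LEN = 16 * 64


def _check_orientation(orientation: str) -> tuple[int, int]:
    try:
        return PATCH_SHAPES[orientation]
    except KeyError:
        raise ValueError(
            f"orientation must be one of {sorted(PATCH_SHAPES)}, got {orientation!r}"
        ) from None


def _axis_positions(length: int, stride: int) -> list[int]:
    # Nominal positions tile the 16-pixel extent; the 64-pixel extent is
    # handled by clamping at extraction time.
    pos = list(range(0, length - 16 + 1, stride))
    if pos[-1] != length - 16:
        pos.append(length - 16)
    return pos


@dataclass(frozen=True)
class PatchGrid:
    """Shared anchor grid for both patch orientations.

    ``anchors`` are nominal (row, col) top-left positions, row-major sorted
    and unique; per-orientation window positions are obtained by clamping
    each anchor so its window fits inside the image.
    """

    image_shape: tuple[int, int]
    anchor_stride: int
    anchors: np.ndarray  # (n, 2) int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def clamped_anchors(self, orientation: str) -> np.ndarray:
        """Per-orientation window top-left positions, one per anchor
        (duplicates possible where border clamping collapses anchors)."""
        h, w = _check_orientation(orientation)
        rows, cols = self.image_shape
        out = self.anchors.copy()
        out[:, 0] = np.minimum(out[:, 0], rows - h)
        out[:, 1] = np.minimum(out[:, 1], cols - w)
        return out

    def window_anchors(self, orientation: str) -> np.ndarray:
        """Deduplicated clamped window positions for one orientation."""
        return np.unique(self.clamped_anchors(orientation), axis=0)


@dataclass
class PatchSet:
    """Flattened patches of one orientation on a grid.

    ``data`` is (n_anchors, 1024) float64, row k holding the row-major
    flattening of the window at anchor k. ``norm`` records which
    normalization, if any, the data are expressed in.
    """

    orientation: str
    data: np.ndarray
    grid: PatchGrid
    norm: "NormStats | None" = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != PATCH_LEN:
            raise ValueError(f"data must be n x {PATCH_LEN}, got {self.data.shape}")
        if self.data.shape[0] != self.grid.n_anchors:
            raise ValueError("one patch row per grid anchor required")
        if not np.isfinite(self.data).all():
            raise ValueError("patch data must be finite")


@dataclass(frozen=True)
class NormStats:
    """Global normalization: standardize, then map the training-set
    standardized range linearly onto [range_lo, range_hi].

    The rescale keeps normalized intensities inside the open unit interval
    required by the logistic-sigmoid decoder while remaining exactly
    invertible.
    """

    mean: float
    std: float
    s_lo: float  # standardized training minimum
    s_hi: float  # standardized training maximum
    range_lo: float = 0.1
    range_hi: float = 0.9

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise DegenerateDataError("std must be > 0")
        if not self.range_lo < self.range_hi:
            raise ValueError("range_lo must be < range_hi")
        if not self.s_lo < self.s_hi:
            raise DegenerateDataError("degenerate standardized range")

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = (np.asarray(x, dtype=np.float64) - self.mean) / self.std
        return self.range_lo + (s - self.s_lo) * (self.range_hi - self.range_lo) / (
            self.s_hi - self.s_lo
        )

    def inverse(self, y: np.ndarray) -> np.ndarray:
        s = self.s_lo + (np.asarray(y, dtype=np.float64) - self.range_lo) * (
            self.s_hi - self.s_lo
        ) / (self.range_hi - self.range_lo)
        return s * self.std + self.mean


def build_grid(image_shape: tuple[int, int], anchor_stride: int = 16) -> PatchGrid:
    """Anchor grid covering the image so every pixel lies inside at least one
    window of each orientation."""
    rows, cols = image_shape
    if rows < 64 or cols < 64:
        raise ValueError(f"image must be at least 64x64 pixels, got {rows}x{cols}")
    if anchor_stride < 1:
        raise ValueError("anchor_stride must be >= 1")
    rpos = _axis_positions(rows, anchor_stride)
    cpos = _axis_positions(cols, anchor_stride)
    anchors = np.array([(r, c) for r in rpos for c in cpos], dtype=np.int64)
    return PatchGrid(image_shape=(rows, cols), anchor_stride=anchor_stride,
                     anchors=anchors)


def extract(image: Image2D, grid: PatchGrid, orientation: str) -> PatchSet:
    """Pure extraction: row k of the result is the flattened window at
    (clamped) anchor k."""
    if image.shape != grid.image_shape:
        raise ValueError(f"grid built for {grid.image_shape}, image is {image.shape}")
    h, w = _check_orientation(orientation)
    pix = image.pixels
    data = np.empty((grid.n_anchors, PATCH_LEN))
    for k, (r, c) in enumerate(grid.clamped_anchors(orientation)):
        data[k] = pix[r:r + h, c:c + w].ravel()
    return PatchSet(orientation=orientation, data=data, grid=grid)


def fit_norm(training_patches: list[PatchSet], range_lo: float = 0.1,
             range_hi: float = 0.9) -> NormStats:
    """One global (mean, std) pooled over all entries of all patch sets of
    both orientations (population convention), plus the pooled standardized
    range used for the affine rescale."""
    if not training_patches:
        raise ValueError("at least one patch set required")
    pooled = np.concatenate([p.data.ravel() for p in training_patches])
    mean = float(pooled.mean())
    std = float(pooled.std())  # population (ddof=0)
    if std == 0.0:
        raise DegenerateDataError("pooled patch variance is zero")
    s_lo = float((pooled.min() - mean) / std)
    s_hi = float((pooled.max() - mean) / std)
    return NormStats(mean=mean, std=std, s_lo=s_lo, s_hi=s_hi,
                     range_lo=range_lo, range_hi=range_hi)


def normalize(patches: PatchSet, norm: NormStats) -> PatchSet:
    return replace(patches, data=norm.forward(patches.data), norm=norm)


def denormalize(patches: PatchSet, norm: NormStats | None = None) -> PatchSet:
    norm = norm if norm is not None else patches.norm
    if norm is None:
        raise ValueError("no NormStats available to invert")
    return replace(patches, data=norm.inverse(patches.data), norm=None)


def reassemble(patch_matrix: np.ndarray, grid: PatchGrid, orientation: str,
               image_shape: tuple[int, int] | None = None,
               ) -> tuple[Image2D, np.ndarray]:
    """Composite patches back to an image; each pixel is the arithmetic mean
    of every patch value covering it. Returns the image and the coverage map."""
    h, w = _check_orientation(orientation)
    shape = image_shape if image_shape is not None else grid.image_shape
    if shape != grid.image_shape:
        raise ValueError("image_shape must match the grid")
    patch_matrix = np.asarray(patch_matrix, dtype=np.float64)
    if patch_matrix.shape != (grid.n_anchors, PATCH_LEN):
        raise ValueError("one row of length 1024 per grid anchor required")
    acc = np.zeros(shape)
    cov = np.zeros(shape, dtype=np.int64)
    for k, (r, c) in enumerate(grid.clamped_anchors(orientation)):
        acc[r:r + h, c:c + w] += patch_matrix[k].reshape(h, w)
        cov[r:r + h, c:c + w] += 1
    if (cov == 0).any():  # pragma: no cover - impossible for a valid grid
        raise ValueError("grid leaves pixels uncovered")
    return Image2D(acc / cov), cov


# ---------------------------------------------------------------------------
# serialization: one-line JSON header + raw float64 block

def save_patch_set(patches: PatchSet, path) -> None:
    header = {
        "orientation": patches.orientation,
        "image_shape": list(patches.grid.image_shape),
        "anchor_stride": patches.grid.anchor_stride,
        "n_patches": int(patches.data.shape[0]),
        "norm": None if patches.norm is None else {
            "mean": patches.norm.mean, "std": patches.norm.std,
            "s_lo": patches.norm.s_lo, "s_hi": patches.norm.s_hi,
            "range_lo": patches.norm.range_lo, "range_hi": patches.norm.range_hi,
        },
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(np.ascontiguousarray(patches.data).tobytes())


def load_patch_set(path) -> PatchSet:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        raw = fh.read()
    grid = build_grid(tuple(header["image_shape"]), header["anchor_stride"])
    data = np.frombuffer(raw, dtype=np.float64).reshape(header["n_patches"], PATCH_LEN)
    norm = None
    if header["norm"] is not None:
        norm = NormStats(**header["norm"])
    return PatchSet(orientation=header["orientation"], data=data.copy(), grid=grid,
                    norm=norm)
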