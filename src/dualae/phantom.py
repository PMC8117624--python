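"""Seeded synthetic brain phantoms with pixel-level ground truth.

The generator stands in for real skull-stripped MRI slices and emulates the
two properties of brain MRI that reconstruction-based anomaly detection
relies on:

* **Shared anatomy.** All subjects drawn with the same ``anatomy_seed``
  share one smooth two-class tissue template (bright/dark matter, like
  white/gray matter in T1) plus a fine shared texture — a learnable normal
  appearance. Each image adds its own small smooth intensity variation
  (``variation_amplitude``), the unlearnable inter-subject component.
* **Bimodal tissue intensity.** Brain pixels cluster at
  ``base_intensity +- tissue_contrast/2`` with soft partial-volume
  boundaries, so a mean-grey-level binarization separates the two classes
  stably instead of splitting a unimodal histogram at its mode.

Anomalies are compact bright blobs (jittered ellipses with re-rolled local
texture) offset by ``anomaly_intensity_shift``. Every image is reproducible
bit-for-bit from its :class:`PhantomSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PlacementError

__all__ = ["Image2D", "PhantomSpec", "generate_phantom", "generate_corpus"]


@dataclass
class Image2D:
    """One grayscale slice: float intensities in [0, 1] plus an optional brain mask.

    Coordinates are (row, col), 0-based, row-major.
    """

    pixels: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite everywhere")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.pixels.shape:
                raise ValueError(
                    f"brain_mask shape {self.brain_mask.shape} != pixels shape {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def domain(self) -> np.ndarray:
        """Evaluation domain: the brain mask if present, else the full frame."""
        if self.brain_mask is not None:
            return self.brain_mask
        return np.ones(self.pixels.shape, dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Attributes
    ----------
    image_size : pixels per side of the square image (>= 128 so at least one
        16x64 patch fits with margin).
    brain_axes : (row, col) semi-axes of the brain ellipse, pixels.
    texture_scale : Gaussian smoothing length of the anatomy fields, pixels.
    texture_amplitude : standard deviation of the shared fine texture,
        intensity units.
    base_intensity : mean brain-tissue intensity in [0, 1]; the two tissue
        classes sit at base +- tissue_contrast/2.
    tissue_contrast : intensity separation of the two tissue classes.
    variation_amplitude : std of the per-image smooth intensity variation
        (inter-subject variability; not shared, hence not learnable).
    skull / skull_width / skull_intensity : optional bright annulus around the
        brain (off by default; real inputs are skull-stripped upstream).
    n_anomalies : number of non-overlapping anomalous blobs to inject.
    anomaly_radius_range : (min, max) blob semi-axis, pixels.
    anomaly_intensity_shift : additive intensity offset of anomalous tissue.
    anatomy_seed : seed of the shared anatomy template; images with equal
        anatomy_seed depict "subjects" from the same population.
    seed : per-image RNG seed; identical specs give bit-identical images.
    """

    image_size: int = 256
    brain_axes: tuple[float, float] = (100.0, 80.0)
    texture_scale: float = 8.0
    texture_amplitude: float = 0.05
    base_intensity: float = 0.5
    tissue_contrast: float = 0.18
    variation_amplitude: float = 0.02
    skull: bool = False
    skull_width: float = 6.0
    skull_intensity: float = 0.95
    n_anomalies: int = 2
    anomaly_radius_range: tuple[float, float] = (8.0, 16.0)
    anomaly_intensity_shift: float = 0.3
    anatomy_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 128:
            raise ValueError("image_size must be >= 128")
        if self.n_anomalies < 0:
            raise ValueError("n_anomalies must be >= 0")
        lo, hi = self.anomaly_radius_range
        if not (0 < lo <= hi):
            raise ValueError("anomaly_radius_range must satisfy 0 < min <= max")
        if hi >= min(self.brain_axes):
            raise ValueError("anomaly radius range must lie within brain_axes")
        if max(self.brain_axes) >= self.image_size / 2:
            raise ValueError("brain_axes must fit inside the image")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], scale: float,
                  amplitude: float) -> np.ndarray:
    """Zero-mean Gaussian-blurred white noise rescaled to the given std."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    sd = field_.std()
    if sd == 0:  # pragma: no cover - only for pathological scales
        return np.zeros(shape)
    return field_ * (amplitude / sd)


def _place_anomaly(rng: np.random.Generator, spec: PhantomSpec, brain: np.ndarray,
                   occupied: np.ndarray, index: int,
                   coords: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """One jittered filled ellipse fully inside the brain, away from ``occupied``."""
    n = spec.image_size
    center = (n - 1) / 2.0
    a_brain, b_brain = spec.brain_axes
    rr, cc = coords
    for _ in range(200):
        r_a = rng.uniform(*spec.anomaly_radius_range)
        r_b = r_a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, np.pi)
        margin = r_a + 3.0
        cy = center + rng.uniform(-1, 1) * max(a_brain - margin, 1.0)
        cx = center + rng.uniform(-1, 1) * max(b_brain - margin, 1.0)
        dr, dc = rr - cy, cc - cx
        u = np.cos(theta) * dr + np.sin(theta) * dc
        v = -np.sin(theta) * dr + np.cos(theta) * dc
        quad = (u / r_a) ** 2 + (v / r_b) ** 2
        jitter = _smooth_noise(rng, (n, n), 4.0, 0.12)
        mask = (quad + jitter) <= 1.0
        # keep one connected blob around the center, holes filled
        labels, nlab = ndimage.label(mask)
        if nlab == 0:
            continue
        lab_center = labels[int(round(cy)), int(round(cx))]
        if lab_center == 0:
            continue
        mask = ndimage.binary_fill_holes(labels == lab_center)
        if mask.sum() < 16:
            continue
        if (mask & ~brain).any() or (mask & occupied).any():
            continue
        return mask
    raise PlacementError(
        f"could not place anomaly {index} inside the brain after 200 attempts"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, np.ndarray]:
    """Generate one phantom slice and its ground-truth anomaly mask.

    Returns
    -------
    image : Image2D with ``brain_mask`` set (skull excluded from the mask).
    ground_truth : boolean array marking exactly the injected anomaly pixels;
        its connected-component count equals ``spec.n_anomalies``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    center = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    a, b = spec.brain_axes
    ellipse = ((rr - center) / a) ** 2 + ((cc - center) / b) ** 2
    brain = ellipse <= 1.0

    # shared anatomy: two-class tissue map with partial-volume boundaries,
    # plus a fine shared texture (both from anatomy_seed)
    rng_anat = np.random.default_rng(spec.anatomy_seed)
    tissue_field = _smooth_noise(rng_anat, (n, n), spec.texture_scale, 1.0)
    tissue = ndimage.gaussian_filter(
        (tissue_field > 0).astype(np.float64) - 0.5, 1.5) * spec.tissue_contrast
    fine = _smooth_noise(rng_anat, (n, n), max(2.0, spec.texture_scale / 2.0),
                         spec.texture_amplitude)
    # per-image smooth variation (from the image seed)
    variation = _smooth_noise(rng, (n, n), spec.texture_scale,
                              spec.variation_amplitude)
    pixels = np.zeros((n, n))
    pixels[brain] = (spec.base_intensity + tissue[brain] + fine[brain]
                     + variation[brain])

    if spec.skull:
        outer = ((rr - center) / (a + spec.skull_width)) ** 2 + (
            (cc - center) / (b + spec.skull_width)
        ) ** 2 <= 1.0
        pixels[outer & ~brain] = spec.skull_intensity

    ground_truth = np.zeros((n, n), dtype=bool)
    occupied = np.zeros((n, n), dtype=bool)
    for k in range(spec.n_anomalies):
        blob = _place_anomaly(rng, spec, brain, occupied, k, (rr, cc))
        local = _smooth_noise(rng, (n, n), max(2.0, spec.texture_scale / 2.0),
                              spec.texture_amplitude)
        pixels[blob] = spec.base_intensity + spec.anomaly_intensity_shift + local[blob]
        ground_truth |= blob
        # 3-pixel exclusion zone keeps components separated
        occupied |= ndimage.binary_dilation(blob, iterations=3)

    pixels = np.clip(pixels, 0.0, 1.0)
    return Image2D(pixels, brain_mask=brain), ground_truth


def generate_corpus(spec: PhantomSpec, n_normal: int, n_anomalous: int,
                    seed: int) -> list[tuple[Image2D, np.ndarray]]:
    """Deterministic corpus: ``n_normal`` anomaly-free images followed by
    ``n_anomalous`` images with at least one anomaly.

    Per-image seeds are ``seed + image_index`` so the corpus is reproducible
    and individual images can be regenerated in isolation.
    """
    if n_normal < 0 or n_anomalous < 0:
        raise ValueError("corpus counts must be >= 0")
    out: list[tuple[Image2D, np.ndarray]] = []
    for i in range(n_normal):
        out.append(generate_phantom(replace(spec, seed=seed + i, n_anomalies=0)))
    for j in range(n_anomalous):
        s = replace(spec, seed=seed + n_normal + j,
                    n_anomalies=max(1, spec.n_anomalies))
        out.append(generate_phantom(s))
    return out
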