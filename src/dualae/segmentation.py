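"""Image reconstruction from optimized latents and residual-based segmentation.

Inference pipeline per image: extract directional patches, normalize,
encode with the horizontal/vertical autoencoders, run the auxiliary
encoder, fuse/optimize the latents by truncated SVD, decode, denormalize,
reassemble both orientations and average them. Anomalies are then segmented
by binarizing the input/reconstruction difference (or the class-map
disagreement of their mean-grey-level binarizations), followed by area
filtering, hole filling and connected-component analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from . import autoencoder as ae
from . import latent_fusion as lf
from . import patches as pt
from .errors import ConfigurationError
from .phantom import Image2D

__all__ = [
    "ModelBundle", "SegmentConfig", "SegmentationResult",
    "reconstruct_image", "residual_mask", "postprocess", "segment",
    "default_min_area",
]


@dataclass
class ModelBundle:
    """Everything needed for inference: the two primary autoencoders, the
    auxiliary autoencoder, the shared normalization, the anchor stride, the
    fusion options and (for corpus-basis fusion) the fitted fusion factors."""

    h_model: ae.AutoencoderModel
    v_model: ae.AutoencoderModel
    aux_model: ae.AutoencoderModel | None
    norm: pt.NormStats
    stride: int = 16
    fusion: lf.FusionConfig = field(default_factory=lf.FusionConfig)
    corpus_fusion: lf.FusedLatent | None = None
    train_config: ae.TrainConfig | None = None
    #: binarization level for the residual image, calibrated on the normal
    #: training corpus (mean + k*std of pooled within-brain residuals);
    #: None -> fall back to the per-image average grey level of the residual
    residual_threshold: float | None = None

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ae.save_model(self.h_model, d / "horizontal.ae", self.train_config)
        ae.save_model(self.v_model, d / "vertical.ae", self.train_config)
        if self.aux_model is not None:
            ae.save_model(self.aux_model, d / "auxiliary.ae", self.train_config)
        manifest = {
            "format_version": 1,
            "stride": self.stride,
            "norm": {
                "mean": self.norm.mean, "std": self.norm.std,
                "s_lo": self.norm.s_lo, "s_hi": self.norm.s_hi,
                "range_lo": self.norm.range_lo, "range_hi": self.norm.range_hi,
            },
            "fusion": {
                "rank": self.fusion.rank,
                "energy_threshold": self.fusion.energy_threshold,
                "enable_aux": self.fusion.enable_aux,
                "enable_align": self.fusion.enable_align,
                "enable_svd": self.fusion.enable_svd,
                "basis": self.fusion.basis,
            },
            "has_aux": self.aux_model is not None,
            "has_corpus_fusion": self.corpus_fusion is not None,
            "residual_threshold": self.residual_threshold,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if self.corpus_fusion is not None:
            cf = self.corpus_fusion
            np.savez(d / "corpus_fusion.npz",
                     S_r=cf.S_r, V_r=cf.V_r, col_means=cf.col_means,
                     singular_values=cf.singular_values,
                     rank=np.array(cf.rank),
                     energy_fraction=np.array(cf.energy_fraction),
                     block_widths=np.array(cf.block_widths))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        h_model, cfg = ae.load_model(d / "horizontal.ae")
        v_model, _ = ae.load_model(d / "vertical.ae")
        aux_model = None
        if manifest["has_aux"]:
            aux_model, _ = ae.load_model(d / "auxiliary.ae")
        norm = pt.NormStats(**manifest["norm"])
        fusion = lf.FusionConfig(**manifest["fusion"])
        corpus_fusion = None
        if manifest["has_corpus_fusion"]:
            with np.load(d / "corpus_fusion.npz") as z:
                corpus_fusion = lf.FusedLatent(
                    U_r=None, S_r=z["S_r"], V_r=z["V_r"],
                    col_means=z["col_means"],
                    singular_values=z["singular_values"],
                    rank=int(z["rank"]),
                    energy_fraction=float(z["energy_fraction"]),
                    block_widths=tuple(int(w) for w in z["block_widths"]),
                )
        return cls(h_model=h_model, v_model=v_model, aux_model=aux_model,
                   norm=norm, stride=manifest["stride"], fusion=fusion,
                   corpus_fusion=corpus_fusion, train_config=cfg,
                   residual_threshold=manifest.get("residual_threshold"))


@dataclass(frozen=True)
class SegmentConfig:
    """Post-reconstruction segmentation options."""

    min_area: int | None = None     # None -> scaled default (64 px at 256x256)
    connectivity: int = 8           # 4 or 8
    mode: str = "residual"          # "residual" | "xor" | "bright"
    #: shrink the brain mask by this many pixels before thresholding;
    #: reconstruction error is concentrated at the high-contrast brain
    #: boundary (the skull-stripping edge, a known trouble spot for
    #: reconstruction-based detectors), and excluding a thin rim avoids
    #: spurious boundary detections
    boundary_erosion: int = 6

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.mode not in ("residual", "xor", "bright"):
            raise ValueError("mode must be 'residual', 'xor' or 'bright'")
        if self.boundary_erosion < 0:
            raise ValueError("boundary_erosion must be >= 0")
        if self.min_area is not None and self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass
class SegmentationResult:
    """Reconstruction, residual map, final anomaly mask and component table."""

    reconstruction: Image2D
    residual: np.ndarray
    binary_mask: np.ndarray
    components: list[dict]
    params_used: dict


def default_min_area(image_shape: tuple[int, int]) -> int:
    """64 px at 256x256, scaled with image area."""
    rows, cols = image_shape
    return max(1, int(round(64.0 * (rows * cols) / (256.0 * 256.0))))


def _latents(image: Image2D, bundle: ModelBundle):
    grid = pt.build_grid(image.shape, bundle.stride)
    ph = pt.normalize(pt.extract(image, grid, pt.HORIZONTAL), bundle.norm)
    pv = pt.normalize(pt.extract(image, grid, pt.VERTICAL), bundle.norm)
    z_h = ae.encode(bundle.h_model, ph.data)
    z_v = ae.encode(bundle.v_model, pv.data)
    return grid, ph, pv, lf.PairedLatents(anchors=grid.anchors, Z_h=z_h, Z_v=z_v)


def reconstruct_image(image: Image2D, bundle: ModelBundle,
                      return_parts: bool = False):
    """Reconstruct one image through the full fusion pipeline.

    With ``return_parts=True`` also returns a dict of intermediates
    (normalized patch matrices, latents, decoded patch matrices, per-stage
    losses) for inspection and patch-level scoring.
    """
    if bundle.h_model.n_inputs != pt.PATCH_LEN or bundle.v_model.n_inputs != pt.PATCH_LEN:
        raise ConfigurationError("primary autoencoders must accept 1024-length patches")
    grid, ph, pv, paired = _latents(image, bundle)
    fusion = bundle.fusion
    cfg = bundle.train_config if bundle.train_config is not None else ae.TrainConfig()

    z_prime = None
    l_aux_enc = l_align = float("nan")
    if fusion.enable_aux and bundle.aux_model is not None:
        z_prime, l_aux_enc, l_align = lf.auxiliary_encode(
            paired, bundle.aux_model, cfg, align=fusion.enable_align)

    l_svd = 0.0
    if fusion.enable_svd:
        if fusion.basis == "corpus" and bundle.corpus_fusion is not None:
            zh_opt, zv_opt = lf.project_fusion(bundle.corpus_fusion, paired, z_prime)
            l_svd = bundle.corpus_fusion.truncation_error
        else:
            fused = lf.svd_fuse(paired, z_prime, rank=fusion.rank,
                                energy_threshold=fusion.energy_threshold)
            zh_opt, zv_opt = lf.invert_fusion(fused)
            l_svd = fused.truncation_error
    else:
        zh_opt, zv_opt = paired.Z_h, paired.Z_v

    xh_hat = ae.decode(bundle.h_model, zh_opt)
    xv_hat = ae.decode(bundle.v_model, zv_opt)
    rec_h, _ = pt.reassemble(bundle.norm.inverse(xh_hat), grid, pt.HORIZONTAL)
    rec_v, _ = pt.reassemble(bundle.norm.inverse(xv_hat), grid, pt.VERTICAL)
    pixels = np.clip(0.5 * (rec_h.pixels + rec_v.pixels), 0.0, 1.0)
    reconstruction = Image2D(pixels, brain_mask=image.brain_mask)
    if not return_parts:
        return reconstruction

    domain = image.domain()
    parts = {
        "grid": grid,
        "X_h": ph.data, "X_v": pv.data,
        "Z_h": paired.Z_h, "Z_v": paired.Z_v, "Z_prime": z_prime,
        "Zh_opt": zh_opt, "Zv_opt": zv_opt,
        "Xh_hat": xh_hat, "Xv_hat": xv_hat,
        "patch_l1_h": np.mean(np.abs(ph.data - xh_hat), axis=1),
        "patch_l1_v": np.mean(np.abs(pv.data - xv_hat), axis=1),
        "losses": {
            "L_enc_h": ae.loss(bundle.h_model, ph.data, cfg).total,
            "L_enc_v": ae.loss(bundle.v_model, pv.data, cfg).total,
            "L_aux_rec_h": float(np.mean(np.sum((xh_hat - ph.data) ** 2, axis=1))),
            "L_aux_rec_v": float(np.mean(np.sum((xv_hat - pv.data) ** 2, axis=1))),
            "L_aux_enc": l_aux_enc,
            "L_svd": l_svd,
            "L_rec": float(np.mean(np.abs(image.pixels - pixels)[domain])),
            "L_align": l_align,
        },
    }
    return reconstruction, parts


def residual_mask(image: Image2D, reconstruction: Image2D,
                  brain_mask: np.ndarray | None = None,
                  mode: str = "residual",
                  threshold: float | None = None) -> np.ndarray:
    """Candidate anomaly pixels from binarization and image subtraction.

    ``"residual"`` (default): subtract the reconstruction from the input and
    convert the absolute difference image to binary. The binarization level
    is ``threshold`` when given (normally the level calibrated on the normal
    training corpus, see :class:`ModelBundle`), else the difference image's
    average grey level over the brain mask. This is the reading of
    binarization-plus-image-subtraction under which anomalies are detected
    regardless of which tissue class they overlap; an anomaly over bright
    tissue never flips its mean-threshold class, so the class-map readings
    below cannot see it.

    ``"xor"`` / ``"bright"``: threshold the input and the reconstruction at
    their own mean grey levels first, then take the pixel-wise disagreement
    of the two class maps ("xor"), or only pixels bright in the input and
    not in the reconstruction ("bright").

    All modes intersect the candidate mask with the brain mask.
    """
    domain = brain_mask if brain_mask is not None else image.domain()
    domain = np.asarray(domain, dtype=bool)
    if mode == "residual":
        diff = np.abs(image.pixels - reconstruction.pixels)
        level = threshold if threshold is not None else diff[domain].mean()
        cand = diff > level
    elif mode in ("xor", "bright"):
        b_in = image.pixels > image.pixels[domain].mean()
        b_rec = reconstruction.pixels > reconstruction.pixels[domain].mean()
        cand = (b_in ^ b_rec) if mode == "xor" else (b_in & ~b_rec)
    else:
        raise ValueError("mode must be 'residual', 'xor' or 'bright'")
    return cand & domain


def postprocess(candidate: np.ndarray, min_area: int = 64,
                connectivity: int = 8,
                residual: np.ndarray | None = None,
                ) -> tuple[np.ndarray, list[dict]]:
    """Area filtering, hole filling and connected-component bookkeeping.

    Components smaller than ``min_area`` are dropped first, then holes in
    the survivors are filled (so filled specks cannot sneak past the area
    filter). Returns the final mask and one record per component with its
    label, area, bounding box and mean residual (NaN when no residual map
    is supplied).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 2 if connectivity == 8 else 1
    candidate = np.asarray(candidate, dtype=bool)
    labels = measure.label(candidate, connectivity=conn)
    keep = np.zeros_like(candidate)
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            keep[labels == region.label] = True
    filled = ndimage.binary_fill_holes(keep)
    final_labels = measure.label(filled, connectivity=conn)
    components = []
    for region in measure.regionprops(final_labels):
        region_mask = final_labels == region.label
        mean_res = (float(np.mean(residual[region_mask]))
                    if residual is not None else float("nan"))
        components.append({
            "label": int(region.label),
            "area": int(region.area),
            "bbox": tuple(int(v) for v in region.bbox),
            "mean_residual": mean_res,
        })
    return filled, components


def eroded_domain(domain: np.ndarray, erosion: int) -> np.ndarray:
    """Brain mask shrunk by ``erosion`` pixels (no-op for erosion 0)."""
    domain = np.asarray(domain, dtype=bool)
    if erosion <= 0:
        return domain
    return ndimage.binary_erosion(domain, iterations=erosion)


def segment(image: Image2D, bundle: ModelBundle,
            config: SegmentConfig | None = None) -> SegmentationResult:
    """Full segmentation: reconstruct, compare, post-process."""
    config = config if config is not None else SegmentConfig()
    reconstruction = reconstruct_image(image, bundle)
    domain = image.domain()
    seg_domain = eroded_domain(domain, config.boundary_erosion)
    residual = np.abs(image.pixels - reconstruction.pixels)
    residual[~domain] = 0.0
    threshold = (bundle.residual_threshold if config.mode == "residual"
                 else None)
    candidate = residual_mask(image, reconstruction, seg_domain,
                              mode=config.mode, threshold=threshold)
    min_area = (config.min_area if config.min_area is not None
                else default_min_area(image.shape))
    mask, components = postprocess(candidate, min_area=min_area,
                                   connectivity=config.connectivity,
                                   residual=residual)
    mask &= seg_domain
    return SegmentationResult(
        reconstruction=reconstruction,
        residual=residual,
        binary_mask=mask,
        components=components,
        params_used={
            "min_area": min_area,
            "connectivity": config.connectivity,
            "mode": config.mode,
            "boundary_erosion": config.boundary_erosion,
            "threshold": threshold,
            "fusion": bundle.fusion,
        },
    )
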