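"""Model/Results interface over the full pipeline.

`DualAutoencoder` bundles the training corpus and hyperparameters;
`fit()` trains the horizontal, vertical and auxiliary autoencoders, fits
the global patch normalization and the corpus-level SVD fusion factors, and
returns a `DualAutoencoderResults` carrying the trained `ModelBundle`,
per-stage loss histories, diagnostics, a `summary()` table, and inference
methods (`reconstruct`, `segment`, `evaluate`, `plot_segmentation`).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import autoencoder as ae
from . import latent_fusion as lf
from . import metrics as mx
from . import patches as pt
from . import segmentation as sg
from .phantom import Image2D

__all__ = ["DualAutoencoder", "DualAutoencoderResults"]


class DualAutoencoder:
    """Dual directional sparse autoencoder with SVD latent fusion.

    Parameters
    ----------
    images : training images (normal appearance only); anomalous content in
        the training set weakens the anomaly-detection premise.
    stride : anchor stride of the shared patch grid, pixels.
    hidden_size : hidden width of each primary autoencoder (typical
        widths: 64, 128 or 256).
    train_config : SGD hyperparameters shared by all three autoencoders;
        its seed is the master seed from which per-network seeds derive.
    aux_epochs : epochs for the auxiliary autoencoder (defaults to the
        primary epoch count).
    fusion : fusion-stage options (rank policy, corpus/image basis, ablation
        switches).
    """

    def __init__(self, images: list[Image2D], stride: int = 16,
                 hidden_size: int = 128,
                 train_config: ae.TrainConfig | None = None,
                 aux_epochs: int | None = None,
                 fusion: lf.FusionConfig | None = None,
                 residual_sigma: float = 3.0,
                 boundary_erosion: int = 6):
        if not images:
            raise ValueError("at least one training image required")
        self.images = list(images)
        self.stride = stride
        self.hidden_size = hidden_size
        self.train_config = train_config if train_config is not None else ae.TrainConfig()
        self.aux_epochs = aux_epochs
        self.fusion = fusion if fusion is not None else lf.FusionConfig()
        # residual binarization level = mean + residual_sigma * std of the
        # pooled within-brain training residuals (three-sigma rule)
        self.residual_sigma = residual_sigma
        self.boundary_erosion = boundary_erosion

    @classmethod
    def from_corpus(cls, corpus: list[tuple[Image2D, np.ndarray]],
                    **kwargs) -> "DualAutoencoder":
        """Build from a phantom corpus of (image, truth-mask) pairs,
        keeping only anomaly-free images for training."""
        images = [img for img, truth in corpus if not np.asarray(truth).any()]
        return cls(images, **kwargs)

    # ------------------------------------------------------------------
    def _training_matrices(self):
        sets_h, sets_v = [], []
        for img in self.images:
            grid = pt.build_grid(img.shape, self.stride)
            sets_h.append(pt.extract(img, grid, pt.HORIZONTAL))
            sets_v.append(pt.extract(img, grid, pt.VERTICAL))
        norm = pt.fit_norm(sets_h + sets_v)
        X_h = np.vstack([pt.normalize(p, norm).data for p in sets_h])
        X_v = np.vstack([pt.normalize(p, norm).data for p in sets_v])
        return norm, X_h, X_v

    def fit(self, verbose: bool = False) -> "DualAutoencoderResults":
        """Stagewise training: primary autoencoders, auxiliary autoencoder
        on the paired latents, then the corpus fusion basis."""
        cfg = self.train_config
        norm, X_h, X_v = self._training_matrices()
        # independent seeds per network, derived from the master seed
        cfg_h = replace(cfg, seed=cfg.seed)
        cfg_v = replace(cfg, seed=cfg.seed + 1)
        aux_cfg = replace(cfg, seed=cfg.seed + 2,
                          max_epochs=self.aux_epochs or cfg.max_epochs)
        if verbose:
            print(f"training horizontal autoencoder on {X_h.shape[0]} patches")
        h_model, hist_h = ae.train(X_h, cfg_h, hidden_size=self.hidden_size)
        if verbose:
            print(f"training vertical autoencoder on {X_v.shape[0]} patches")
        v_model, hist_v = ae.train(X_v, cfg_v, hidden_size=self.hidden_size)

        paired = lf.PairedLatents(anchors=None,
                                  Z_h=ae.encode(h_model, X_h),
                                  Z_v=ae.encode(v_model, X_v))
        aux_model = hist_aux = None
        z_prime = None
        if self.fusion.enable_aux:
            concat = np.hstack([paired.Z_h, paired.Z_v])
            if verbose:
                print(f"training auxiliary autoencoder on {concat.shape[0]} latent pairs")
            aux_model, hist_aux = ae.train(concat, aux_cfg,
                                           hidden_size=self.hidden_size)
            z_prime, _, _ = lf.auxiliary_encode(paired, aux_model, aux_cfg,
                                                align=self.fusion.enable_align)
        corpus_fusion = None
        if self.fusion.enable_svd:
            corpus_fusion = lf.svd_fuse(paired, z_prime,
                                        rank=self.fusion.rank,
                                        energy_threshold=self.fusion.energy_threshold)
        bundle = sg.ModelBundle(h_model=h_model, v_model=v_model,
                                aux_model=aux_model, norm=norm,
                                stride=self.stride, fusion=self.fusion,
                                corpus_fusion=corpus_fusion,
                                train_config=cfg)
        bundle.residual_threshold = self._calibrate_threshold(bundle, verbose)
        return DualAutoencoderResults(
            model=self, bundle=bundle,
            loss_history={"horizontal": hist_h, "vertical": hist_v,
                          "auxiliary": hist_aux},
            n_patches=X_h.shape[0],
        )


    def _calibrate_threshold(self, bundle: sg.ModelBundle,
                             verbose: bool = False) -> float:
        """Binarization level for the residual image, from the normal
        training corpus: mean + residual_sigma * std of all within-brain
        residuals (brain mask eroded as at inference)."""
        pooled = []
        for img in self.images:
            rec = sg.reconstruct_image(img, bundle)
            dom = sg.eroded_domain(img.domain(), self.boundary_erosion)
            pooled.append(np.abs(img.pixels - rec.pixels)[dom])
        pooled = np.concatenate(pooled)
        threshold = float(pooled.mean() + self.residual_sigma * pooled.std())
        if verbose:
            print(f"residual threshold calibrated at {threshold:.4f} "
                  f"(mean {pooled.mean():.4f} + {self.residual_sigma} * "
                  f"std {pooled.std():.4f})")
        return threshold


class DualAutoencoderResults:
    """Fitted pipeline: trained weights, training diagnostics, inference."""

    def __init__(self, model: DualAutoencoder, bundle: sg.ModelBundle,
                 loss_history: dict, n_patches: int):
        self.model = model
        self.bundle = bundle
        self.loss_history = loss_history
        self.n_patches = n_patches

    # -- inference ------------------------------------------------------
    def reconstruct(self, image: Image2D, return_parts: bool = False):
        return sg.reconstruct_image(image, self.bundle, return_parts=return_parts)

    def segment(self, image: Image2D,
                config: sg.SegmentConfig | None = None) -> sg.SegmentationResult:
        return sg.segment(image, self.bundle, config)

    def evaluate(self, pairs: list[tuple[Image2D, np.ndarray]],
                 config: sg.SegmentConfig | None = None) -> dict:
        """Segment every (image, truth) pair and report per-image and mean
        DSC/PPV/Sensitivity plus pooled pixel-score AUC."""
        per_image = []
        all_scores, all_truth = [], []
        for image, truth in pairs:
            truth = np.asarray(truth, dtype=bool)
            res = self.segment(image, config)
            dom = image.domain()
            c = mx.confusion(res.binary_mask, truth, dom)
            row = {"dsc": mx.dsc(c), "tp": c.TP, "fp": c.FP, "fn": c.FN,
                   "tn": c.TN,
                   "fp_area_fraction": c.FP / max(1, int(dom.sum()))}
            if truth.any():
                row["ppv"] = mx.ppv(c)
                row["sensitivity"] = mx.sensitivity(c)
                all_scores.append(res.residual[dom])
                all_truth.append(truth[dom])
            per_image.append(row)
        out = {"per_image": per_image,
               "mean_dsc": float(np.mean([r["dsc"] for r in per_image]))}
        with_truth = [r for r in per_image if "ppv" in r]
        if with_truth:
            out["mean_ppv"] = float(np.nanmean([r["ppv"] for r in with_truth]))
            out["mean_sensitivity"] = float(
                np.nanmean([r["sensitivity"] for r in with_truth]))
            out["pixel_auc"] = mx.auc(np.concatenate(all_scores),
                                      np.concatenate(all_truth))
        normals = [r for r in per_image if "ppv" not in r]
        if normals:
            out["mean_fp_area_fraction_normals"] = float(
                np.mean([r["fp_area_fraction"] for r in normals]))
        return out

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        b = self.bundle
        lines = [
            "Dual sparse autoencoder with SVD latent fusion",
            "=" * 52,
            f"training images        : {len(self.model.images)}",
            f"patches per orientation: {self.n_patches}",
            f"anchor stride          : {b.stride}",
            f"hidden units           : {b.h_model.hidden_size}",
            f"normalization          : mean={b.norm.mean:.4f} std={b.norm.std:.4f} "
            f"-> [{b.norm.range_lo}, {b.norm.range_hi}]",
        ]
        for name in ("horizontal", "vertical", "auxiliary"):
            hist = self.loss_history.get(name)
            if hist:
                lines.append(
                    f"{name:<10} loss        : {hist[0]:.4f} -> {hist[-1]:.4f} "
                    f"({len(hist)} epochs)")
        if b.corpus_fusion is not None:
            cf = b.corpus_fusion
            lines.append(
                f"fusion basis           : rank {cf.rank} of width "
                f"{cf.V_r.shape[0]} (energy {cf.energy_fraction:.3f})")
        else:
            lines.append("fusion basis           : disabled")
        if b.residual_threshold is not None:
            lines.append(f"residual threshold     : {b.residual_threshold:.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        self.bundle.save(directory)

    # -- plotting -------------------------------------------------------
    def plot_segmentation(self, image: Image2D, truth: np.ndarray | None = None,
                          config: sg.SegmentConfig | None = None):
        """Input / reconstruction / residual / final-mask panel figure."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        res = self.segment(image, config)
        panels = [(image.pixels, "input"),
                  (res.reconstruction.pixels, "reconstruction"),
                  (res.residual, "residual"),
                  (res.binary_mask, "segmentation")]
        if truth is not None:
            panels.append((np.asarray(truth, dtype=bool), "ground truth"))
        fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3.2))
        for ax, (img, title) in zip(np.atleast_1d(axes), panels):
            ax.imshow(img, cmap="gray", interpolation="nearest")
            ax.set_title(title)
            ax.axis("off")
        fig.tight_layout()
        return fig
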