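"""Auxiliary encoding of paired latents and SVD-based low-rank fusion.

The horizontal and vertical autoencoders produce one latent vector each per
anchor. An auxiliary autoencoder over the concatenated pair supplies a
supporting representation Z' that reduces the discrepancy between the two
latent spaces. The stacked matrix F = [Z_h | Z_v | Z'] is column-centered
and truncated by SVD at a rank chosen either explicitly or by retained
squared-singular-value energy; by the Eckart-Young theorem this is the
least-squares-optimal low-rank representation. Inverting the truncation
(or projecting new latents onto the retained subspace) moves latent vectors
toward the subspace spanned by normal appearance, which is what suppresses
anomalies in the final reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import AutoencoderModel, TrainConfig, encode, loss
from .errors import ConfigurationError, DegenerateDataError, RankError

__all__ = [
    "PairedLatents", "FusedLatent", "FusionConfig",
    "auxiliary_encode", "svd_fuse", "invert_fusion", "project_fusion",
    "total_loss",
]

logger = logging.getLogger(__name__)

_CLIP_EPS = 1e-7  # keep inverted latents strictly inside (0, 1)


@dataclass
class PairedLatents:
    """Row-aligned horizontal/vertical latents on a shared anchor list."""

    anchors: np.ndarray  # (n, 2) grid anchors
    Z_h: np.ndarray      # (n, d_h)
    Z_v: np.ndarray      # (n, d_v)

    def __post_init__(self) -> None:
        self.Z_h = np.atleast_2d(np.asarray(self.Z_h, dtype=np.float64))
        self.Z_v = np.atleast_2d(np.asarray(self.Z_v, dtype=np.float64))
        if self.Z_h.shape[0] != self.Z_v.shape[0]:
            raise ValueError("Z_h and Z_v must have equal row counts")
        if self.anchors is not None and len(self.anchors) != self.Z_h.shape[0]:
            raise ValueError("one latent row per anchor required")


@dataclass(frozen=True)
class FusionConfig:
    """Options of the fusion stage.

    ``rank`` fixes the truncation rank; when None, the smallest rank whose
    retained energy fraction reaches ``energy_threshold`` is used.
    ``basis`` selects whether the SVD basis is fitted on the training corpus
    (and new latents are projected onto it) or refitted per image.
    """

    rank: int | None = None
    energy_threshold: float = 0.95
    enable_aux: bool = True
    enable_align: bool = True
    enable_svd: bool = True
    basis: str = "corpus"  # "corpus" | "image"

    def __post_init__(self) -> None:
        if not 0 < self.energy_threshold <= 1:
            raise ValueError("energy_threshold must lie in (0, 1]")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.basis not in ("corpus", "image"):
            raise ValueError("basis must be 'corpus' or 'image'")


@dataclass
class FusedLatent:
    """Truncated SVD of the column-centered stacked latent matrix."""

    U_r: np.ndarray | None      # (n, r); None when loaded without scores
    S_r: np.ndarray             # (r,)
    V_r: np.ndarray             # (width, r), orthonormal columns
    col_means: np.ndarray       # (width,)
    singular_values: np.ndarray  # full spectrum
    rank: int
    energy_fraction: float
    block_widths: tuple[int, int, int]  # (d_h, d_v, d_aux); d_aux may be 0

    @property
    def truncation_error(self) -> float:
        """Frobenius error of the rank-r approximation: sqrt(sum_{i>r} s_i^2)."""
        return float(np.sqrt(np.sum(self.singular_values[self.rank:] ** 2)))


def auxiliary_encode(paired: PairedLatents, aux_model: AutoencoderModel,
                     config: TrainConfig | None = None, align: bool = True,
                     ) -> tuple[np.ndarray, float, float]:
    """Auxiliary latents over concatenated [z_h || z_v] pairs.

    Returns (Z_prime, L_aux_enc, L_align): the auxiliary latent matrix, the
    auxiliary autoencoder's sparse-MSE loss on the concatenated vectors, and
    the mean l1 distance between the two latent spaces (NaN when alignment
    is disabled).
    """
    concat = np.hstack([paired.Z_h, paired.Z_v])
    if aux_model.n_inputs != concat.shape[1]:
        raise ConfigurationError(
            f"auxiliary model expects {aux_model.n_inputs} inputs, "
            f"latent pair width is {concat.shape[1]}"
        )
    z_prime = encode(aux_model, concat)
    cfg = config if config is not None else TrainConfig()
    l_aux_enc = loss(aux_model, concat, cfg).total
    if align:
        if paired.Z_h.shape[1] != paired.Z_v.shape[1]:
            raise ConfigurationError(
                "latent alignment requires equal horizontal/vertical widths "
                f"({paired.Z_h.shape[1]} != {paired.Z_v.shape[1]})"
            )
        l_align = float(np.mean(np.abs(paired.Z_h - paired.Z_v)))
    else:
        l_align = float("nan")
    return z_prime, l_aux_enc, l_align


def _stack(paired: PairedLatents, z_prime: np.ndarray | None) -> tuple[np.ndarray, tuple[int, int, int]]:
    blocks = [paired.Z_h, paired.Z_v]
    d_a = 0
    if z_prime is not None:
        z_prime = np.atleast_2d(np.asarray(z_prime, dtype=np.float64))
        blocks.append(z_prime)
        d_a = z_prime.shape[1]
    return np.hstack(blocks), (paired.Z_h.shape[1], paired.Z_v.shape[1], d_a)


def svd_fuse(paired: PairedLatents, z_prime: np.ndarray | None = None,
             rank: int | None = None, energy_threshold: float = 0.95,
             ) -> FusedLatent:
    """Column-center F = [Z_h | Z_v | Z'] and truncate its SVD.

    The rank is ``rank`` when given, otherwise the smallest r whose retained
    energy fraction (sum of the top-r squared singular values over the total)
    reaches ``energy_threshold``.
    """
    F, widths = _stack(paired, z_prime)
    n = F.shape[0]
    if n < 2:
        raise ValueError("fusion requires at least 2 anchors")
    col_means = F.mean(axis=0)
    Fc = F - col_means
    U, S, Vt = np.linalg.svd(Fc, full_matrices=False)
    total_energy = float(np.sum(S ** 2))
    if total_energy == 0.0:
        raise DegenerateDataError("all-constant latent matrix; nothing to fuse")
    max_rank = min(F.shape)
    if rank is not None:
        if rank > max_rank:
            raise RankError(f"rank {rank} exceeds min(n, width) = {max_rank}")
        r = rank
    else:
        cum = np.cumsum(S ** 2) / total_energy
        r = int(np.searchsorted(cum, energy_threshold) + 1)
        r = min(r, max_rank)
    energy_fraction = float(np.sum(S[:r] ** 2) / total_energy)
    return FusedLatent(
        U_r=U[:, :r], S_r=S[:r], V_r=Vt[:r].T, col_means=col_means,
        singular_values=S, rank=r, energy_fraction=energy_fraction,
        block_widths=widths,
    )


def _split_blocks(F_hat: np.ndarray, widths: tuple[int, int, int]
                  ) -> tuple[np.ndarray, np.ndarray]:
    d_h, d_v, _ = widths
    z_h = np.clip(F_hat[:, :d_h], _CLIP_EPS, 1 - _CLIP_EPS)
    z_v = np.clip(F_hat[:, d_h:d_h + d_v], _CLIP_EPS, 1 - _CLIP_EPS)
    return z_h, z_v


def invert_fusion(fused: FusedLatent) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the low-rank latent matrix and return the optimized
    horizontal/vertical blocks, clipped into (0, 1) for the sigmoid decoders."""
    if fused.U_r is None:
        raise ValueError("fusion factors were saved without row scores (U_r)")
    F_hat = fused.U_r * fused.S_r @ fused.V_r.T + fused.col_means
    return _split_blocks(F_hat, fused.block_widths)


def project_fusion(fused: FusedLatent, paired: PairedLatents,
                   z_prime: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Project new latents onto a previously fitted low-rank basis.

    Used when the fusion basis is learned on the normal training corpus:
    directions of variation absent from normal appearance are removed from
    the test image's latents.
    """
    F, widths = _stack(paired, z_prime)
    if F.shape[1] != fused.V_r.shape[0]:
        raise ConfigurationError(
            f"latent width {F.shape[1]} does not match fusion basis "
            f"width {fused.V_r.shape[0]}"
        )
    Fc = F - fused.col_means
    F_hat = (Fc @ fused.V_r) @ fused.V_r.T + fused.col_means
    return _split_blocks(F_hat, widths)


def total_loss(parts: dict[str, float]) -> float:
    """Overall loss: plain sum of the named stage losses (two encoder
    losses, two decoder-reconstruction losses, auxiliary encoder loss, SVD
    truncation loss, image reconstruction loss). Components are logged."""
    total = float(sum(parts.values()))
    logger.debug("total loss %.6g = %s", total,
                 " + ".join(f"{k}={v:.6g}" for k, v in parts.items()))
    return total
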