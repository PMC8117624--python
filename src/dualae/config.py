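"""Flat namespaced pipeline configuration (YAML file + CLI overrides).

Keys are ``section.option`` strings; unknown keys are rejected so typos
fail fast. The effective, defaults-merged configuration is echoed to the
log and written beside every run's outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, object] = {
    # phantom generator
    "phantom.image_size": 256,
    "phantom.brain_axes": [100.0, 80.0],
    "phantom.texture_scale": 8.0,
    "phantom.texture_amplitude": 0.08,
    "phantom.base_intensity": 0.5,
    "phantom.skull": False,
    "phantom.skull_width": 6.0,
    "phantom.skull_intensity": 0.95,
    "phantom.n_anomalies": 2,
    "phantom.anomaly_radius_range": [8.0, 16.0],
    "phantom.anomaly_intensity_shift": 0.3,
    # patch grid / normalization
    "patches.anchor_stride": 16,
    "patches.range_lo": 0.1,
    "patches.range_hi": 0.9,
    # autoencoder training
    "train.hidden_size": 128,
    "train.learning_rate": 0.001,
    "train.max_epochs": 4000,
    "train.batch_size": 256,
    "train.sparsity_regularization": 1.0,
    "train.sparsity_proportion": 0.05,
    "train.l2_regularization": 0.001,
    "train.lr_decay": 0.5,
    # latent fusion
    "fusion.rank": None,
    "fusion.energy_threshold": 0.95,
    "fusion.enable_aux": True,
    "fusion.enable_align": True,
    "fusion.enable_svd": True,
    "fusion.basis": "corpus",
    # segmentation
    "segment.min_area": None,
    "segment.connectivity": 8,
    "segment.mode": "residual",
    "segment.boundary_erosion": 6,
    "segment.residual_sigma": 3.0,
}


def load_config(path=None, overrides: dict[str, object] | None = None
                ) -> dict[str, object]:
    """Merge defaults <- YAML file <- explicit overrides; reject unknown keys."""
    cfg = dict(DEFAULTS)
    sources: list[dict[str, object]] = []
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a mapping")
        sources.append(loaded)
    if overrides:
        sources.append({k: v for k, v in overrides.items() if v is not None})
    for src in sources:
        unknown = set(src) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        cfg.update(src)
    return cfg


def echo_config(cfg: dict[str, object], out_dir=None) -> None:
    """Log the effective configuration and save it beside the outputs."""
    for key in sorted(cfg):
        logger.info("config %s = %r", key, cfg[key])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "effective_config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True))
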