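"""Single-file YAML configuration mirroring the framework's setting tables.

A config file has up to three sections::

    augmentation:            # preset name or per-transform settings
      preset: generic        # or explicit {rotation2d: {probability: .., range: [..]}, ...}
    training:                # TrainingConfig fields
      patch_size: 128
      learning_rate: 0.001
    postprocess:             # preset name or explicit class rules
      preset: pulmonary_tracheal
      # or: fill_holes: true / min_volume_ml: 0.1 /
      #     classes: {trachea: {threshold: 0.5, n_largest: 1, must_touch: parenchyma}}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .augment import PRESETS, AugmentationPolicy
from .network import TrainingConfig
from .postprocess import TABLE_PRESETS, ConfigurationError, PostProcessSpec


@dataclass
class RunConfig:
    augmentation: AugmentationPolicy
    training: TrainingConfig
    postprocess: PostProcessSpec | None


def _load_policy(section) -> AugmentationPolicy:
    if section is None:
        return PRESETS["generic"]()
    if isinstance(section, str):
        section = {"preset": section}
    preset = section.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigurationError(
                f"unknown augmentation preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        if section:
            raise ConfigurationError("augmentation preset and explicit settings are exclusive")
        return PRESETS[preset]()
    return AugmentationPolicy.from_dict(section)


def _load_postprocess(section) -> PostProcessSpec | None:
    if section is None:
        return None
    if isinstance(section, str):
        section = {"preset": section}
    preset = section.pop("preset", None)
    if preset is not None:
        if preset not in TABLE_PRESETS:
            raise ConfigurationError(
                f"unknown post-processing preset {preset!r}; choose from {sorted(TABLE_PRESETS)}"
            )
        return TABLE_PRESETS[preset]
    return PostProcessSpec.from_dict(section)


def load_config(path: str | Path) -> RunConfig:
    """Parse a run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    training = TrainingConfig(**(raw.get("training") or {}))
    return RunConfig(
        augmentation=_load_policy(raw.get("augmentation")),
        training=training,
        postprocess=_load_postprocess(raw.get("postprocess")),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    doc = {
        "augmentation": cfg.augmentation.to_dict(),
        "training": cfg.training.to_dict(),
        "postprocess": cfg.postprocess.to_dict() if cfg.postprocess else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


__all__ = ["RunConfig", "load_config", "save_config"]
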