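"""YAML configuration for pipeline runs.

The YAML mirrors the dataclass fields, e.g.::

    root_seed: 7
    cohort:
      n_training: 200
      n_patients: 70
      offset_mean_sd: [4.0, 2.0]
    phantom:
      grid_shape: [32, 32, 32]
    training:
      iterations: 150
    occlusion:
      mask_size: 8

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .attention import OcclusionConfig
from .model import ArchitectureSpec, ConvBlock, TrainingConfig
from .phantom import CognitionModel, CohortSpec, NfLModel, PhantomSpec
from .pipeline import RunConfig
from .stats import StratificationConfig

_SUBCONFIGS = {
    "cohort": CohortSpec,
    "phantom": PhantomSpec,
    "training": TrainingConfig,
    "architecture": ArchitectureSpec,
    "occlusion": OcclusionConfig,
    "stratification": StratificationConfig,
    "nfl_model": NfLModel,
    "cognition_model": CognitionModel,
}


def _build(cls, data: dict):
    if not isinstance(data, dict):
        raise TypeError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SUBCONFIGS and isinstance(value, dict):
            kwargs[key] = _build(_SUBCONFIGS[key], value)
        elif key == "conv_blocks":
            kwargs[key] = tuple(ConvBlock(*b) for b in value)
        elif key == "tissue_intensity_means":
            kwargs[key] = {int(k): float(v) for k, v in value.items()}
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data)
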