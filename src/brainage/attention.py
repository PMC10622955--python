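"""Occlusion-sensitivity attention maps for the age regressor.

A sliding mask (default 8x8x8 voxels) hides part of the input volume; the
attention weight of a mask placement is the absolute shift of the predicted
age it causes.  The map is the weight-combination of the binary masks --
each voxel accumulates the weights of every placement covering it, divided
by its coverage count when overlap normalization is on (with the default
non-overlapping stride the two conventions coincide).  Population maps are
voxelwise averages of subject maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AgeModel


def _as_triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError("expected a scalar or a length-3 tuple")
    return t


@dataclass(frozen=True)
class OcclusionConfig:
    """Sliding-mask protocol for occlusion sensitivity."""

    mask_size: tuple[int, int, int] | int = (8, 8, 8)
    stride: tuple[int, int, int] | int | None = None  # default: non-overlapping
    fill_value: float = 0.0
    normalize_overlap: bool = True

    def resolved(self, grid_shape: tuple[int, ...]) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        mask = _as_triple(self.mask_size)
        stride = mask if self.stride is None else _as_triple(self.stride)
        if any(s < 1 for s in stride):
            raise ValueError("stride must be >= 1")
        if any(m > g for m, g in zip(mask, grid_shape)):
            raise ValueError(f"mask {mask} larger than volume {tuple(grid_shape)}")
        return mask, stride


@dataclass
class AttentionMap:
    """Non-negative occlusion-weight grid (years of prediction shift per voxel)."""

    weights: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if (self.weights < 0).any():
            raise ValueError("attention weights must be non-negative")


def mask_placements(
    grid_shape: tuple[int, ...], config: OcclusionConfig
) -> list[tuple[slice, slice, slice]]:
    """The stride lattice of mask positions covering the volume."""
    mask, stride = config.resolved(grid_shape)
    axes = []
    for g, m, s in zip(grid_shape, mask, stride):
        starts = list(range(0, g - m + 1, s))
        # make sure the trailing edge is covered when stride does not tile exactly
        if starts[-1] + m < g:
            starts.append(g - m)
        axes.append(starts)
    return [
        (slice(i, i + mask[0]), slice(j, j + mask[1]), slice(l, l + mask[2]))
        for i in axes[0] for j in axes[1] for l in axes[2]
    ]


def occlusion_map(
    model: AgeModel,
    volume: np.ndarray,
    config: OcclusionConfig | None = None,
    subject_id: str = "",
    batch_size: int = 64,
) -> AttentionMap:
    """Occlusion-sensitivity map of one preprocessed volume.

    For every placement, weight = |predict(masked) - predict(original)|;
    the map sums weight * indicator(mask region), divided per voxel by its
    coverage count if ``normalize_overlap``.
    """
    config = config or OcclusionConfig()
    volume = np.asarray(volume, dtype=np.float32)
    placements = mask_placements(volume.shape, config)
    baseline = float(model.predict(volume[None])[0])

    weights = np.zeros(len(placements), dtype=np.float64)
    for start in range(0, len(placements), batch_size):
        chunk = placements[start:start + batch_size]
        batch = np.repeat(volume[None], len(chunk), axis=0)
        for b, sl in enumerate(chunk):
            batch[b][sl] = config.fill_value
        preds = model.predict(batch)
        weights[start:start + len(chunk)] = np.abs(preds - baseline)

    out = np.zeros(volume.shape, dtype=np.float64)
    coverage = np.zeros(volume.shape, dtype=np.int64)
    for w, sl in zip(weights, placements):
        out[sl] += w
        coverage[sl] += 1
    if config.normalize_overlap:
        np.divide(out, coverage, out=out, where=coverage > 0)
    return AttentionMap(weights=out, subject_id=subject_id)


def average_maps(maps: Sequence[AttentionMap]) -> AttentionMap:
    """Voxelwise mean of subject maps; the population-level attention map."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    shape = maps[0].weights.shape
    if any(m.weights.shape != shape for m in maps):
        raise ValueError("all maps must share a shape")
    mean = np.mean([m.weights for m in maps], axis=0)
    return AttentionMap(weights=mean, subject_id="population")


def region_attention_ratio(
    population_map: AttentionMap,
    labels: np.ndarray,
    signal_labels: Sequence[int] = (2, 4),
    background_label: int = 0,
) -> float:
    """Mean attention inside the age-signal tissues over the background mean.

    The phantom generator injects its age signal into ventricular size and
    GM-ribbon thickness, so a trained model's attention should concentrate
    there; the background shell outside the brain carries no signal.
    """
    w = population_map.weights
    signal = np.isin(labels, signal_labels)
    background = labels == background_label
    if not signal.any() or not background.any():
        raise ValueError("label map lacks signal or background voxels")
    bg = float(w[background].mean())
    sig = float(w[signal].mean())
    return sig / bg if bg > 0 else np.inf
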