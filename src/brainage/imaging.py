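"""Volume I/O, minimal preprocessing, and label-map volumetry.

Preprocessing mirrors the minimal protocol used before CNN age prediction:
min-max intensity normalization over the brain mask and linear resampling
onto a template grid.  Volumetry converts an integer tissue-label map into
the standard report: gray matter / white matter / CSF as percentages of
intracranial volume (ICV) and white-matter-hyperintensity (WMH) load in mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity range over the mask."""


@dataclass
class LabeledVolume:
    """A 3D intensity grid with its co-registered integer tissue-label grid.

    Label codes: 0 background, 1 sulcal CSF, 2 gray matter, 3 white matter,
    4 ventricular CSF, 5 WMH.
    """

    intensities: np.ndarray
    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.intensities.shape != self.labels.shape:
            raise ValueError("intensity and label grids must share a shape")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass(frozen=True)
class VolumetryRecord:
    """Tissue volumes in the reporting convention of clinical volumetry.

    GM, WM and CSF are percentages of ICV (CSF pools sulcal and ventricular
    CSF; WMH voxels are counted as WM tissue); WMH is additionally reported
    as an absolute volume in mL.
    """

    gm_pct_icv: float
    wm_pct_icv: float
    csf_pct_icv: float
    wmh_ml: float


def minmax_normalize(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rescale intensities to [0, 1] over the mask; outside the mask -> 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    values = volume[mask]
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise DegenerateImageError("constant image over mask: no intensity range")
    out = np.zeros_like(volume, dtype=np.float32)
    out[mask] = (volume[mask] - vmin) / (vmax - vmin)
    return out


def resample_affine(
    volume: np.ndarray,
    affine: np.ndarray,
    target_shape: Sequence[int],
    interpolation: Literal["linear", "nearest"] = "linear",
) -> np.ndarray:
    """Resample a volume through a 4x4 voxel-to-voxel affine.

    ``affine`` maps output voxel coordinates to input voxel coordinates
    (pull-back convention).  Trilinear interpolation for intensities,
    nearest-neighbour for label maps; voxels mapping outside the input
    field of view are set to 0.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise np.linalg.LinAlgError("singular affine")
    order = {"linear": 1, "nearest": 0}[interpolation]
    return ndimage.affine_transform(
        volume,
        affine[:3, :3],
        offset=affine[:3, 3],
        output_shape=tuple(int(s) for s in target_shape),
        order=order,
        mode="constant",
        cval=0.0,
    )


def tissue_fractions(vol: LabeledVolume) -> VolumetryRecord:
    """Compute GM/WM/CSF %ICV and WMH mL from a label map.

    ICV is every labelled voxel (codes 1-5).  CSF pools codes 1 and 4;
    WM pools codes 3 and 5 (a hyperintensity is lesioned WM tissue), while
    WMH is also reported separately in mL.
    """
    labels = vol.labels
    valid = (labels >= 0) & (labels <= 5)
    if not valid.all():
        raise ValueError("label map contains invalid codes")
    counts = np.bincount(labels.ravel(), minlength=6)
    icv = counts[1:].sum()
    if icv == 0:
        raise ValueError("empty brain mask")
    gm = counts[2]
    wm = counts[3] + counts[5]
    csf = counts[1] + counts[4]
    return VolumetryRecord(
        gm_pct_icv=100.0 * gm / icv,
        wm_pct_icv=100.0 * wm / icv,
        csf_pct_icv=100.0 * csf / icv,
        wmh_ml=counts[5] * vol.voxel_volume_ml,
    )


def volumetry_table(ids: Sequence[str], volumes: Sequence[LabeledVolume]) -> pd.DataFrame:
    """Volumetry for a cohort as a table ``id,gm_pct,wm_pct,csf_pct,wmh_ml``."""
    rows = []
    for sid, vol in zip(ids, volumes):
        rec = tissue_fractions(vol)
        rows.append(
            {
                "id": sid,
                "gm_pct": rec.gm_pct_icv,
                "wm_pct": rec.wm_pct_icv,
                "csf_pct": rec.csf_pct_icv,
                "wmh_ml": rec.wmh_ml,
            }
        )
    return pd.DataFrame(rows, columns=["id", "gm_pct", "wm_pct", "csf_pct", "wmh_ml"])


# ---------------------------------------------------------------------------
# NIfTI persistence


def _affine_from_voxel_size(voxel_size: Sequence[float]) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size
    return affine


def save_labeled_volume(
    vol: LabeledVolume, intensity_path: str | Path, labels_path: str | Path
) -> None:
    """Write the intensity/label pair as NIfTI-1 images sharing one affine."""
    affine = _affine_from_voxel_size(vol.voxel_size)
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(intensity_path))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine), str(labels_path))


def load_labeled_volume(
    intensity_path: str | Path, labels_path: str | Path
) -> LabeledVolume:
    """Read an intensity/label NIfTI pair back into a LabeledVolume."""
    img = nib.load(str(intensity_path))
    lab = nib.load(str(labels_path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledVolume(
        intensities=np.asarray(img.dataobj, dtype=np.float32),
        labels=np.asarray(lab.dataobj, dtype=np.int16),
        voxel_size=voxel_size,
    )
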