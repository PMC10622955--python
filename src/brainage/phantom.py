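"""Synthetic aging-brain phantom cohorts with known ground truth.

The generator emulates the structural signature of brain aging that a T1-weighted
age-regression model feeds on: ventricular enlargement, cortical gray-matter
thinning with a matching gain in sulcal CSF, and a small age-linked load of
white-matter hyperintensities (WMH).  Geometry is deliberately simple -- nested
concentric ellipsoids -- so that every tissue volume has a computable ground
truth and every downstream stage (volumetry, CNN training, bias correction,
attention maps, cohort statistics) can be tested without any external data.

A phantom is a pair of co-registered 3D grids: a floating-point intensity
volume (arbitrary units, noisy) and a noise-free integer label volume with
codes 0 background, 1 sulcal CSF, 2 gray matter, 3 white matter, 4 ventricular
CSF, 5 WMH.

Cohorts mirror the study design: an all-female training set spanning ages
18-70, study-age controls, and patients whose brains are built at
``chronological age + delta`` where delta is a disease-related aging offset --
the quantity the downstream pipeline must recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import LabeledVolume, save_labeled_volume

logger = logging.getLogger(__name__)

#: Voxel grid of the full-resolution template the real pipeline operates on
#: (1 mm MNI-registered T1 volumes).  Kept for documentation parity; the
#: package default works at desk scale (32^3 voxels over the same field of
#: view).
FULL_SCALE_GRID = (182, 218, 182)

#: The five cognitive domains recorded per subject (standardized scores,
#: normative mean 100, SD 15).
COGNITIVE_DOMAINS = (
    "composite_memory",
    "psychomotor_speed",
    "reaction_time",
    "complex_attention",
    "cognitive_flexibility",
)

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_VENTRICLE = 4
LABEL_WMH = 5


class PhantomConfigError(ValueError):
    """Raised when phantom structure parameters cannot fit the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of a single phantom.

    Volumes are expressed in voxels of the working grid.  Defaults are
    calibrated so that a control cohort (mean age ~37 y) lands near the
    healthy-control volumetry of the study population: CSF ~10.8 % of
    intracranial volume (ICV), GM ~52.3 %, WM ~36.9 %, WMH ~0.06 mL.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (5.6875, 6.8125, 5.6875)
    brain_semiaxes: tuple[float, float, float] = (13.0, 14.5, 13.0)
    ventricle_base_volume: float = 150.0   # voxels at age 18
    ventricle_growth: float = 8.0          # voxels / year
    gm_ribbon_base: float = 5800.0         # voxels at age 18
    gm_thinning: float = 20.0              # voxels / year (lost to sulcal CSF)
    csf_shell_base: float = 325.0          # sulcal CSF voxels at age 18
    morph_age_jitter_sd: float = 2.0       # years, per-subject biological spread
    tissue_intensity_means: Mapping[int, float] = field(
        default_factory=lambda: {
            LABEL_BACKGROUND: 0.0,
            LABEL_CSF: 20.0,
            LABEL_GM: 55.0,
            LABEL_WM: 85.0,
            LABEL_VENTRICLE: 20.0,
            LABEL_WMH: 100.0,
        }
    )
    noise_sd: float = 4.0                  # arbitrary units, intensities only
    wmh_rate: float = 0.04                 # expected lesions / year beyond age 30
    wmh_radius_range: tuple[float, float] = (0.4, 1.0)  # voxels
    age_range: tuple[float, float] = (18.0, 80.0)

    def __post_init__(self) -> None:
        if any(int(g) < 16 for g in self.grid_shape):
            raise PhantomConfigError("grid_shape components must be >= 16")
        if self.ventricle_growth <= 0:
            raise PhantomConfigError("ventricle_growth must be > 0")
        if self.gm_thinning < 0 or self.noise_sd < 0:
            raise PhantomConfigError("gm_thinning and noise_sd must be >= 0")
        for ax, g in zip(self.brain_semiaxes, self.grid_shape):
            if 2 * ax + 2 > g:
                raise PhantomConfigError(
                    f"brain semiaxis {ax} does not fit in grid dimension {g}"
                )
        if self.wmh_radius_range[0] > self.wmh_radius_range[1]:
            raise PhantomConfigError("wmh_radius_range must be (lo, hi) with lo <= hi")
        # Ellipsoid boundary ordering must hold across the supported age span.
        for age in self.age_range:
            self._boundaries(age)

    @property
    def analytic_brain_volume(self) -> float:
        """Analytic ICV in voxels, 4/3 pi abc."""
        a, b, c = self.brain_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c

    def structure_volumes(self, structural_age: float) -> dict[str, float]:
        """Target tissue volumes (voxels) at a given structural age.

        Ventricles grow linearly; the GM ribbon thins linearly, the lost
        volume accruing to sulcal CSF (so GM + sulcal CSF is conserved and
        the WM shell boundary stays fixed while ventricles eat into WM).
        """
        years = structural_age - 18.0
        return {
            "ventricle": self.ventricle_base_volume + self.ventricle_growth * years,
            "gm": self.gm_ribbon_base - self.gm_thinning * years,
            "sulcal_csf": self.csf_shell_base + self.gm_thinning * years,
        }

    def _boundaries(self, structural_age: float) -> tuple[float, float, float]:
        """Relative ellipsoid radii (lambda_vent, lambda_gm_inner, lambda_gm_outer).

        A point at normalized radius rho (rho = 1 on the ICV surface) is
        ventricle if rho <= lambda_vent, WM if <= lambda_gm_inner, GM if
        <= lambda_gm_outer, sulcal CSF if <= 1.
        """
        v = self.structure_volumes(structural_age)
        icv = self.analytic_brain_volume
        lam_outer3 = 1.0 - v["sulcal_csf"] / icv
        lam_inner3 = lam_outer3 - v["gm"] / icv
        lam_vent3 = v["ventricle"] / icv
        if not (0.0 < lam_vent3 < lam_inner3 < lam_outer3 <= 1.0):
            raise PhantomConfigError(
                f"degenerate tissue boundaries at structural age {structural_age:.1f}"
            )
        return tuple(np.cbrt([lam_vent3, lam_inner3, lam_outer3]))


@dataclass(frozen=True)
class NfLModel:
    """log10 plasma neurofilament light (pg/mL) as a linear model of age and offset."""

    intercept: float = 0.33
    slope_per_year_age: float = 0.010
    slope_per_year_offset: float = 0.035
    noise_sd: float = 0.12


@dataclass(frozen=True)
class CognitionModel:
    """Standardized cognitive scores: normative mean 100, SD 15, offset-linked deficit."""

    base: float = 100.0
    sd: float = 15.0
    slope_per_year_offset: Mapping[str, float] = field(
        default_factory=lambda: {
            "composite_memory": 1.0,
            "psychomotor_speed": 0.9,
            "reaction_time": 2.4,
            "complex_attention": 0.85,
            "cognitive_flexibility": 0.95,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a simulated study: training set, controls, patients."""

    n_training: int = 200
    n_controls: int = 24
    n_patients: int = 70
    training_age_range: tuple[float, float] = (18.0, 70.0)
    study_age_range: tuple[float, float] = (18.0, 55.0)
    control_age_mean_sd: tuple[float, float] = (37.0, 9.4)
    patient_age_mean_sd: tuple[float, float] = (35.9, 9.0)
    offset_mean_sd: tuple[float, float] = (4.0, 2.0)
    allow_negative_offset: bool = False
    wmh_patient_rate_multiplier: float = 2.0
    nfl_model: NfLModel = field(default_factory=NfLModel)
    cognition_model: CognitionModel = field(default_factory=CognitionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_training, self.n_controls, self.n_patients) < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass
class SubjectRecord:
    """One simulated participant."""

    id: str
    role: str  # training | control | patient
    chronological_age: float
    offset_delta: float
    log_nfl: float = np.nan
    cognitive_scores: dict[str, float] = field(default_factory=dict)
    volume_ref: str = ""
    volume: LabeledVolume | None = None

    @property
    def effective_age(self) -> float:
        return self.chronological_age + self.offset_delta


# ---------------------------------------------------------------------------
# Random substreams: all randomness flows from one root seed.

_STREAMS = {"ages": 1, "structure": 2, "noise": 3, "covariates": 4, "wmh": 5}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Named, per-subject random substream derived from a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream], int(index)))
    )


# ---------------------------------------------------------------------------
# Single-volume generation


def _normalized_radius(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    center = [(g - 1) / 2.0 for g in shape]
    grids = np.meshgrid(*[np.arange(g, dtype=np.float64) for g in shape], indexing="ij")
    rho2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, spec.brain_semiaxes):
        rho2 += ((g - c) / a) ** 2
    return np.sqrt(rho2)


def generate_subject_volume(
    effective_age: float,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    *,
    wmh_rate_multiplier: float = 1.0,
) -> LabeledVolume:
    """Build one phantom at the given effective (biological) brain age.

    The label volume is a deterministic function of the structural age
    (effective age plus a per-seed biological jitter): concentric outer sulcal
    CSF shell, GM ribbon, WM core and central ventricles, with WMH lesions
    sampled inside WM at an expected count of
    ``wmh_rate * multiplier * max(0, structural_age - 30)``.  Gaussian noise
    is added to the intensity volume only; labels stay noise-free.
    """
    spec = spec or PhantomSpec()
    lo, hi = spec.age_range
    if not (lo <= effective_age <= hi):
        raise ValueError(f"effective_age {effective_age} outside supported range {spec.age_range}")

    rng_struct = _rng(seed, "structure")
    jitter = rng_struct.normal(0.0, spec.morph_age_jitter_sd) if spec.morph_age_jitter_sd else 0.0
    structural_age = float(np.clip(effective_age + jitter, lo, hi))

    rho = _normalized_radius(spec)
    lam_vent, lam_inner, lam_outer = spec._boundaries(structural_age)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[rho <= 1.0] = LABEL_CSF
    labels[rho <= lam_outer] = LABEL_GM
    labels[rho <= lam_inner] = LABEL_WM
    labels[rho <= lam_vent] = LABEL_VENTRICLE

    _add_wmh(labels, rho, lam_vent, lam_inner, structural_age, spec,
             wmh_rate_multiplier, _rng(seed, "wmh"))

    intensities = np.zeros(spec.grid_shape, dtype=np.float32)
    for code, mean in spec.tissue_intensity_means.items():
        intensities[labels == code] = mean
    if spec.noise_sd > 0:
        noise = _rng(seed, "noise").normal(0.0, spec.noise_sd, size=spec.grid_shape)
        intensities = (intensities + noise).astype(np.float32)

    return LabeledVolume(intensities=intensities, labels=labels, voxel_size=spec.voxel_size)


def _add_wmh(
    labels: np.ndarray,
    rho: np.ndarray,
    lam_vent: float,
    lam_inner: float,
    structural_age: float,
    spec: PhantomSpec,
    rate_multiplier: float,
    rng: np.random.Generator,
) -> None:
    """Carve hyperintense spherical lesions into the WM shell, in place."""
    expected = spec.wmh_rate * rate_multiplier * max(0.0, structural_age - 30.0)
    n_lesions = int(rng.poisson(expected)) if expected > 0 else 0
    if n_lesions == 0:
        return
    wm_idx = np.argwhere(labels == LABEL_WM)
    if len(wm_idx) == 0:
        return
    coords = np.indices(labels.shape).reshape(3, -1).T
    for _ in range(n_lesions):
        center = wm_idx[rng.integers(len(wm_idx))]
        radius = rng.uniform(*spec.wmh_radius_range)
        d2 = np.sum((coords - center) ** 2, axis=1).reshape(labels.shape)
        sphere = d2 <= radius**2
        labels[sphere & (labels == LABEL_WM)] = LABEL_WMH


# ---------------------------------------------------------------------------
# Covariates


def sample_covariates(
    record: SubjectRecord, cohort: CohortSpec, rng: np.random.Generator
) -> SubjectRecord:
    """Attach plasma log-NfL and the five cognitive scores to a subject.

    log10 NfL rises with chronological age and with the aging offset delta;
    cognitive scores start at the normative mean of 100 and fall linearly
    with delta, with noise at the normative SD of 15.
    """
    nfl = cohort.nfl_model
    record.log_nfl = (
        nfl.intercept
        + nfl.slope_per_year_age * record.chronological_age
        + nfl.slope_per_year_offset * record.offset_delta
        + (rng.normal(0.0, nfl.noise_sd) if nfl.noise_sd else 0.0)
    )
    cog = cohort.cognition_model
    scores: dict[str, float] = {}
    for domain in COGNITIVE_DOMAINS:
        slope = cog.slope_per_year_offset.get(domain, 0.0)
        score = cog.base - slope * record.offset_delta
        if cog.sd:
            score += rng.normal(0.0, cog.sd)
        if not (40.0 <= score <= 160.0):
            logger.warning(
                "subject %s: %s score %.1f outside the plausible range [40, 160]",
                record.id, domain, score,
            )
        scores[domain] = float(score)
    record.cognitive_scores = scores
    return record


# ---------------------------------------------------------------------------
# Cohort generation

MANIFEST_COLUMNS = (
    ["id", "role", "chronological_age", "offset_delta", "log_nfl"]
    + list(COGNITIVE_DOMAINS)
    + ["volume_path"]
)


def _sample_ages(cohort: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    lo_t, hi_t = cohort.training_age_range
    lo_s, hi_s = cohort.study_age_range
    training = rng.uniform(lo_t, hi_t, size=cohort.n_training)
    controls = np.clip(
        rng.normal(*cohort.control_age_mean_sd, size=cohort.n_controls), lo_s, hi_s
    )
    patients = np.clip(
        rng.normal(*cohort.patient_age_mean_sd, size=cohort.n_patients), lo_s, hi_s
    )
    return {"training": training, "control": controls, "patient": patients}


def generate_cohort(
    cohort: CohortSpec | None = None,
    spec: PhantomSpec | None = None,
    out_dir: str | Path | None = None,
) -> list[SubjectRecord]:
    """Simulate a full study cohort: subjects, covariates, and phantom volumes.

    Training and control subjects are built at their chronological age
    (offset delta = 0); patients at ``chronological age + delta`` with delta
    drawn from the cohort's offset distribution (truncated at zero unless
    negative offsets are allowed).  Patients additionally carry the cohort's
    WMH rate multiplier.

    If ``out_dir`` is given, every phantom is written as a NIfTI pair
    (``<id>_t1.nii.gz`` / ``<id>_labels.nii.gz``) and a ``manifest.csv`` is
    written; otherwise volumes stay attached in memory.
    """
    cohort = cohort or CohortSpec()
    spec = spec or PhantomSpec()
    rng_ages = _rng(cohort.seed, "ages")
    ages = _sample_ages(cohort, rng_ages)

    offsets = rng_ages.normal(*cohort.offset_mean_sd, size=cohort.n_patients)
    if not cohort.allow_negative_offset:
        offsets = np.maximum(offsets, 0.0)

    records: list[SubjectRecord] = []
    for role in ("training", "control", "patient"):
        for j, age in enumerate(ages[role]):
            delta = float(offsets[j]) if role == "patient" else 0.0
            records.append(
                SubjectRecord(
                    id=f"{role[:3]}{j:04d}",
                    role=role,
                    chronological_age=float(age),
                    offset_delta=delta,
                )
            )

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i, rec in enumerate(records):
        rng_cov = _rng(cohort.seed, "covariates", i)
        sample_covariates(rec, cohort, rng_cov)
        mult = cohort.wmh_patient_rate_multiplier if rec.role == "patient" else 1.0
        # Per-subject volume seed derived from the root seed and subject index.
        vol_seed = int(
            np.random.SeedSequence(entropy=int(cohort.seed), spawn_key=(99, i))
            .generate_state(1)[0] % (2**31)
        )
        rec.volume = generate_subject_volume(
            rec.effective_age, spec, seed=vol_seed, wmh_rate_multiplier=mult
        )
        if out_path is not None:
            t1 = out_path / f"{rec.id}_t1.nii.gz"
            save_labeled_volume(rec.volume, t1, out_path / f"{rec.id}_labels.nii.gz")
            rec.volume_ref = str(t1)

    if out_path is not None:
        manifest_frame(records).to_csv(out_path / "manifest.csv", index=False)
    return records


def manifest_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate a cohort as the manifest CSV schema."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "role": rec.role,
            "chronological_age": rec.chronological_age,
            "offset_delta": rec.offset_delta,
            "log_nfl": rec.log_nfl,
        }
        row.update({d: rec.cognitive_scores.get(d, np.nan) for d in COGNITIVE_DOMAINS})
        row["volume_path"] = rec.volume_ref
        rows.append(row)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
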