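"""Phantom generator: determinism, aging morphology, covariates, cohorts."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats as sps

from brainage.imaging import tissue_fractions
from brainage.phantom import (
    COGNITIVE_DOMAINS,
    CohortSpec,
    NfLModel,
    CognitionModel,
    PhantomConfigError,
    PhantomSpec,
    SubjectRecord,
    generate_cohort,
    generate_subject_volume,
    manifest_frame,
    sample_covariates,
)


def noise_free(spec=None, **kw):
    spec = spec or PhantomSpec()
    return replace(spec, morph_age_jitter_sd=0.0, noise_sd=0.0, wmh_rate=0.0, **kw)


class TestSubjectVolume:
    def test_seeded_determinism(self):
        a = generate_subject_volume(45.0, seed=3)
        b = generate_subject_volume(45.0, seed=3)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_changes_noise(self):
        a = generate_subject_volume(45.0, seed=3)
        b = generate_subject_volume(45.0, seed=4)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_ventricles_grow_with_age(self):
        old = generate_subject_volume(70.0, seed=5)
        young = generate_subject_volume(20.0, seed=5)
        assert (old.labels == 4).sum() > (young.labels == 4).sum()

    def test_monotone_fractions_noise_free(self):
        spec = noise_free()
        fracs = [tissue_fractions(generate_subject_volume(a, spec, seed=0))
                 for a in (20, 30, 40, 50, 60, 70)]
        vent = [f.csf_pct_icv for f in fracs]
        gm = [f.gm_pct_icv for f in fracs]
        assert all(b > a for a, b in zip(vent, vent[1:]))
        assert all(b < a for a, b in zip(gm, gm[1:]))

    def test_concentric_structure(self):
        spec = noise_free()
        vol = generate_subject_volume(40.0, spec, seed=0)
        labels = vol.labels
        # tissues are radially ordered: ventricle < WM < GM < sulcal CSF
        center = [(g - 1) / 2 for g in labels.shape]
        grids = np.meshgrid(*[np.arange(g) for g in labels.shape], indexing="ij")
        rho = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in
                          zip(grids, center, spec.brain_semiaxes)))
        order = [rho[labels == code].max() for code in (4, 3, 2, 1)]
        assert order == sorted(order)
        assert all((labels == code).any() for code in (1, 2, 3, 4))

    def test_control_csf_near_published_mean(self):
        """Mean control CSF fraction calibrated to the healthy-control value
        of 10.80 % of ICV (within +/- 1.5)."""
        rng = np.random.default_rng(2024)
        fracs = []
        for i in range(24):
            age = float(np.clip(rng.normal(37.0, 9.4), 18, 55))
            vol = generate_subject_volume(age, seed=500 + i)
            fracs.append(tissue_fractions(vol).csf_pct_icv)
        assert abs(np.mean(fracs) - 10.80) < 1.5

    def test_wmh_lies_inside_brain(self):
        spec = replace(PhantomSpec(), wmh_rate=2.0)  # force many lesions
        vol = generate_subject_volume(70.0, spec, seed=1)
        wmh = np.argwhere(vol.labels == 5)
        assert len(wmh) > 0
        brain = vol.labels > 0
        for idx in wmh:  # every neighbour of a WMH voxel is intracranial
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    assert brain[tuple(nb)]

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_subject_volume(95.0, seed=0)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(PhantomConfigError):
            PhantomSpec(brain_semiaxes=(20.0, 20.0, 20.0))
        with pytest.raises(PhantomConfigError):
            PhantomSpec(gm_thinning=200.0)


class TestCovariates:
    def _record(self, age=36.0, delta=0.0):
        return SubjectRecord(id="x", role="patient", chronological_age=age,
                             offset_delta=delta)

    def test_zero_offset_zero_noise_scores_are_100(self):
        cohort = CohortSpec(
            nfl_model=NfLModel(noise_sd=0.0),
            cognition_model=CognitionModel(sd=0.0),
        )
        rec = sample_covariates(self._record(), cohort, np.random.default_rng(0))
        assert all(v == 100.0 for v in rec.cognitive_scores.values())

    def test_log_nfl_arithmetic(self):
        cohort = CohortSpec(
            nfl_model=NfLModel(intercept=0.4, slope_per_year_age=0.005,
                               slope_per_year_offset=0.02, noise_sd=0.0),
        )
        rec = sample_covariates(self._record(age=36.0, delta=4.0), cohort,
                                np.random.default_rng(0))
        assert rec.log_nfl == pytest.approx(0.4 + 0.26, abs=1e-12)

    def test_nfl_increases_with_age_in_controls(self):
        cohort = CohortSpec()
        rng = np.random.default_rng(1)
        ages = rng.uniform(18, 55, size=500)
        vals = []
        for i, age in enumerate(ages):
            rec = sample_covariates(
                SubjectRecord(id=f"c{i}", role="control",
                              chronological_age=float(age), offset_delta=0.0),
                cohort, rng)
            vals.append(rec.log_nfl)
        r, p = sps.pearsonr(vals, ages)
        assert r > 0 and p < 0.01

    def test_extreme_score_warning(self, caplog):
        cohort = CohortSpec(cognition_model=CognitionModel(
            sd=0.0, slope_per_year_offset={"reaction_time": 10.0}))
        with caplog.at_level("WARNING"):
            sample_covariates(self._record(delta=10.0), cohort, np.random.default_rng(0))
        assert "outside the plausible range" in caplog.text

    def test_domains_are_the_five_recorded(self):
        rec = sample_covariates(self._record(), CohortSpec(), np.random.default_rng(0))
        assert tuple(rec.cognitive_scores) == COGNITIVE_DOMAINS


class TestCohort:
    def test_manifest_roles_without_patients(self):
        recs = generate_cohort(CohortSpec(n_training=2, n_controls=2, n_patients=0, seed=0))
        frame = manifest_frame(recs)
        assert set(frame.role) == {"training", "control"}

    def test_effective_age_identity(self, small_cohort):
        for rec in small_cohort:
            assert rec.effective_age == rec.chronological_age + rec.offset_delta
            if rec.role != "patient":
                assert rec.offset_delta == 0.0
            else:
                assert rec.offset_delta >= 0.0

    def test_patient_mean_age_matches_study_population(self):
        recs = generate_cohort(CohortSpec(seed=42))
        ages = [r.chronological_age for r in recs if r.role == "patient"]
        assert abs(np.mean(ages) - 35.9) < 2.0

    def test_cohort_determinism(self):
        cohort = CohortSpec(n_training=3, n_controls=3, n_patients=3, seed=9)
        a, b = generate_cohort(cohort), generate_cohort(cohort)
        pd.testing.assert_frame_equal(manifest_frame(a), manifest_frame(b))
        assert np.array_equal(a[0].volume.intensities, b[0].volume.intensities)

    def test_null_offset_groups_indistinguishable(self):
        """With the offset forced to zero, patient and control ventricle
        fractions come from the same distribution (non-significant t in at
        least 8/10 seeds)."""
        nonsig = 0
        for seed in range(10):
            cohort = CohortSpec(n_training=0, n_controls=24, n_patients=24,
                                offset_mean_sd=(0.0, 0.0), seed=100 + seed)
            recs = generate_cohort(cohort)
            csf = {role: [tissue_fractions(r.volume).csf_pct_icv
                          for r in recs if r.role == role]
                   for role in ("control", "patient")}
            _, p = sps.ttest_ind(csf["patient"], csf["control"])
            nonsig += p > 0.05
        assert nonsig >= 8

    def test_writes_nifti_and_manifest(self, tmp_path):
        cohort = CohortSpec(n_training=1, n_controls=1, n_patients=1, seed=1)
        recs = generate_cohort(cohort, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        for rec in recs:
            assert (tmp_path / f"{rec.id}_t1.nii.gz").exists()
            assert (tmp_path / f"{rec.id}_labels.nii.gz").exists()
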