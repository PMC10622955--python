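"""End-to-end orchestration: simulate -> preprocess -> train -> predict ->
score -> attention -> statistics.

One :func:`run_full_pipeline` call reproduces, on a synthetic cohort with a
known injected aging offset, the structure of a BrainAGE study's result
tables: patient-vs-control MRI metrics with effect sizes (``mri_table``),
high/low BrainAGE comparisons of neurodegeneration markers
(``stratified_table``), the univariate risk-factor screen
(``risk_univariate``) and the multivariate logistic model (``risk_model``).
The high/low cutoff is re-derived per run from the ROC/Youden analysis
against low reaction-time performance, mirroring the published procedure
rather than hard-coding its cohort-specific cutoff of z = 0.9.

Runs are deterministic for a fixed root seed in single-thread execution;
the root seed fans out to the cohort sampler, the network initialization
and the training shuffles/augmentations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .attention import AttentionMap, OcclusionConfig, average_maps, occlusion_map, region_attention_ratio
from .imaging import minmax_normalize, tissue_fractions
from .model import AgeModel, ArchitectureSpec, TrainingConfig, crossvalidate, train
from .phantom import (
    COGNITIVE_DOMAINS,
    CohortSpec,
    PhantomSpec,
    SubjectRecord,
    generate_cohort,
    manifest_frame,
)
from .published import verify_printed_values  # noqa: F401  (re-exported pipeline verb)
from .scoring import (
    BiasModel,
    control_reference,
    correct_gaps,
    fit_bias_model,
    to_zscore,
)
from .stats import (
    GroupSummary,
    StratificationConfig,
    anova_oneway,
    ancova_age_adjusted,
    cohens_d_pooled,
    mann_whitney,
    pairwise_posthoc,
    roc_youden,
    screen_and_fit_logistic,
    two_sample_t,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    occlusion: OcclusionConfig = field(default_factory=OcclusionConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    output_dir: str | None = None
    root_seed: int = 0
    include_crossval: bool = True
    include_attention: bool = True
    save_volumes: bool = False

    def seeded(self) -> "RunConfig":
        """Propagate the root seed to every module's substream."""
        return replace(
            self,
            cohort=replace(self.cohort, seed=self.root_seed),
            training=replace(self.training, seed=self.root_seed),
        )

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    scores: pd.DataFrame
    bias_model: BiasModel
    mri_table: pd.DataFrame
    youden_threshold: float
    youden_j: float
    roc_curve: pd.DataFrame
    stratified_table: pd.DataFrame
    stratified_pairwise: dict[str, pd.DataFrame]
    risk_univariate: pd.DataFrame
    risk_model: pd.DataFrame | None
    risk_screening: dict
    fold_maes: list[float]
    attention_ratio: float | None
    population_map: AttentionMap | None
    provenance: dict

    def summary(self) -> dict:
        """The report's headline numbers (stable JSON-serializable schema)."""
        pat = self.scores[self.scores.role == "patient"]
        ctl = self.scores[self.scores.role == "control"]
        return {
            "n_patients": int(len(pat)),
            "n_controls": int(len(ctl)),
            "patient_mean_z": float(pat.z_score.mean()),
            "patient_sd_z": float(pat.z_score.std(ddof=1)),
            "control_mean_z": float(ctl.z_score.mean()),
            "control_sd_z": float(ctl.z_score.std(ddof=1)),
            "gap_difference_years": float(
                pat.corrected_gap.mean() - ctl.corrected_gap.mean()
            ),
            "bias_alpha": self.bias_model.alpha,
            "bias_intercept": self.bias_model.intercept,
            "youden_threshold": self.youden_threshold,
            "youden_j": self.youden_j,
            "fold_maes": [float(m) for m in self.fold_maes],
            "attention_ratio": self.attention_ratio,
            "mri_table": self.mri_table.to_dict(orient="records"),
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Stage helpers (each usable on its own; the CLI verbs map onto these)


def preprocess_volumes(records: Sequence[SubjectRecord]) -> np.ndarray:
    """Min-max normalize every subject's intensities over its brain mask."""
    return np.stack(
        [minmax_normalize(r.volume.intensities, r.volume.brain_mask) for r in records]
    )


def predict_cohort(model: AgeModel, records: Sequence[SubjectRecord],
                   volumes: np.ndarray) -> pd.DataFrame:
    """Predicted ages and raw gaps for a cohort (gap vs chronological age)."""
    preds = model.predict(volumes)
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "role": [r.role for r in records],
            "chronological_age": [r.chronological_age for r in records],
            "effective_age": [r.effective_age for r in records],
            "offset_delta": [r.offset_delta for r in records],
            "predicted_age": preds,
            "raw_gap": preds - np.array([r.chronological_age for r in records]),
        }
    )


def score_gaps(scores: pd.DataFrame, bias: BiasModel | None = None
               ) -> tuple[pd.DataFrame, BiasModel]:
    """Bias-correct raw gaps and attach control-referenced z-scores.

    The bias model is fitted on the controls unless one is supplied.
    """
    scores = scores.copy()
    ctl = scores[scores.role == "control"]
    if bias is None:
        bias = fit_bias_model(ctl.raw_gap, ctl.chronological_age, fit_population="controls")
    scores["corrected_gap"] = correct_gaps(scores.raw_gap, scores.chronological_age, bias)
    ref = control_reference(scores.loc[scores.role == "control", "corrected_gap"])
    scores["z_score"] = to_zscore(scores.corrected_gap, ref)
    return scores, bias


def _mri_metric_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        v = tissue_fractions(r.volume)
        rows.append(
            {
                "id": r.id,
                "role": r.role,
                "gm_pct_icv": v.gm_pct_icv,
                "wm_pct_icv": v.wm_pct_icv,
                "csf_pct_icv": v.csf_pct_icv,
                "wmh_ml": v.wmh_ml,
            }
        )
    return pd.DataFrame(rows)


def mri_group_table(scores: pd.DataFrame, volumetry: pd.DataFrame) -> pd.DataFrame:
    """Patient-vs-control MRI metrics: mean (SD), Cohen's d, p per metric."""
    merged = volumetry.merge(scores[["id", "z_score"]], on="id")
    merged = merged.rename(columns={"z_score": "brainage_z"})
    rows = []
    for metric in ("brainage_z", "gm_pct_icv", "wm_pct_icv", "csf_pct_icv", "wmh_ml"):
        pat = merged.loc[merged.role == "patient", metric].to_numpy()
        ctl = merged.loc[merged.role == "control", metric].to_numpy()
        gp, gc = GroupSummary.from_values(pat), GroupSummary.from_values(ctl)
        if metric == "wmh_ml":
            res = mann_whitney(pat, ctl)
        else:
            res = two_sample_t(gp, gc, variant="student")
        rows.append(
            {
                "metric": metric,
                "patient_mean": gp.mean, "patient_sd": gp.sd, "patient_n": gp.n,
                "control_mean": gc.mean, "control_sd": gc.sd, "control_n": gc.n,
                "cohens_d": cohens_d_pooled(gp, gc),
                "p_value": res.p_value,
                "test": res.method,
            }
        )
    return pd.DataFrame(rows)


def stratify_patients(
    scores: pd.DataFrame,
    records: Sequence[SubjectRecord],
    strat: StratificationConfig,
) -> tuple[pd.DataFrame, float, float, pd.DataFrame]:
    """Split patients into high/low BrainAGE by the ROC/Youden-derived z cutoff.

    The binary outcome is low performance on the configured cognitive score
    (standardized score < cutoff).  Falls back to a median split (logged)
    if the cohort happens to contain a single outcome class.
    """
    by_id = {r.id: r for r in records}
    pat = scores[scores.role == "patient"].copy()
    outcome = np.array(
        [by_id[i].cognitive_scores[strat.outcome_score] < strat.outcome_cutoff
         for i in pat.id], dtype=int,
    )
    try:
        yr = roc_youden(pat.z_score.to_numpy(), outcome)
        threshold, j, curve = yr.threshold, yr.j_statistic, yr.curve
    except ValueError:
        threshold = float(pat.z_score.median())
        j, curve = np.nan, pd.DataFrame()
        logger.warning(
            "single-class outcome for '%s': falling back to median z split at %.2f",
            strat.outcome_score, threshold,
        )
    pat["brainage_group"] = np.where(pat.z_score >= threshold, "high", "low")
    return pat, float(threshold), float(j), curve


def stratified_marker_table(
    pat: pd.DataFrame,
    scores: pd.DataFrame,
    volumetry: pd.DataFrame,
    records: Sequence[SubjectRecord],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """High/low BrainAGE patients vs controls: neurodegeneration markers.

    ANOVA for approximately normal variables, Kruskal-Wallis for WMH, an
    age-adjusted ANCOVA for log NfL, Bonferroni pairwise follow-up when the
    omnibus test is significant.
    """
    by_id = {r.id: r for r in records}
    merged = volumetry.merge(scores[["id", "z_score", "chronological_age"]], on="id")
    groups = {
        "high": merged[merged.id.isin(pat.loc[pat.brainage_group == "high", "id"])],
        "low": merged[merged.id.isin(pat.loc[pat.brainage_group == "low", "id"])],
        "control": merged[merged.role == "control"],
    }
    names = list(groups)
    rows, pairwise = [], {}

    def add_row(variable, vecs, variant):
        degenerate = any(len(v) < 2 for v in vecs)
        if degenerate:  # a high/low split can leave a 1-subject group
            logger.warning("group with n < 2 for %s: omnibus test skipped", variable)
            row = {"variable": variable, "test": variant, "p_value": np.nan}
        else:
            res = anova_oneway(vecs, variant=variant)
            row = {"variable": variable, "test": res.method, "p_value": res.p_value}
        for name, v in zip(names, vecs):
            row[f"{name}_mean"] = float(np.mean(v)) if len(v) else np.nan
            row[f"{name}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
            row[f"{name}_n"] = len(v)
        rows.append(row)
        if not degenerate and row["p_value"] < 0.05:
            pairwise[variable] = pairwise_posthoc(vecs, names, variant=variant)

    add_row("brainage_z", [g.z_score.to_numpy() for g in groups.values()], "anova")
    for metric in ("gm_pct_icv", "wm_pct_icv", "csf_pct_icv"):
        add_row(metric, [g[metric].to_numpy() for g in groups.values()], "anova")
    add_row("wmh_ml", [g.wmh_ml.to_numpy() for g in groups.values()], "kruskal")

    # age-adjusted log NfL (ANCOVA)
    ids = np.concatenate([g.id.to_numpy() for g in groups.values()])
    labels = np.concatenate([[n] * len(g) for n, g in groups.items()])
    nfl = np.array([by_id[i].log_nfl for i in ids])
    ages = np.array([by_id[i].chronological_age for i in ids])
    adjusted, res = ancova_age_adjusted(nfl, labels, ages)
    row = {"variable": "log_nfl_age_adjusted", "test": res.method, "p_value": res.p_value}
    for name in names:
        row[f"{name}_mean"] = adjusted[name]
        row[f"{name}_sd"] = np.nan
        row[f"{name}_n"] = int((labels == name).sum())
    rows.append(row)

    for domain in COGNITIVE_DOMAINS:
        vecs = [
            np.array([by_id[i].cognitive_scores[domain] for i in g.id]) for g in groups.values()
        ]
        add_row(domain, vecs, "anova")
    return pd.DataFrame(rows), pairwise


#: Covariates screened as candidate risk factors for high BrainAGE.  The
#: reaction-time score is deliberately excluded: it defines the outcome cutoff.
RISK_COVARIATES = (
    "chronological_age",
    "log_nfl",
    "wmh_ml",
    "composite_memory",
    "psychomotor_speed",
    "complex_attention",
    "cognitive_flexibility",
)


def _risk_table(pat: pd.DataFrame, records: Sequence[SubjectRecord],
                volumetry: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    by_id = {r.id: r for r in records}
    wmh = volumetry.set_index("id").wmh_ml
    rows = []
    for i in pat.id:
        r = by_id[i]
        row = {
            "chronological_age": r.chronological_age,
            "log_nfl": r.log_nfl,
            "wmh_ml": float(wmh[i]),
        }
        row.update({d: r.cognitive_scores[d] for d in COGNITIVE_DOMAINS if d != "reaction_time"})
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(RISK_COVARIATES))
    outcome = (pat.brainage_group == "high").to_numpy().astype(int)
    return table, outcome


def risk_univariate_table(pat: pd.DataFrame, records: Sequence[SubjectRecord],
                  volumetry: pd.DataFrame) -> pd.DataFrame:
    """Univariate high-vs-low comparison of every candidate risk factor."""
    table, outcome = _risk_table(pat, records, volumetry)
    rows = []
    degenerate = min(outcome.sum(), len(outcome) - outcome.sum()) < 2
    for col in table.columns:
        hi = table.loc[outcome == 1, col].to_numpy()
        lo = table.loc[outcome == 0, col].to_numpy()
        res = None if degenerate else two_sample_t(hi, lo)
        rows.append(
            {
                "variable": col,
                "high_mean": hi.mean(), "high_sd": hi.std(ddof=1), "high_n": len(hi),
                "low_mean": lo.mean(), "low_sd": lo.std(ddof=1), "low_n": len(lo),
                "p_value": np.nan if res is None else res.p_value,
            }
        )
    return pd.DataFrame(rows)


def risk_model_table(pat: pd.DataFrame, records: Sequence[SubjectRecord],
                  volumetry: pd.DataFrame) -> tuple[pd.DataFrame | None, dict]:
    """Screened multivariate logistic model of high BrainAGE."""
    table, outcome = _risk_table(pat, records, volumetry)
    if min(outcome.sum(), len(outcome) - outcome.sum()) < 2:
        logger.warning("degenerate high/low split: logistic screen skipped")
        return None, {"entered": [], "excluded_collinear": [], "univariate": []}
    report = screen_and_fit_logistic(table, outcome)
    meta = {
        "entered": report.entered,
        "excluded_collinear": report.excluded_collinear,
        "univariate": report.univariate.to_dict(orient="records"),
    }
    return report.final_model, meta


# ---------------------------------------------------------------------------
# Full pipeline


def run_full_pipeline(config: RunConfig | None = None) -> RunReport:
    """Execute every stage in order on one simulated study."""
    config = (config or RunConfig()).seeded()
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    t_start = time.time()
    try:
        records = generate_cohort(
            config.cohort, config.phantom, out_dir=out if config.save_volumes else None
        )
        training = [r for r in records if r.role == "training"]
        study = [r for r in records if r.role != "training"]
        logger.info("[simulate] %d subjects (%.1fs)", len(records), time.time() - t_start)

        stage = "preprocess"
        volumes = preprocess_volumes(records)
        vol_by_role = {
            "training": volumes[: len(training)],
            "study": volumes[len(training):],
        }

        stage = "train"
        t0 = time.time()
        model = AgeModel(config.architecture, seed=config.root_seed)
        train(model, vol_by_role["training"],
              np.array([r.effective_age for r in training]), config.training)
        logger.info("[train] final MAE %.2f y (%.1fs)",
                    model.training_history[-1], time.time() - t0)

        fold_maes: list[float] = []
        if config.include_crossval:
            stage = "crossvalidate"
            fold_maes = crossvalidate(
                vol_by_role["training"],
                np.array([r.effective_age for r in training]),
                config.training,
                config.architecture,
            )
            logger.info("[crossvalidate] fold MAEs %s", np.round(fold_maes, 2))

        stage = "predict"
        scores = predict_cohort(model, study, vol_by_role["study"])

        stage = "score"
        scores["role"] = [r.role for r in study]
        scores, bias = score_gaps(scores)

        attention_ratio, pop_map = None, None
        if config.include_attention:
            stage = "attention"
            t0 = time.time()
            maps = [
                occlusion_map(model, vol, config.occlusion, subject_id=r.id)
                for r, vol in zip(study, vol_by_role["study"])
            ]
            pop_map = average_maps(maps)
            # reference geometry: a mid-cohort control's labels
            ref_labels = study[0].volume.labels
            attention_ratio = region_attention_ratio(pop_map, ref_labels)
            logger.info("[attention] signal/background ratio %.2f (%.1fs)",
                        attention_ratio, time.time() - t0)

        stage = "stats"
        volumetry = _mri_metric_frame(study)
        t2 = mri_group_table(scores, volumetry)
        pat, threshold, j, curve = stratify_patients(scores, study, config.stratification)
        t3, t3_pairs = stratified_marker_table(pat, scores, volumetry, study)
        t4 = risk_univariate_table(pat, study, volumetry)
        t5, t5_meta = risk_model_table(pat, study, volumetry)
    except Exception as exc:
        if out is not None:
            (out / "FAILED_STAGE").write_text(stage)
        raise PipelineStageError(stage, exc) from exc

    provenance = {
        "config_hash": config.config_hash(),
        "root_seed": config.root_seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "wall_time_s": round(time.time() - t_start, 2),
    }
    report = RunReport(
        scores=scores, bias_model=bias, mri_table=t2,
        youden_threshold=threshold, youden_j=j, roc_curve=curve,
        stratified_table=t3, stratified_pairwise=t3_pairs, risk_univariate=t4, risk_model=t5,
        risk_screening=t5_meta, fold_maes=fold_maes,
        attention_ratio=attention_ratio, population_map=pop_map,
        provenance=provenance,
    )
    if out is not None:
        _persist(report, records, out)
    return report


def _persist(report: RunReport, records: Sequence[SubjectRecord], out: Path) -> None:
    manifest_frame(records).to_csv(out / "manifest.csv", index=False)
    report.scores.to_csv(out / "scores.csv", index=False)
    (out / "bias_model.json").write_text(report.bias_model.to_json())
    report.mri_table.to_csv(out / "mri_table.csv", index=False)
    report.stratified_table.to_csv(out / "stratified_table.csv", index=False)
    report.risk_univariate.to_csv(out / "risk_univariate.csv", index=False)
    if report.risk_model is not None:
        report.risk_model.to_csv(out / "risk_model.csv", index=False)
    if len(report.roc_curve):
        report.roc_curve.to_csv(out / "roc_curve.csv", index=False)
    if report.population_map is not None:
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(report.population_map.weights.astype(np.float32), np.eye(4)),
            str(out / "attention_population.nii.gz"),
        )
    (out / "report.json").write_text(json.dumps(report.summary(), indent=2))


# ---------------------------------------------------------------------------
# Signal + null evaluation sharing one trained model (the expensive stage)


def signal_and_null_run(root_seed: int, config: RunConfig | None = None) -> dict:
    """One seed of the offset-recovery experiment.

    Trains the regressor once, scores (a) the configured cohort with its
    injected aging offset and (b) a matched null cohort with the offset
    forced to zero, and computes the quantities the validation experiments
    monitor: gap difference, one-sided p, held-out accuracy, attention
    localization, and the null-cohort p.
    """
    from scipy import stats as sps

    config = (config or RunConfig()).seeded()
    config = replace(config, root_seed=root_seed).seeded()

    records = generate_cohort(config.cohort, config.phantom)
    training = [r for r in records if r.role == "training"]
    study = [r for r in records if r.role != "training"]

    volumes = preprocess_volumes(records)
    Xtr, Xst = volumes[: len(training)], volumes[len(training):]

    model = AgeModel(config.architecture, seed=config.root_seed)
    train(model, Xtr, np.array([r.effective_age for r in training]), config.training)

    scores = predict_cohort(model, study, Xst)
    scores, bias = score_gaps(scores)
    pat = scores[scores.role == "patient"]
    ctl = scores[scores.role == "control"]
    t, p_two = sps.ttest_ind(pat.corrected_gap, ctl.corrected_gap)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2

    held_pred = scores.predicted_age.to_numpy()
    held_true = scores.effective_age.to_numpy()
    mae = float(np.mean(np.abs(held_pred - held_true)))
    r = float(np.corrcoef(held_pred, held_true)[0, 1])

    # constant-predictor baseline: MAE of predicting the training mean age
    train_ages = np.array([x.effective_age for x in training])
    baseline_mae = float(np.mean(np.abs(held_true - train_ages.mean())))

    # null cohort: same design, offset forced to zero, fresh draw
    null_cohort = replace(config.cohort, offset_mean_sd=(0.0, 0.0),
                          seed=config.root_seed + 10_000)
    null_records = [r for r in generate_cohort(null_cohort, config.phantom)
                    if r.role != "training"]
    null_scores = predict_cohort(model, null_records, preprocess_volumes(null_records))
    null_scores["role"] = [r.role for r in null_records]
    null_scores, _ = score_gaps(null_scores)
    npat = null_scores[null_scores.role == "patient"]
    nctl = null_scores[null_scores.role == "control"]
    _, null_p = sps.ttest_ind(npat.corrected_gap, nctl.corrected_gap)

    out = {
        "seed": root_seed,
        "gap_difference_years": float(pat.corrected_gap.mean() - ctl.corrected_gap.mean()),
        "one_sided_p": float(p_one),
        "patient_mean_z": float(pat.z_score.mean()),
        "control_mean_z": float(ctl.z_score.mean()),
        "holdout_mae": mae,
        "holdout_r": r,
        "baseline_mae": baseline_mae,
        "age_sd": float(np.std(held_true)),
        "null_two_sided_p": float(null_p),
        "null_gap_difference_years": float(
            npat.corrected_gap.mean() - nctl.corrected_gap.mean()
        ),
        "bias_alpha": bias.alpha,
    }
    if config.include_attention:
        maps = [
            occlusion_map(model, vol, config.occlusion, subject_id=s.id)
            for s, vol in zip(study, Xst)
        ]
        pop = average_maps(maps)
        out["attention_ratio"] = region_attention_ratio(pop, study[0].volume.labels)
    return out
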