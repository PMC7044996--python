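"""End-to-end orchestration: model development and forward prediction.

``run_develop`` walks the full development sequence on a two-wave study:
case-mix scoring of both survey waves, workload computation and
exclusions, demographic retention, the joint-tercile outcome at follow-up,
the logistic fit, cross-validated discrimination, decile calibration, the
two-covariate comparison model and the 1%-trim sensitivity refit.

``run_predict`` applies a stored coefficient set to the current wave with
projected populations, scores the stress-test scenarios and tabulates
rank stability and risk-class transitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import casemix, outcome, prediction, retention, workload
from .errors import DataError
from .model import (SIMPLE_COVARIATES, CoefficientSet, ModelSpec,
                    build_design_matrix, calibration_by_decile,
                    cross_validated_auroc, fit_risk_model)
from .strata import STRATA

__all__ = ["DevelopmentReport", "PredictionReport", "run_develop", "run_predict",
           "load_study", "practice_scores_wide"]


@dataclass
class StudyTables:
    """A two-wave study loaded from CSV tables (no ground truth)."""

    baseline_panel: pd.DataFrame
    followup_panel: pd.DataFrame
    rosters: dict[int, pd.DataFrame]
    gpps_responses: dict[int, pd.DataFrame]
    intention_survey: pd.DataFrame
    projections: pd.DataFrame


def load_study(indir: str | Path) -> StudyTables:
    """Read the CSV layout written by ``SyntheticStudy.write``."""
    p = Path(indir)
    base = pd.read_csv(p / "panel_baseline.csv")
    fup = pd.read_csv(p / "panel_followup.csv")
    years = (int(base["year"].iloc[0]), int(fup["year"].iloc[0]))
    return StudyTables(
        baseline_panel=base,
        followup_panel=fup,
        rosters={y: pd.read_csv(p / f"roster_{y}.csv") for y in years},
        gpps_responses={y: pd.read_csv(p / f"gpps_responses_{y}.csv") for y in years},
        intention_survey=pd.read_csv(p / "intention_survey.csv"),
        projections=pd.read_csv(p / "projections.csv"),
    )


def practice_scores_wide(scores: pd.DataFrame) -> pd.DataFrame:
    """Long (practice, item, log_or) scores to one column per item."""
    return scores.pivot(index="practice_id", columns="item", values="log_or")


def _panel_workload(panel: pd.DataFrame, weights, deprivation) -> pd.DataFrame:
    strata = panel.set_index("practice_id")[STRATA]
    p = panel.set_index("practice_id")
    records = workload.compute_workload_records(
        strata, p["imd_quintile"], p["gp_fte"], weights, deprivation)
    records["list_size"] = p["list_size"]
    records.index.name = None
    records["practice_id"] = records.index
    return records


@dataclass
class DevelopmentReport:
    coefficients: CoefficientSet
    simple_coefficients: CoefficientSet
    cv_auc_full: float
    cv_auc_simple: float
    fold_aucs_full: list[float]
    fold_aucs_simple: list[float]
    calibration: pd.DataFrame
    outcome_grid: pd.DataFrame
    cutpoints: dict[str, tuple[float, float]]
    exclusion_logs: dict[str, dict[str, int]]
    undersupply_prevalence: float
    n_practices_model: int
    trim_sensitivity: CoefficientSet | None
    baseline_scores: pd.DataFrame = field(repr=False, default=None)
    followup_scores: pd.DataFrame = field(repr=False, default=None)
    design_matrix: pd.DataFrame = field(repr=False, default=None)
    outcome_status: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.coefficients.to_json(out / "coefficients.json")
        self.simple_coefficients.to_json(out / "coefficients_simple.json")
        self.calibration.to_csv(out / "calibration.csv", index=False)
        (out / "cutpoints.json").write_text(json.dumps(
            {k: list(v) for k, v in self.cutpoints.items()}, indent=2))
        summary = {
            "cv_auc_full": self.cv_auc_full,
            "cv_auc_simple": self.cv_auc_simple,
            "fold_aucs_full": self.fold_aucs_full,
            "fold_aucs_simple": self.fold_aucs_simple,
            "undersupply_prevalence": self.undersupply_prevalence,
            "n_practices_model": self.n_practices_model,
            "exclusion_logs": self.exclusion_logs,
        }
        (out / "development_summary.json").write_text(json.dumps(summary, indent=2))


def run_develop(
    study,
    seed: int = 0,
    trim_fraction: float = workload.TRIM_FRACTION,
    sensitivity_trim: float | None = 0.01,
    weights: workload.WeightTable | None = None,
    deprivation: workload.DeprivationAdjustment | None = None,
    survival: retention.SurvivalTable | None = None,
    item_specs=None,
    n_folds: int = 10,
    baseline_scores: pd.DataFrame | None = None,
    followup_scores: pd.DataFrame | None = None,
) -> DevelopmentReport:
    """Develop the undersupply risk model on a two-wave study."""
    years = sorted(study.rosters)
    y0, y1 = years[0], years[-1]
    deprivation = deprivation or workload.DeprivationAdjustment()
    survival = survival or retention.default_survival_table()
    base_ids = pd.Index(study.baseline_panel["practice_id"])
    if weights is None:
        national = study.baseline_panel.set_index("practice_id")[STRATA].sum(axis=0)
        weights = workload.default_weight_table().normalised(national)

    # case-mix scores for both waves (the slow step; precomputed scores may
    # be passed in)
    if baseline_scores is None:
        baseline_scores = casemix.score_all_items(
            study.gpps_responses[y0], specs=item_specs, all_practices=base_ids)
    if followup_scores is None:
        followup_scores = casemix.score_all_items(
            study.gpps_responses[y1], specs=item_specs,
            all_practices=pd.Index(study.followup_panel["practice_id"]))

    # workload and exclusions per wave
    wl_base = _panel_workload(study.baseline_panel, weights, deprivation)
    wl_fup = _panel_workload(study.followup_panel, weights, deprivation)
    kept_base, log_base = workload.apply_exclusions(wl_base, trim_fraction=trim_fraction)
    kept_fup, log_fup = workload.apply_exclusions(wl_fup, trim_fraction=trim_fraction)

    # follow-up outcome: joint terciles over the post-exclusion national set
    fup_access = practice_scores_wide(followup_scores)["access"] \
        .reindex(kept_fup.index)
    access_t, access_cuts = outcome.tercile_assign(fup_access)
    workload_t, workload_cuts = outcome.tercile_assign(kept_fup["workload_per_fte"])
    status, grid = outcome.classify_undersupply(access_t, workload_t)

    # baseline covariates for practices surviving both waves' exclusions
    retention_est = retention.expected_remaining_demographic(
        study.rosters[y0], survival).set_index("practice_id")
    scores_b = practice_scores_wide(baseline_scores)
    panel_b = study.baseline_panel.set_index("practice_id")
    ids = kept_base.index.intersection(status.index)
    raw = pd.DataFrame({
        "access": scores_b["access"].reindex(ids),
        "continuity": scores_b["continuity"].reindex(ids),
        "satisfaction": scores_b["satisfaction"].reindex(ids),
        "nurse_gp_ratio": (panel_b["nurse_fte"] / panel_b["gp_fte"]).reindex(ids),
        "workload_per_fte": kept_base["workload_per_fte"].reindex(ids),
        "gp_fte": kept_base["gp_fte"].reindex(ids),
        "other_gp_ratio": panel_b["other_gp_ratio"].reindex(ids),
        "rural": panel_b["rural"].reindex(ids),
        "imd_quintile": panel_b["imd_quintile"].reindex(ids),
        "projected_adjusted_list": wl_fup["adjusted_weighted_list"].reindex(ids),
        "prop_remaining": retention_est["expected_remaining"].reindex(ids),
    })
    X = build_design_matrix(raw)
    y = status["undersupply"].reindex(X.index).astype(int)

    spec = ModelSpec(n_folds=n_folds, seed=seed)
    coeffs = fit_risk_model(X, y, spec)
    simple = fit_risk_model(X, y, ModelSpec(covariates=SIMPLE_COVARIATES,
                                            n_folds=n_folds, seed=seed))
    auc_full, folds_full = cross_validated_auroc(X, y, k=n_folds, seed=seed)
    auc_simple, folds_simple = cross_validated_auroc(
        X, y, k=n_folds, seed=seed, covariates=SIMPLE_COVARIATES)
    fitted_p = pd.Series(
        np.asarray(coeffs.linear_predictor(X), dtype=float), index=X.index)
    calib = calibration_by_decile(
        pd.Series(1 / (1 + np.exp(-fitted_p)), index=X.index), y)

    trim_coeffs = None
    if sensitivity_trim is not None:
        kept_s, _ = workload.apply_exclusions(wl_base, trim_fraction=sensitivity_trim)
        kept_fs, _ = workload.apply_exclusions(wl_fup, trim_fraction=sensitivity_trim)
        at, ac = outcome.tercile_assign(
            practice_scores_wide(followup_scores)["access"].reindex(kept_fs.index))
        wt, wc = outcome.tercile_assign(kept_fs["workload_per_fte"])
        status_s, _ = outcome.classify_undersupply(at, wt)
        ids_s = kept_s.index.intersection(status_s.index)
        raw_s = raw.reindex(ids_s.intersection(raw.index))
        extra = ids_s.difference(raw.index)
        if len(extra):  # practices admitted only under the looser trim
            raw_s = pd.concat([raw_s, pd.DataFrame({
                "access": scores_b["access"].reindex(extra),
                "continuity": scores_b["continuity"].reindex(extra),
                "satisfaction": scores_b["satisfaction"].reindex(extra),
                "nurse_gp_ratio": (panel_b["nurse_fte"] / panel_b["gp_fte"]).reindex(extra),
                "workload_per_fte": kept_s["workload_per_fte"].reindex(extra),
                "gp_fte": kept_s["gp_fte"].reindex(extra),
                "other_gp_ratio": panel_b["other_gp_ratio"].reindex(extra),
                "rural": panel_b["rural"].reindex(extra),
                "imd_quintile": panel_b["imd_quintile"].reindex(extra),
                "projected_adjusted_list": wl_fup["adjusted_weighted_list"].reindex(extra),
                "prop_remaining": retention_est["expected_remaining"].reindex(extra),
            })])
        X_s = build_design_matrix(raw_s)
        y_s = status_s["undersupply"].reindex(X_s.index).astype(int)
        trim_coeffs = fit_risk_model(X_s, y_s, spec)

    return DevelopmentReport(
        coefficients=coeffs,
        simple_coefficients=simple,
        cv_auc_full=auc_full,
        cv_auc_simple=auc_simple,
        fold_aucs_full=folds_full,
        fold_aucs_simple=folds_simple,
        calibration=calib,
        outcome_grid=grid,
        cutpoints={"access": access_cuts, "workload_per_fte": workload_cuts},
        exclusion_logs={"baseline": log_base, "followup": log_fup},
        undersupply_prevalence=float(y.mean()),
        n_practices_model=int(len(X)),
        trim_sensitivity=trim_coeffs,
        baseline_scores=baseline_scores,
        followup_scores=followup_scores,
        design_matrix=X,
        outcome_status=status,
    )


@dataclass
class PredictionReport:
    predictions: pd.DataFrame            # practice x scenario rows
    baseline_cutoffs: tuple[float, float]
    rank_correlations: dict[str, float]
    transitions: dict[str, pd.DataFrame]
    retention_spearman: float
    median_risk: float
    retention_method_rank_correlation: float

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(out / "predictions.csv", index=False)
        pd.DataFrame(
            {"scenario": list(self.rank_correlations),
             "spearman_vs_baseline": list(self.rank_correlations.values())}
        ).to_csv(out / "rank_correlations.csv", index=False)
        for label, table in self.transitions.items():
            table.to_csv(out / f"transitions_{label}.csv")
        summary = {
            "baseline_cutoffs": list(self.baseline_cutoffs),
            "median_risk": self.median_risk,
            "retention_methods_spearman": self.retention_spearman,
            "retention_method_rank_correlation":
                self.retention_method_rank_correlation,
        }
        (out / "prediction_summary.json").write_text(json.dumps(summary, indent=2))


def run_predict(
    study,
    coefficients: CoefficientSet,
    scenarios: dict[str, prediction.ScenarioSpec] | None = None,
    region_practices: pd.Index | None = None,
    weights: workload.WeightTable | None = None,
    deprivation: workload.DeprivationAdjustment | None = None,
    survival: retention.SurvivalTable | None = None,
    intention_mapping: retention.IntentionMapping | None = None,
    current_scores: pd.DataFrame | None = None,
    item_specs=None,
    trim_fraction: float = workload.TRIM_FRACTION,
) -> PredictionReport:
    """Score current practices, with projections, under every scenario."""
    scenarios = dict(prediction.STANDARD_SCENARIOS) if scenarios is None else scenarios
    if "baseline" not in scenarios:
        raise DataError("scenario set must include a baseline")
    years = sorted(study.rosters)
    y1 = years[-1]
    panel = study.followup_panel.set_index("practice_id")
    deprivation = deprivation or workload.DeprivationAdjustment()
    survival = survival or retention.default_survival_table()
    intention_mapping = intention_mapping or retention.default_intention_mapping()
    if weights is None:
        weights = workload.default_weight_table().normalised(panel[STRATA].sum(axis=0))

    if current_scores is None:
        current_scores = casemix.score_all_items(
            study.gpps_responses[y1], specs=item_specs,
            all_practices=pd.Index(study.followup_panel["practice_id"]))
    scores = practice_scores_wide(current_scores)

    wl_now = _panel_workload(study.followup_panel, weights, deprivation)
    kept, _ = workload.apply_exclusions(wl_now, trim_fraction=trim_fraction)

    proj_strata = prediction.project_population(
        panel[STRATA], panel["area_id"], study.projections)
    proj_awl = workload.deprivation_adjust(
        workload.compute_weighted_list(proj_strata, weights),
        panel["imd_quintile"], deprivation)

    roster = study.rosters[y1]
    ret_surv = retention.expected_remaining_survey(
        roster, study.intention_survey, intention_mapping, survival
    ).set_index("practice_id")
    ret_demo = retention.expected_remaining_demographic(
        roster, survival).set_index("practice_id")
    ret_rho, _ = retention.compare_retention_methods(
        ret_surv.reset_index(), ret_demo.reset_index())

    ids = kept.index
    if region_practices is not None:
        ids = ids.intersection(region_practices)

    def _raw(method_est):
        return pd.DataFrame({
            "access": scores["access"].reindex(ids),
            "continuity": scores["continuity"].reindex(ids),
            "satisfaction": scores["satisfaction"].reindex(ids),
            "nurse_gp_ratio": (panel["nurse_fte"] / panel["gp_fte"]).reindex(ids),
            "workload_per_fte": kept["workload_per_fte"].reindex(ids),
            "gp_fte": kept["gp_fte"].reindex(ids),
            "other_gp_ratio": panel["other_gp_ratio"].reindex(ids),
            "rural": panel["rural"].reindex(ids),
            "imd_quintile": panel["imd_quintile"].reindex(ids),
            "projected_adjusted_list": proj_awl.reindex(ids),
            "prop_remaining": method_est["expected_remaining"].reindex(ids),
        })

    X_by_method = {
        "survey": build_design_matrix(_raw(ret_surv)),
        "demographic": build_design_matrix(_raw(ret_demo)),
    }
    lp_by_method = {m: coefficients.linear_predictor(X) for m, X in X_by_method.items()}

    base_spec = scenarios["baseline"]
    base_X = X_by_method[base_spec.retention_method]
    base_lp = lp_by_method[base_spec.retention_method]
    base_p = prediction.predict_risk(coefficients, base_X)
    cutoffs = prediction.relative_cutoffs(base_p)
    base_rel = prediction.classify_risk(base_p, "relative")

    rows, rank_corr, transitions = [], {}, {}
    for label, spec_s in scenarios.items():
        X_s = X_by_method[spec_s.retention_method]
        lp_s = lp_by_method[spec_s.retention_method]
        p_s = prediction.apply_scenario(lp_s, X_s, spec_s, coefficients)
        rel = prediction.classify_risk(p_s, "relative")
        ab = prediction.classify_risk(p_s, "absolute", baseline_cutoffs=cutoffs)
        rows.append(pd.DataFrame({
            "practice_id": p_s.index, "scenario": label,
            "probability": p_s.to_numpy(),
            "relative_class": rel.to_numpy(), "absolute_class": ab.to_numpy(),
        }))
        if label != "baseline":
            rho, table = prediction.compare_rankings(base_p, p_s, base_rel, rel)
            rank_corr[label] = rho
            transitions[label] = table

    # the retention-method comparison: baseline prediction swapping survey
    # for demographic retention
    alt_p = prediction.predict_risk(coefficients, X_by_method["demographic"])
    method_rho, _ = prediction.compare_rankings(base_p, alt_p)

    return PredictionReport(
        predictions=pd.concat(rows, ignore_index=True),
        baseline_cutoffs=cutoffs,
        rank_correlations=rank_corr,
        transitions=transitions,
        retention_spearman=ret_rho,
        median_risk=float(base_p.median()),
        retention_method_rank_correlation=method_rho,
    )
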