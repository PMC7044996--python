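"""Development of the logistic undersupply risk model.

The model regresses a binary undersupply outcome at follow-up on baseline
practice covariates: the three case-mix-adjusted survey scores, staffing
ratios, workload per GP FTE, rurality, deprivation quintile, the projected
adjusted weighted list, the expected proportion of GP FTE remaining in
patient care, and its interaction with the nurse/GP ratio. Every covariate
is retained regardless of significance. Discrimination is assessed by
10-fold cross-validated AUROC and calibration by deciles of predicted
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .errors import DataError, FitError

__all__ = [
    "COVARIATE_ORDER", "SIMPLE_COVARIATES", "CoefficientSet", "ModelSpec",
    "build_design_matrix", "fit_risk_model", "cross_validated_auroc",
    "calibration_by_decile", "screen_interactions",
]

#: canonical design-matrix column order (constant last)
COVARIATE_ORDER = [
    "access", "continuity", "satisfaction",
    "nurse_gp_ratio", "workload_per_fte_k", "gp_fte", "other_gp_ratio",
    "rural", "imd_q2", "imd_q3", "imd_q4", "imd_q5",
    "projected_list_k", "prop_remaining", "prop_remaining_x_nurse_ratio",
    "const",
]

#: the two-covariate comparison model: just the outcome-defining factors
SIMPLE_COVARIATES = ["access", "workload_per_fte_k", "const"]

#: raw practice columns the design matrix is built from
RAW_COLUMNS = ["access", "continuity", "satisfaction", "nurse_gp_ratio",
               "workload_per_fte", "gp_fte", "other_gp_ratio", "rural",
               "imd_quintile", "projected_adjusted_list", "prop_remaining"]

#: how raw columns map to covariates; enough to rebuild the linear
#: predictor from raw practice data without ambiguity
TRANSFORMS = {
    "workload_per_fte_k": {"source": "workload_per_fte", "scale": 1e-3,
                           "unit": "per 1000 patients per GP FTE"},
    "projected_list_k": {"source": "projected_adjusted_list", "scale": 1e-3,
                         "unit": "per 1000 patients"},
    "rural": {"source": "rural", "coding": "indicator", "reference": "urban"},
    "imd_q2": {"source": "imd_quintile", "coding": "indicator", "level": 2,
               "reference": 1},
    "imd_q3": {"source": "imd_quintile", "coding": "indicator", "level": 3,
               "reference": 1},
    "imd_q4": {"source": "imd_quintile", "coding": "indicator", "level": 4,
               "reference": 1},
    "imd_q5": {"source": "imd_quintile", "coding": "indicator", "level": 5,
               "reference": 1},
    "prop_remaining_x_nurse_ratio": {
        "source": ["prop_remaining", "nurse_gp_ratio"], "coding": "product"},
}


@dataclass
class ModelSpec:
    """Covariate selection and cross-validation settings."""

    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_ORDER))
    outcome: str = "undersupply"
    n_folds: int = 10
    seed: int = 0


@dataclass
class CoefficientSet:
    """Named logistic coefficients with Wald CIs and transform metadata."""

    table: pd.DataFrame  # index = covariate; columns coef, ci_low, ci_high, p
    transforms: dict = field(default_factory=lambda: dict(TRANSFORMS))

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coef"]

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        beta = self.coefficients
        missing = set(beta.index) - set(X.columns)
        if missing:
            raise DataError(f"design matrix missing covariates: {sorted(missing)}")
        return X[beta.index] @ beta

    def to_json(self, path) -> None:
        payload = {
            "coefficients": {
                name: {"coef": float(r["coef"]), "ci_low": float(r["ci_low"]),
                       "ci_high": float(r["ci_high"]), "p": float(r["p"])}
                for name, r in self.table.iterrows()
            },
            "transforms": self.transforms,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            payload = json.load(fh)
        table = pd.DataFrame(payload["coefficients"]).T
        return cls(table=table, transforms=payload["transforms"])


def build_design_matrix(practice_data: pd.DataFrame,
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """Assemble the design matrix from raw practice columns.

    Complete cases only; incomplete practices are dropped (the count is
    available by comparing index lengths). List-size covariates are
    rescaled to thousands; IMD quintile is dummy-coded with quintile 1
    (least deprived) as reference; rural is an indicator against an urban
    reference; the interaction column is the elementwise product of the
    retention proportion and the nurse/GP ratio.
    """
    covariates = list(COVARIATE_ORDER) if covariates is None else list(covariates)
    df = practice_data
    needed = [c for c in RAW_COLUMNS if c in df.columns]
    for col in RAW_COLUMNS:
        if col not in df.columns:
            raise DataError(f"missing raw column {col!r}")
        if df[col].isna().mean() > 0.5:
            raise DataError(f"covariate {col!r} missing for >50% of practices; "
                            "likely schema mismatch")
    complete = df.dropna(subset=needed)

    X = pd.DataFrame(index=complete.index)
    X["access"] = complete["access"]
    X["continuity"] = complete["continuity"]
    X["satisfaction"] = complete["satisfaction"]
    X["nurse_gp_ratio"] = complete["nurse_gp_ratio"]
    X["workload_per_fte_k"] = complete["workload_per_fte"] / 1000.0
    X["gp_fte"] = complete["gp_fte"]
    X["other_gp_ratio"] = complete["other_gp_ratio"]
    X["rural"] = complete["rural"].astype(float)
    for q in (2, 3, 4, 5):
        X[f"imd_q{q}"] = (complete["imd_quintile"] == q).astype(float)
    X["projected_list_k"] = complete["projected_adjusted_list"] / 1000.0
    X["prop_remaining"] = complete["prop_remaining"]
    X["prop_remaining_x_nurse_ratio"] = X["prop_remaining"] * X["nurse_gp_ratio"]
    X["const"] = 1.0
    return X[covariates]


def fit_risk_model(X: pd.DataFrame, y: pd.Series,
                   spec: ModelSpec | None = None) -> CoefficientSet:
    """Maximum-likelihood logistic fit with Wald 95% intervals.

    A reduced ``spec.covariates`` list gives the simpler comparison model
    through the same operation.
    """
    spec = spec or ModelSpec()
    cols = [c for c in spec.covariates if c in X.columns]
    missing = set(spec.covariates) - set(cols)
    if missing:
        raise DataError(f"covariates not in design matrix: {sorted(missing)}")
    yv = y.reindex(X.index).astype(float)
    if yv.nunique() < 2:
        raise DataError("outcome has a single class; cannot fit")
    try:
        res = sm.Logit(yv, X[cols]).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError(f"logistic fit did not converge: {res.mle_retvals}")
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "coef": res.params, "ci_low": ci[0], "ci_high": ci[1],
        "p": res.pvalues,
    })
    return CoefficientSet(table=table)


def cross_validated_auroc(
    X: pd.DataFrame, y: pd.Series, k: int = 10, seed: int = 0,
    covariates: list[str] | None = None, pool: bool = False,
) -> tuple[float, list[float]]:
    """Mean k-fold cross-validated AUROC plus the per-fold values.

    Folds are simple random splits from the seed. A fold whose training
    part has a single outcome class triggers a refold with a fresh seed
    (up to 5 attempts). ``pool=True`` computes a single AUROC over pooled
    held-out predictions instead of averaging fold AUROCs.
    """
    cols = list(X.columns) if covariates is None else covariates
    Xv = X[cols].to_numpy(dtype=float)
    yv = y.reindex(X.index).to_numpy(dtype=float)
    if len(yv) < k:
        raise DataError(f"n={len(yv)} below fold count k={k}")

    for attempt in range(5):
        folds = list(KFold(n_splits=k, shuffle=True,
                           random_state=seed + attempt).split(Xv))
        if all(len(np.unique(yv[tr])) == 2 and len(np.unique(yv[te])) == 2
               for tr, te in folds):
            break
    else:
        raise DataError("could not form folds with both classes after 5 attempts")

    fold_aucs, pooled_p, pooled_y = [], [], []
    for tr, te in folds:
        # L-BFGS: no hessian inversion, so separable folds still score
        res = sm.Logit(yv[tr], Xv[tr]).fit(disp=0, maxiter=200, method="lbfgs")
        p = expit(Xv[te] @ res.params)
        fold_aucs.append(float(roc_auc_score(yv[te], p)))
        pooled_p.append(p)
        pooled_y.append(yv[te])
    if pool:
        mean_auc = float(roc_auc_score(np.concatenate(pooled_y),
                                       np.concatenate(pooled_p)))
    else:
        mean_auc = float(np.mean(fold_aucs))
    return mean_auc, fold_aucs


def calibration_by_decile(predicted: pd.Series, observed: pd.Series) -> pd.DataFrame:
    """Mean predicted vs observed undersupply fraction by risk decile.

    Deciles are rank-based (stable sort), so tied predictions split into
    equal-count groups rather than collapsing into one.
    """
    if len(predicted) < 10:
        raise DataError("need at least 10 practices for decile calibration")
    p = np.asarray(predicted, dtype=float)
    yv = np.asarray(observed.reindex(predicted.index), dtype=float)
    order = np.argsort(p, kind="mergesort")
    groups = np.array_split(order, 10)
    rows = []
    for d, idx in enumerate(groups, start=1):
        rows.append({
            "decile": d,
            "mean_predicted": float(p[idx].mean()),
            "observed_fraction": float(yv[idx].mean()),
            "count": int(len(idx)),
        })
    return pd.DataFrame(rows)


def screen_interactions(
    X: pd.DataFrame, y: pd.Series,
    base_covariates: list[str],
    moderator: str = "prop_remaining",
    candidates: tuple[str, ...] = ("other_gp_ratio", "access", "nurse_gp_ratio"),
) -> pd.DataFrame:
    """Diagnostic screen: add moderator x candidate interactions in turn.

    Reports the Wald p-value of each interaction when added singly to the
    base model. Purely descriptive — no automated selection.
    """
    rows = []
    for cand in candidates:
        name = f"{moderator}_x_{cand}"
        Xi = X[base_covariates].copy()
        Xi[name] = X[moderator] * X[cand]
        res = sm.Logit(y.reindex(X.index).astype(float), Xi).fit(disp=0, maxiter=200)
        rows.append({"interaction": name, "coef": float(res.params[name]),
                     "p": float(res.pvalues[name])})
    return pd.DataFrame(rows)
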