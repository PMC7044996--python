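"""Forward risk prediction and scenario stress testing.

A fitted coefficient set is applied to current practice data, with the
projected registered population, to give each practice a probability of
being in undersupply five years ahead. Although the outcome was defined
relative to national terciles at development time, applying stored
coefficients treats those cutpoints as absolute: the prediction is the risk
of exceeding the development-period workload cutpoint while falling below
its access cutpoint.

Stress scenarios perturb the fitted model rather than the data: a
recruitment-difficulty scenario adds ``delta_beta_leave`` per unit
proportion of GP FTE expected to leave (so a delta of 2 multiplies a
practice's odds of imbalance by exp(2 x 0.10) = 1.22 when 10% of its
workforce is expected to leave), and a demand scenario inflates the
projected adjusted weighted list by a multiplicative factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .errors import ConfigurationError, DataError, SchemaError
from .model import CoefficientSet
from .strata import STRATA

__all__ = [
    "ScenarioSpec", "STANDARD_SCENARIOS", "project_population", "predict_risk",
    "scenario_odds_multiplier", "apply_scenario", "classify_risk",
    "compare_rankings",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One stress test: a retention-coefficient increment (on the
    proportion-leaving scale) and a list-inflation factor."""

    label: str
    delta_beta_leave: float = 0.0
    list_inflation: float = 1.0
    retention_method: str = "survey"

    def __post_init__(self) -> None:
        if self.list_inflation <= 0:
            raise ConfigurationError(f"scenario {self.label!r}: list_inflation "
                                     "must be > 0")
        if self.retention_method not in ("survey", "demographic"):
            raise ConfigurationError(f"scenario {self.label!r}: unknown "
                                     f"retention_method {self.retention_method!r}")
        if self.label == "baseline" and (self.delta_beta_leave != 0.0
                                         or self.list_inflation != 1.0):
            raise ConfigurationError("baseline scenario must have "
                                     "delta_beta_leave=0 and list_inflation=1")


#: the six standard stress tests: modest/substantial recruitment difficulty
#: (A, B), 20%/40% list growth (C, D) and their combinations (E, F)
STANDARD_SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec("baseline"),
    "A": ScenarioSpec("A", delta_beta_leave=2.0),
    "B": ScenarioSpec("B", delta_beta_leave=4.0),
    "C": ScenarioSpec("C", list_inflation=1.2),
    "D": ScenarioSpec("D", list_inflation=1.4),
    "E": ScenarioSpec("E", delta_beta_leave=2.0, list_inflation=1.2),
    "F": ScenarioSpec("F", delta_beta_leave=4.0, list_inflation=1.4),
}


def project_population(strata_counts: pd.DataFrame, practice_area: pd.Series,
                       projections: pd.DataFrame) -> pd.DataFrame:
    """Scale each practice's strata by its area's projected growth ratios.

    The practice's share of its area's population is held constant. Areas
    with a missing or zero-baseline stratum ratio are treated as ratio 1.
    ``projections`` is long-form (area_id, stratum, growth_ratio).
    """
    areas = practice_area.reindex(strata_counts.index)
    if areas.isna().any():
        raise DataError("every practice must map to one area")
    ratio_wide = projections.pivot(index="area_id", columns="stratum",
                                   values="growth_ratio")
    missing_cols = set(STRATA) - set(ratio_wide.columns)
    if missing_cols & set(strata_counts.columns):
        raise SchemaError(f"projection strata missing: {sorted(missing_cols)[:4]}")
    ratios = ratio_wide.reindex(index=areas.to_numpy(),
                                columns=strata_counts.columns).fillna(1.0)
    ratios[ratios <= 0] = 1.0
    return strata_counts * ratios.to_numpy()


def predict_risk(coefficients: CoefficientSet, X: pd.DataFrame) -> pd.Series:
    """Inverse-logit of the linear predictor under the stored transforms."""
    lp = coefficients.linear_predictor(X)
    return pd.Series(expit(lp), index=X.index, name="probability")


def scenario_odds_multiplier(delta_beta_leave: float,
                             proportion_leaving: float) -> float:
    """Factor by which a practice's odds of imbalance change.

    ``exp(delta x proportion leaving)``: a delta of 2 with 10% of GP FTE
    expected to leave multiplies the odds by exp(0.2) ~ 1.22.
    """
    if not (0.0 <= proportion_leaving <= 1.0):
        raise DataError("proportion_leaving must lie in [0, 1]")
    return float(np.exp(delta_beta_leave * proportion_leaving))


def apply_scenario(
    baseline_lp: pd.Series,
    covariates: pd.DataFrame,
    spec: ScenarioSpec,
    coefficients: CoefficientSet,
) -> pd.Series:
    """Scenario-adjusted probabilities from baseline linear predictors.

    The linear predictor shifts by ``delta_beta_leave x (1 - proportion
    remaining)`` and by the projected-list coefficient times the covariate
    increment implied by the inflation factor.
    """
    lp = baseline_lp.copy()
    if spec.delta_beta_leave != 0.0:
        lp = lp + spec.delta_beta_leave * (1.0 - covariates["prop_remaining"])
    if spec.list_inflation != 1.0:
        beta_proj = float(coefficients.coefficients["projected_list_k"])
        lp = lp + beta_proj * covariates["projected_list_k"] * (spec.list_inflation - 1.0)
    return pd.Series(expit(lp), index=baseline_lp.index, name="probability")


def classify_risk(
    probabilities: pd.Series,
    mode: str = "relative",
    baseline_cutoffs: tuple[float, float] | None = None,
) -> pd.Series:
    """High / moderate / low risk classes.

    Relative mode flags the top quartile within the scenario as high and
    the bottom quartile as low. Absolute mode applies stored probability
    cutoffs from the baseline scenario: high at or above the baseline 75th
    percentile, low at or below the baseline 25th.
    """
    if len(probabilities) < 4:
        raise DataError("need at least 4 practices to classify risk")
    if mode == "relative":
        lo, hi = (float(q) for q in np.quantile(probabilities, [0.25, 0.75]))
    elif mode == "absolute":
        if baseline_cutoffs is None:
            raise DataError("absolute mode requires baseline cutoffs")
        lo, hi = baseline_cutoffs
    else:
        raise ConfigurationError(f"unknown classification mode {mode!r}")
    cls = np.where(probabilities >= hi, "high",
                   np.where(probabilities <= lo, "low", "moderate"))
    return pd.Series(cls, index=probabilities.index, name=f"{mode}_class")


def relative_cutoffs(probabilities: pd.Series) -> tuple[float, float]:
    """The 25th/75th percentile cutoffs a scenario's relative classes use."""
    lo, hi = np.quantile(probabilities, [0.25, 0.75])
    return float(lo), float(hi)


def compare_rankings(
    baseline: pd.Series, scenario: pd.Series,
    baseline_classes: pd.Series | None = None,
    scenario_classes: pd.Series | None = None,
) -> tuple[float, pd.DataFrame | None]:
    """Spearman rank correlation plus a class-transition table."""
    shared = baseline.index.intersection(scenario.index)
    if len(shared) != len(baseline) or len(shared) != len(scenario):
        raise DataError("mismatched practice ids between prediction sets")
    rho = float(spearmanr(baseline.loc[shared], scenario.loc[shared]).statistic)
    table = None
    if baseline_classes is not None and scenario_classes is not None:
        order = ["low", "moderate", "high"]
        table = pd.crosstab(baseline_classes.loc[shared],
                            scenario_classes.loc[shared]).reindex(
            index=order, columns=order, fill_value=0)
    return rho, table
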