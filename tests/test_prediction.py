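"""Forward prediction, scenario algebra and risk classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gprisk.errors import ConfigurationError, DataError
from gprisk.model import CoefficientSet, COVARIATE_ORDER
from gprisk.prediction import (STANDARD_SCENARIOS, ScenarioSpec,
                               apply_scenario, classify_risk,
                               compare_rankings, predict_risk,
                               project_population, relative_cutoffs,
                               scenario_odds_multiplier)
from gprisk.strata import STRATA


def _coeffs(values: dict[str, float]) -> CoefficientSet:
    table = pd.DataFrame({"coef": pd.Series(values)})
    table["ci_low"] = table["coef"] - 0.1
    table["ci_high"] = table["coef"] + 0.1
    table["p"] = 0.05
    return CoefficientSet(table=table)


def test_scenario_odds_multiplier_printed_equivalences():
    assert scenario_odds_multiplier(2.0, 0.10) == pytest.approx(1.2214, abs=1e-4)
    assert scenario_odds_multiplier(4.0, 0.10) == pytest.approx(1.4918, abs=1e-4)
    assert scenario_odds_multiplier(17.0, 0.0) == 1.0


def test_scenario_spec_validation():
    with pytest.raises(ConfigurationError, match="list_inflation"):
        ScenarioSpec("X", list_inflation=0.0)
    with pytest.raises(ConfigurationError, match="baseline"):
        ScenarioSpec("baseline", delta_beta_leave=1.0)
    with pytest.raises(ConfigurationError, match="retention_method"):
        ScenarioSpec("X", retention_method="astrology")


def test_standard_scenarios_compose_a_c_and_b_d():
    s = STANDARD_SCENARIOS
    assert s["E"].delta_beta_leave == s["A"].delta_beta_leave
    assert s["E"].list_inflation == s["C"].list_inflation
    assert s["F"].delta_beta_leave == s["B"].delta_beta_leave
    assert s["F"].list_inflation == s["D"].list_inflation


def _strata_frame():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(50, 300, (4, len(STRATA))),
                      index=[f"P{i}" for i in range(4)], columns=STRATA)
    return df


def test_project_population_identity_and_scaling():
    strata = _strata_frame()
    areas = pd.Series("A1", index=strata.index)
    proj_unit = pd.DataFrame({"area_id": "A1", "stratum": STRATA,
                              "growth_ratio": 1.0})
    assert np.allclose(project_population(strata, areas, proj_unit), strata)
    proj = proj_unit.copy()
    proj["growth_ratio"] = 1.1
    out = project_population(strata, areas, proj)
    assert np.allclose(out, strata * 1.1)


def test_projection_aggregates_by_area_ratio():
    """When all practices share the area's structure, area totals grow by
    the aggregate ratio."""
    strata = pd.DataFrame(100, index=["P1", "P2", "P3"], columns=STRATA)
    areas = pd.Series("A1", index=strata.index)
    rng = np.random.default_rng(1)
    ratios = rng.uniform(0.9, 1.2, len(STRATA))
    proj = pd.DataFrame({"area_id": "A1", "stratum": STRATA,
                         "growth_ratio": ratios})
    out = project_population(strata, areas, proj)
    agg_ratio = out.sum(axis=1) / strata.sum(axis=1)
    assert np.allclose(agg_ratio, ratios.mean())


def test_predict_risk_matches_closed_form_constant():
    """With every covariate at zero, probability = inverse-logit of the
    constant: expit(-4.15) ~ 0.0155."""
    coeffs = _coeffs({c: 0.0 for c in COVARIATE_ORDER} | {"const": -4.15,
                                                          "access": -0.96})
    X = pd.DataFrame(0.0, index=["P1"], columns=COVARIATE_ORDER)
    X["const"] = 1.0
    p = predict_risk(coeffs, X)
    assert p.iloc[0] == pytest.approx(1 / (1 + np.exp(4.15)), abs=1e-6)
    assert p.iloc[0] == pytest.approx(0.0155, abs=5e-4)
    # a better (higher) access score lowers risk under its negative weight
    X_better = X.copy()
    X_better["access"] = 1.0
    assert predict_risk(coeffs, X_better).iloc[0] < p.iloc[0]
    with pytest.raises(DataError, match="access"):
        predict_risk(coeffs, X.drop(columns=["access"]))


def _baseline(n=100, seed=2):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"P{i:03d}" for i in range(n)])
    cov = pd.DataFrame({
        "prop_remaining": rng.uniform(0.5, 0.95, n),
        "projected_list_k": rng.uniform(4, 14, n),
    }, index=idx)
    lp = pd.Series(rng.normal(-2.5, 1.0, n), index=idx)
    return lp, cov


def test_baseline_scenario_reproduces_probabilities_exactly():
    lp, cov = _baseline()
    coeffs = _coeffs({"projected_list_k": 0.14})
    p0 = pd.Series(expit(lp), index=lp.index)
    p = apply_scenario(lp, cov, ScenarioSpec("baseline"), coeffs)
    assert np.allclose(p, p0, atol=1e-12)


def test_scenario_a_odds_ratio_identity():
    """odds(A)/odds(baseline) = exp(2 x proportion leaving), per practice."""
    lp, cov = _baseline()
    coeffs = _coeffs({"projected_list_k": 0.14})
    p0 = pd.Series(expit(lp), index=lp.index)
    pA = apply_scenario(lp, cov, STANDARD_SCENARIOS["A"], coeffs)
    odds_ratio = (pA / (1 - pA)) / (p0 / (1 - p0))
    expected = np.exp(2.0 * (1.0 - cov["prop_remaining"]))
    assert np.allclose(odds_ratio, expected, rtol=1e-9)


def test_scenario_log_odds_decomposition():
    lp, cov = _baseline(seed=5)
    beta_proj = 0.14
    coeffs = _coeffs({"projected_list_k": beta_proj})
    spec = ScenarioSpec("F", delta_beta_leave=4.0, list_inflation=1.4)
    p = apply_scenario(lp, cov, spec, coeffs)
    shift = np.log(p / (1 - p)) - lp
    expected = (4.0 * (1 - cov["prop_remaining"])
                + beta_proj * cov["projected_list_k"] * 0.4)
    assert np.allclose(shift, expected, atol=1e-9)


def test_list_inflation_shifts_covariate_by_twenty_percent():
    lp, cov = _baseline(seed=6)
    coeffs = _coeffs({"projected_list_k": 0.14})
    p = apply_scenario(lp, cov, STANDARD_SCENARIOS["C"], coeffs)
    shift = np.log(p / (1 - p)) - lp
    assert np.allclose(shift, 0.14 * cov["projected_list_k"] * 0.2, atol=1e-9)


def test_relative_classification_quartile_counts():
    p = pd.Series(np.linspace(0.01, 0.99, 100),
                  index=[f"P{i}" for i in range(100)])
    cls = classify_risk(p, "relative")
    assert (cls == "high").sum() == 25
    assert (cls == "low").sum() == 25
    assert (cls == "moderate").sum() == 50


def test_baseline_absolute_equals_relative():
    rng = np.random.default_rng(7)
    p = pd.Series(rng.uniform(0.01, 0.5, 200))
    rel = classify_risk(p, "relative")
    ab = classify_risk(p, "absolute", baseline_cutoffs=relative_cutoffs(p))
    assert (rel == ab).all()


def test_uniform_shift_keeps_relative_moves_absolute():
    rng = np.random.default_rng(8)
    lp = pd.Series(rng.normal(-2.5, 1.0, 200))
    p0 = pd.Series(expit(lp), index=lp.index)
    p1 = pd.Series(expit(lp + 0.8), index=lp.index)
    cuts = relative_cutoffs(p0)
    assert (classify_risk(p0, "relative") == classify_risk(p1, "relative")).all()
    high0 = (classify_risk(p0, "absolute", baseline_cutoffs=cuts) == "high").sum()
    high1 = (classify_risk(p1, "absolute", baseline_cutoffs=cuts) == "high").sum()
    assert high1 >= high0


def test_classify_risk_needs_four_practices():
    with pytest.raises(DataError, match="4"):
        classify_risk(pd.Series([0.1, 0.2, 0.3]), "relative")


def test_compare_rankings_identity_and_reversal():
    p = pd.Series(np.linspace(0.1, 0.9, 50), index=[f"P{i}" for i in range(50)])
    cls = classify_risk(p, "relative")
    rho, table = compare_rankings(p, p, cls, cls)
    assert rho == pytest.approx(1.0)
    assert table.to_numpy().sum() == np.diag(table).sum()
    rev = pd.Series(p.to_numpy()[::-1], index=p.index)
    assert compare_rankings(p, rev)[0] == pytest.approx(-1.0)
    with pytest.raises(DataError, match="mismatch"):
        compare_rankings(p, p.iloc[:10])
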