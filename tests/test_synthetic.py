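"""Generator contracts: determinism, linkage, known-truth structure."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

import gprisk
from gprisk.errors import ConfigurationError
from gprisk.strata import STRATA
from gprisk.synthetic import (SyntheticConfig, Truth, generate_gpps_responses,
                              generate_intention_survey, generate_panel)


def _mini_truth(effects: dict[str, float], remain: pd.Series | None = None,
                casemix_effects=None, intercepts=None) -> Truth:
    ids = list(effects)
    eff = pd.DataFrame({item: [effects[p] for p in ids]
                        for item in ("access", "continuity", "satisfaction")},
                       index=ids)
    from gprisk.synthetic import DEFAULT_CASEMIX_EFFECTS, DEFAULT_ITEM_INTERCEPTS
    return Truth(
        coefficients={}, item_intercepts=intercepts or DEFAULT_ITEM_INTERCEPTS,
        casemix_effects=casemix_effects or DEFAULT_CASEMIX_EFFECTS,
        practice_effects_baseline=eff, practice_effects_followup=eff,
        gp_remain_probability=remain if remain is not None else pd.Series(dtype=float),
        prop_remaining=pd.Series(dtype=float), design_matrix=pd.DataFrame(),
        undersupply_probability=pd.Series(dtype=float),
        undersupply=pd.Series(dtype=int))


def test_fixed_seed_reproduces_study_exactly(small_study):
    again = generate_panel(small_study.config)
    assert_frame_equal(small_study.baseline_panel, again.baseline_panel)
    assert_frame_equal(small_study.followup_panel, again.followup_panel)
    for year in small_study.gpps_responses:
        assert_frame_equal(small_study.gpps_responses[year],
                           again.gpps_responses[year])
    assert_frame_equal(small_study.intention_survey, again.intention_survey)
    assert (small_study.truth.undersupply == again.truth.undersupply).all()


def test_strata_are_nonnegative_integers_summing_to_list_size(small_study):
    for panel in (small_study.baseline_panel, small_study.followup_panel):
        counts = panel[STRATA]
        assert (counts >= 0).all().all()
        assert (counts.to_numpy() == counts.to_numpy().astype(int)).all()
        assert (counts.sum(axis=1) == panel["list_size"]).all()


def test_followup_practices_all_exist_at_baseline(small_study):
    assert set(small_study.followup_panel["practice_id"]) <= \
        set(small_study.baseline_panel["practice_id"])


@pytest.mark.parametrize("field, value", [
    ("n_practices", 5),
    ("rural_fraction", 1.5),
    ("survey_response_rate", -0.1),
    ("list_size_log_sd", 0.0),
    ("imd_distribution", (21.0, -1.0)),
])
def test_invalid_config_names_the_field(field, value):
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        SyntheticConfig(**{field: value})


def test_unknown_true_coefficient_name_rejected():
    with pytest.raises(ConfigurationError, match="true_model_coefficients"):
        SyntheticConfig(true_model_coefficients={"not_a_covariate": 1.0})


def test_uniform_dirichlet_gives_equal_mean_stratum_shares():
    cfg = SyntheticConfig(n_practices=2000, strata_dirichlet_alpha=5.0,
                          gpps_respondents_per_practice=0, seed=2)
    study = generate_panel(cfg)
    shares = study.baseline_panel[STRATA].div(
        study.baseline_panel["list_size"], axis=0).mean(axis=0)
    # law of large numbers: mean share per cell ~ 1/36
    assert np.allclose(shares, 1.0 / len(STRATA), atol=0.004)


def test_zero_coefficients_leave_followup_independent_of_baseline():
    """With no true signal the latent outcome is coin-flip-from-constant:
    its correlation with every baseline covariate is Monte-Carlo small."""
    cfg = SyntheticConfig(
        n_practices=2000, gpps_respondents_per_practice=0, seed=3,
        true_model_coefficients={"const": -2.0})
    study = generate_panel(cfg)
    X, u = study.truth.design_matrix, study.truth.undersupply
    for col in X.columns:
        if col == "const":
            continue
        r = np.corrcoef(X[col], u.reindex(X.index))[0, 1]
        assert abs(r) < 0.08, f"{col} correlates with null outcome (r={r:.3f})"


def test_prevalence_rises_with_coefficient_magnitude():
    """Scaling all slope coefficients up raises undersupply prevalence
    (the constant sits far in the convex tail of the logistic)."""
    means = []
    for scale in (0.0, 1.0, 2.0):
        prevs = []
        for rep in range(10):
            beta = {k: v * scale for k, v in
                    gprisk.synthetic.DEFAULT_TRUE_COEFFICIENTS.items()}
            beta["const"] = -4.15
            cfg = SyntheticConfig(n_practices=200,
                                  gpps_respondents_per_practice=0,
                                  seed=100 + rep, true_model_coefficients=beta)
            prevs.append(generate_panel(cfg).truth.undersupply.mean())
        means.append(np.mean(prevs))
    assert means[0] < means[1] < means[2]


def test_gpps_item_rate_matches_logistic_intercept():
    """Zero practice effect + zero covariate effects: the positive-response
    rate equals the inverse-logit of the item intercept."""
    null_eff = {k: {kk: 0.0 for kk in v}
                for k, v in gprisk.synthetic.DEFAULT_CASEMIX_EFFECTS.items()}
    truth = _mini_truth({"P1": 0.0}, casemix_effects=null_eff,
                        intercepts={"access": 1.3, "continuity": 0.4,
                                    "satisfaction": 1.6})
    panel = pd.DataFrame({"practice_id": ["P1"], "imd_quintile": [3]})
    resp = generate_gpps_responses(panel, truth, 42,
                                   respondents_per_practice=100_000)
    from gprisk.casemix import DEFAULT_ITEM_SPECS, dichotomise_item
    for item, intercept in truth.item_intercepts.items():
        frac = dichotomise_item(resp, DEFAULT_ITEM_SPECS[item])["outcome"].mean()
        expected = 1 / (1 + np.exp(-intercept))
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / len(resp))


def test_gpps_practice_effect_difference_recovered():
    """Two practices with true effects +1/-1 differ by ~2 observed log-odds."""
    null_eff = {k: {kk: 0.0 for kk in v}
                for k, v in gprisk.synthetic.DEFAULT_CASEMIX_EFFECTS.items()}
    truth = _mini_truth({"Phi": 1.0, "Plo": -1.0}, casemix_effects=null_eff)
    panel = pd.DataFrame({"practice_id": ["Phi", "Plo"], "imd_quintile": [3, 3]})
    resp = generate_gpps_responses(panel, truth, 7,
                                   respondents_per_practice=50_000)
    from gprisk.casemix import DEFAULT_ITEM_SPECS, dichotomise_item
    binary = dichotomise_item(resp, DEFAULT_ITEM_SPECS["access"])
    rates = binary.groupby("practice_id")["outcome"].mean()
    logodds = np.log(rates / (1 - rates))
    assert abs((logodds["Phi"] - logodds["Plo"]) - 2.0) < 0.1


def test_gpps_zero_respondents_keeps_schema():
    truth = _mini_truth({"P1": 0.0})
    panel = pd.DataFrame({"practice_id": ["P1"], "imd_quintile": [3]})
    resp = generate_gpps_responses(panel, truth, 1, respondents_per_practice=0)
    assert resp.empty
    assert "access" in resp.columns and "deprivation_quintile" in resp.columns


@pytest.mark.parametrize("rate, expect_all, expect_none", [
    (1.0, True, False), (0.0, False, True),
])
def test_intention_survey_response_rate_extremes(toy_roster, rate,
                                                 expect_all, expect_none):
    remain = pd.Series(0.8, index=toy_roster["gp_id"])
    truth = _mini_truth({"P1": 0.0}, remain=remain)
    survey = generate_intention_survey(toy_roster, truth, rate, 9)
    if expect_all:
        assert survey["responded"].all()
        assert survey["intention"].notna().all()
    if expect_none:
        assert not survey["responded"].any()
        assert survey["intention"].isna().all()


def test_intention_survey_responder_count_is_binomial():
    """A census of 3370 GPs at 67% response yields ~2258 responders
    (binomial sd ~27)."""
    n = 3370
    roster = pd.DataFrame({
        "practice_id": "P1", "gp_id": [f"g{i}" for i in range(n)],
        "age": 45.0, "gender": "F", "fte": 1.0, "role": "partner"})
    remain = pd.Series(0.8, index=roster["gp_id"])
    truth = _mini_truth({"P1": 0.0}, remain=remain)
    survey = generate_intention_survey(roster, truth, 0.67, 13)
    assert abs(survey["responded"].sum() - 0.67 * n) < 4 * np.sqrt(n * 0.67 * 0.33)


def test_write_and_load_roundtrip(tmp_path, small_study):
    from gprisk.pipeline import load_study
    small_study.write(tmp_path)
    loaded = load_study(tmp_path)
    assert_frame_equal(
        loaded.baseline_panel, small_study.baseline_panel,
        check_dtype=False)
    assert len(loaded.intention_survey) == len(small_study.intention_survey)
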