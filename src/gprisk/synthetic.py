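"""Seeded synthetic practice panels with known ground truth.

The generator emulates the tables a practice-level supply-demand analysis
consumes: two linked panel waves (registered populations by gender x 5-year
age band, staffing, deprivation, rurality), individual GP rosters, a
respondent-level patient survey with case-mix covariates, a GP
career-intention survey and area-level population projections.

The forward model inverts the structure the development model assumes:
each practice's baseline covariates are pushed through a logistic linear
predictor with known ("true") coefficients to draw a latent undersupply
indicator; follow-up access scores and workload are then generated around
that indicator, so the tercile-based pipeline outcome carries recoverable
signal while zero true coefficients leave follow-up independent of
baseline. The ``Truth`` record retains everything needed for parameter
recovery: practice random effects, per-GP leave probabilities, the exact
design matrix and the drawn outcomes.

All randomness descends from one root seed through named substreams, one
per table, so the generated study is byte-identical under a fixed seed and
adding draws to one table never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import model as model_mod
from . import retention as retention_mod
from . import workload as workload_mod
from ._rng import substream
from .casemix import DEFAULT_ITEM_SPECS
from .errors import ConfigurationError
from .strata import AGE_MIDPOINTS, STRATA, stratum_age_band

__all__ = ["SyntheticConfig", "SyntheticStudy", "Truth", "generate_panel",
           "generate_gpps_responses", "generate_intention_survey",
           "DEFAULT_TRUE_COEFFICIENTS"]

#: generating coefficients for the forward model; magnitudes chosen to be
#: realistic for practice-level undersupply risk (worse access, higher
#: workload and more deprived populations raise risk; larger GP teams
#: lower it)
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "access": -0.96, "continuity": -0.09, "satisfaction": -0.48,
    "nurse_gp_ratio": 1.02, "workload_per_fte_k": 0.40, "gp_fte": -0.17,
    "other_gp_ratio": 0.65, "rural": -0.13,
    "imd_q2": 0.02, "imd_q3": 0.13, "imd_q4": 0.57, "imd_q5": 0.36,
    "projected_list_k": 0.14, "prop_remaining": 0.38,
    "prop_remaining_x_nurse_ratio": -1.01, "const": -4.15,
}

#: respondent age bands used in the patient survey (adults only)
RESPONDENT_AGE_BANDS = ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+"]

#: true case-mix fixed effects on the logit scale, shared by all items
DEFAULT_CASEMIX_EFFECTS = {
    "age_band": {b: 0.08 * i for i, b in enumerate(RESPONDENT_AGE_BANDS)},
    "gender": {"F": 0.0, "M": 0.05},
    "ethnicity": {"white": 0.0, "minority": -0.30},
    "long_term_condition": {0: 0.0, 1: -0.20},
    "deprivation_quintile": {q: -0.08 * (q - 1) for q in range(1, 6)},
}

DEFAULT_ITEM_INTERCEPTS = {"access": 1.3, "continuity": 0.4, "satisfaction": 1.6}

GP_ROLES = ["partner", "salaried", "registrar", "retainer", "other"]
GP_ROLE_WEIGHTS = [0.45, 0.30, 0.10, 0.05, 0.10]

# follow-up score construction around the latent undersupply indicator
ITEM_UNDERSUPPLY_SHIFT = {"access": -1.1, "continuity": -0.5, "satisfaction": -0.7}
WORKLOAD_UNDERSUPPLY_SHIFT = 0.9   # on log workload-per-FTE
WORKLOAD_LOG_SD = 0.30
ITEM_CORR = 0.6


def _default_strata_alpha() -> pd.Series:
    """Age-pyramid-shaped Dirichlet concentrations, total ~60."""
    shares = {}
    for s in STRATA:
        a = AGE_MIDPOINTS[stratum_age_band(s)]
        shares[s] = np.exp(-((a - 38.0) / 55.0) ** 2)
    v = pd.Series(shares).reindex(STRATA)
    return 60.0 * v / v.sum()


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_practices: int = 300
    baseline_year: int = 2012
    followup_year: int = 2016
    list_size_log_mean: float = float(np.log(7000.0))
    list_size_log_sd: float = 0.55
    strata_dirichlet_alpha: float | pd.Series | None = None  # None -> pyramid
    gp_per_1000_mean: float = 0.60
    nurse_ratio_mean: float = 0.50
    imd_distribution: tuple[float, float] = (21.0, 8.0)  # mean, sd of IMD score
    rural_fraction: float = 0.33
    true_model_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS))
    gpps_respondents_per_practice: float = 125.0
    survey_response_rate: float = 0.67
    n_areas: int = 8
    practice_effect_sd: float = 0.35
    bad_fte_rate: float = 0.005  # corrupt staffing records (<0.5 FTE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_practices < 10:
            raise ConfigurationError("n_practices must be >= 10")
        for fld in ("rural_fraction", "survey_response_rate", "bad_fte_rate"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{fld} must lie in [0, 1], got {v}")
        for fld in ("list_size_log_sd", "gp_per_1000_mean", "nurse_ratio_mean",
                    "practice_effect_sd"):
            if getattr(self, fld) <= 0:
                raise ConfigurationError(f"{fld} must be positive")
        if self.gpps_respondents_per_practice < 0:
            raise ConfigurationError("gpps_respondents_per_practice must be >= 0")
        mean, sd = self.imd_distribution
        if mean <= 0 or sd <= 0:
            raise ConfigurationError("imd_distribution mean and sd must be positive")
        unknown = set(self.true_model_coefficients) - set(model_mod.COVARIATE_ORDER)
        if unknown:
            raise ConfigurationError(
                f"true_model_coefficients has unknown names: {sorted(unknown)}")

    def alpha_vector(self) -> pd.Series:
        a = self.strata_dirichlet_alpha
        if a is None:
            return _default_strata_alpha()
        if np.isscalar(a):
            if a <= 0:
                raise ConfigurationError("strata_dirichlet_alpha must be positive")
            return pd.Series(float(a), index=STRATA)
        vec = pd.Series(a).reindex(STRATA)
        if vec.isna().any() or (vec <= 0).any():
            raise ConfigurationError(
                "strata_dirichlet_alpha must cover all strata with positive values")
        return vec


@dataclass
class Truth:
    """Generating parameters retained for parameter-recovery checks."""

    coefficients: dict[str, float]
    item_intercepts: dict[str, float]
    casemix_effects: dict
    practice_effects_baseline: pd.DataFrame   # practice_id x item log-odds
    practice_effects_followup: pd.DataFrame
    gp_remain_probability: pd.Series          # per gp_id
    prop_remaining: pd.Series                 # per practice, FTE-weighted
    design_matrix: pd.DataFrame               # true baseline covariates
    undersupply_probability: pd.Series
    undersupply: pd.Series                    # latent Bernoulli draw


@dataclass
class SyntheticStudy:
    """Two linked panel waves plus surveys, projections and ground truth."""

    config: SyntheticConfig
    baseline_panel: pd.DataFrame
    followup_panel: pd.DataFrame
    rosters: dict[int, pd.DataFrame]          # year -> roster
    gpps_responses: dict[int, pd.DataFrame]   # year -> respondent table
    intention_survey: pd.DataFrame
    projections: pd.DataFrame                 # area_id, stratum, growth_ratio
    truth: Truth

    def write(self, outdir: str | Path) -> None:
        """Write every table as CSV and the truth record as JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline_panel.to_csv(out / "panel_baseline.csv", index=False)
        self.followup_panel.to_csv(out / "panel_followup.csv", index=False)
        for year, roster in self.rosters.items():
            roster.to_csv(out / f"roster_{year}.csv", index=False)
        for year, resp in self.gpps_responses.items():
            resp.to_csv(out / f"gpps_responses_{year}.csv", index=False)
        self.intention_survey.to_csv(out / "intention_survey.csv", index=False)
        self.projections.to_csv(out / "projections.csv", index=False)
        truth = {
            "coefficients": self.truth.coefficients,
            "item_intercepts": self.truth.item_intercepts,
            "prop_remaining": self.truth.prop_remaining.round(6).to_dict(),
            "undersupply": {k: int(v) for k, v in self.truth.undersupply.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _draw_practice_effects(rng: np.random.Generator, practice_ids, sd: float,
                           mean: np.ndarray | None = None) -> pd.DataFrame:
    items = list(DEFAULT_ITEM_INTERCEPTS)
    k = len(items)
    cov = sd ** 2 * (ITEM_CORR * np.ones((k, k)) + (1 - ITEM_CORR) * np.eye(k))
    draws = rng.multivariate_normal(np.zeros(k), cov, size=len(practice_ids))
    if mean is not None:
        draws = draws + mean
    return pd.DataFrame(draws, index=practice_ids, columns=items)


def generate_panel(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study from one seeded configuration."""
    seed = config.seed
    ids = [f"P{i:05d}" for i in range(config.n_practices)]
    idx = pd.Index(ids, name="practice_id")

    # --- baseline practice structure -------------------------------------
    rng = substream(seed, "practices")
    area_ids = [f"A{i:02d}" for i in rng.integers(0, config.n_areas, config.n_practices)]
    list_size = np.maximum(
        800, rng.lognormal(config.list_size_log_mean, config.list_size_log_sd,
                           config.n_practices)).astype(int)
    imd_mean, imd_sd = config.imd_distribution
    sigma2 = np.log(1 + (imd_sd / imd_mean) ** 2)
    imd_score = rng.lognormal(np.log(imd_mean) - sigma2 / 2, np.sqrt(sigma2),
                              config.n_practices)
    quint_cuts = np.quantile(imd_score, [0.2, 0.4, 0.6, 0.8])
    imd_quintile = 1 + np.searchsorted(quint_cuts, imd_score)
    rural = (rng.random(config.n_practices) < config.rural_fraction).astype(int)

    rng_s = substream(seed, "strata")
    alpha = config.alpha_vector().to_numpy()
    strata_counts = np.vstack([
        rng_s.multinomial(n, rng_s.dirichlet(alpha)) for n in list_size])
    strata_df = pd.DataFrame(strata_counts, index=idx, columns=STRATA)

    rng_w = substream(seed, "staffing")
    density = rng_w.lognormal(np.log(config.gp_per_1000_mean), 0.25,
                              config.n_practices)
    gp_fte = list_size * density / 1000.0
    bad = rng_w.random(config.n_practices) < config.bad_fte_rate
    gp_fte[bad] = rng_w.uniform(0.05, 0.45, bad.sum())
    nurse_ratio = np.maximum(0.05, rng_w.normal(config.nurse_ratio_mean, 0.15,
                                                config.n_practices))
    nurse_fte = gp_fte * nurse_ratio

    roster_b = _generate_roster(substream(seed, "roster"), ids, gp_fte,
                                config.baseline_year)
    other_fte = roster_b.loc[roster_b["role"] == "other"].groupby("practice_id")["fte"].sum()
    other_ratio = (other_fte.reindex(idx).fillna(0.0) / gp_fte).to_numpy()

    # --- true retention ---------------------------------------------------
    rng_r = substream(seed, "retention")
    surv = retention_mod.default_survival_table()
    base_p = surv.lookup_many(roster_b["gender"], roster_b["age"])
    noise = rng_r.normal(0, 0.3, len(roster_b))
    gp_remain = pd.Series(
        expit(np.log(base_p / (1 - base_p)) + noise).to_numpy(),
        index=pd.Index(roster_b["gp_id"], name="gp_id"))
    remain_by_row = gp_remain.to_numpy()
    prop_remaining = pd.Series(
        (remain_by_row * roster_b["fte"].to_numpy()),
        index=roster_b["practice_id"]).groupby(level=0).sum() \
        / roster_b.groupby("practice_id")["fte"].sum()
    prop_remaining = prop_remaining.reindex(idx)

    # --- projections and follow-up populations ---------------------------
    rng_p = substream(seed, "projections")
    proj_rows = []
    for area in sorted(set(area_ids)):
        base_growth = rng_p.normal(1.06, 0.03)
        for s in STRATA:
            age = AGE_MIDPOINTS[stratum_age_band(s)]
            ratio = base_growth * (1.0 + 0.0012 * (age - 40.0)) \
                + rng_p.normal(0, 0.01)
            proj_rows.append({"area_id": area, "stratum": s,
                              "growth_ratio": float(np.clip(ratio, 0.85, 1.35))})
    projections = pd.DataFrame(proj_rows)
    ratio_wide = projections.pivot(index="area_id", columns="stratum",
                                   values="growth_ratio")[STRATA]
    fu_strata = np.rint(strata_df.to_numpy()
                        * ratio_wide.loc[area_ids].to_numpy()).astype(int)
    fu_strata_df = pd.DataFrame(fu_strata, index=idx, columns=STRATA)
    fu_list = fu_strata_df.sum(axis=1)

    # --- true baseline design matrix and latent outcome -------------------
    weights = workload_mod.default_weight_table().normalised(strata_df.sum(axis=0))
    deprivation = workload_mod.DeprivationAdjustment()
    wl = workload_mod.compute_weighted_list(strata_df, weights)
    awl = workload_mod.deprivation_adjust(wl, pd.Series(imd_quintile, index=idx),
                                          deprivation)
    wpf = awl / gp_fte  # truth-level ratio; exclusions happen downstream
    awl_fu = workload_mod.deprivation_adjust(
        workload_mod.compute_weighted_list(fu_strata_df, weights),
        pd.Series(imd_quintile, index=idx), deprivation)

    effects_b = _draw_practice_effects(substream(seed, "effects_baseline"),
                                       idx, config.practice_effect_sd)
    raw = pd.DataFrame({
        "access": effects_b["access"], "continuity": effects_b["continuity"],
        "satisfaction": effects_b["satisfaction"],
        "nurse_gp_ratio": nurse_ratio, "workload_per_fte": wpf,
        "gp_fte": gp_fte, "other_gp_ratio": other_ratio,
        "rural": rural, "imd_quintile": imd_quintile,
        "projected_adjusted_list": awl_fu, "prop_remaining": prop_remaining,
    }, index=idx)
    X = model_mod.build_design_matrix(raw)
    beta = pd.Series({c: config.true_model_coefficients.get(c, 0.0)
                      for c in model_mod.COVARIATE_ORDER})
    p_under = pd.Series(expit(X @ beta), index=idx)
    rng_o = substream(seed, "outcome")
    u = pd.Series((rng_o.random(config.n_practices) < p_under).astype(int), index=idx)

    # --- follow-up panel around the latent indicator ----------------------
    rng_f = substream(seed, "followup")
    shift = np.array([ITEM_UNDERSUPPLY_SHIFT[i] for i in DEFAULT_ITEM_INTERCEPTS])
    effects_f = _draw_practice_effects(substream(seed, "effects_followup"),
                                       idx, config.practice_effect_sd,
                                       mean=np.outer(u.to_numpy(), shift))
    log_wpf_fu = (np.log(np.median(wpf)) + WORKLOAD_UNDERSUPPLY_SHIFT * u.to_numpy()
                  + rng_f.normal(0, WORKLOAD_LOG_SD, config.n_practices))
    gp_fte_fu = awl_fu.to_numpy() / np.exp(log_wpf_fu)
    bad_fu = rng_f.random(config.n_practices) < config.bad_fte_rate
    gp_fte_fu[bad_fu] = rng_f.uniform(0.05, 0.45, bad_fu.sum())
    nurse_ratio_fu = np.maximum(0.05, nurse_ratio + rng_f.normal(0, 0.05,
                                                                 config.n_practices))

    years_on = config.followup_year - config.baseline_year
    roster_f = roster_b.copy()
    roster_f["age"] = np.minimum(roster_f["age"] + years_on, 74)
    roster_f["year"] = config.followup_year
    # rescale individual FTEs to the new practice totals
    tot = roster_f.groupby("practice_id")["fte"].transform("sum")
    roster_f["fte"] = roster_f["fte"] / tot * \
        pd.Series(gp_fte_fu, index=idx).reindex(roster_f["practice_id"]).to_numpy()
    other_fte_fu = roster_f.loc[roster_f["role"] == "other"].groupby("practice_id")["fte"].sum()
    other_ratio_fu = (other_fte_fu.reindex(idx).fillna(0.0) / gp_fte_fu).to_numpy()

    def _panel(year, strata, lsize, fte, nfte, oratio):
        base = pd.DataFrame({
            "practice_id": ids, "year": year, "area_id": area_ids,
            "list_size": np.asarray(lsize, dtype=int),
            "gp_fte": np.round(fte, 3), "nurse_fte": np.round(nfte, 3),
            "other_gp_ratio": np.round(oratio, 4),
            "imd_score": np.round(imd_score, 2), "imd_quintile": imd_quintile,
            "rural": rural,
        })
        return pd.concat([base, strata.reset_index(drop=True)], axis=1)

    baseline_panel = _panel(config.baseline_year, strata_df, list_size,
                            gp_fte, nurse_fte, other_ratio)
    followup_panel = _panel(config.followup_year, fu_strata_df, fu_list,
                            gp_fte_fu, gp_fte_fu * nurse_ratio_fu, other_ratio_fu)

    truth = Truth(
        coefficients={c: float(beta[c]) for c in beta.index},
        item_intercepts=dict(DEFAULT_ITEM_INTERCEPTS),
        casemix_effects=DEFAULT_CASEMIX_EFFECTS,
        practice_effects_baseline=effects_b,
        practice_effects_followup=effects_f,
        gp_remain_probability=gp_remain,
        prop_remaining=prop_remaining,
        design_matrix=X,
        undersupply_probability=p_under,
        undersupply=u,
    )

    gpps = {
        config.baseline_year: generate_gpps_responses(
            baseline_panel, truth, substream(seed, "gpps_baseline"),
            wave="baseline",
            respondents_per_practice=config.gpps_respondents_per_practice),
        config.followup_year: generate_gpps_responses(
            followup_panel, truth, substream(seed, "gpps_followup"),
            wave="followup",
            respondents_per_practice=config.gpps_respondents_per_practice),
    }
    intention = generate_intention_survey(
        roster_f, truth, config.survey_response_rate,
        substream(seed, "intentions"))

    return SyntheticStudy(
        config=config,
        baseline_panel=baseline_panel,
        followup_panel=followup_panel,
        rosters={config.baseline_year: roster_b, config.followup_year: roster_f},
        gpps_responses=gpps,
        intention_survey=intention,
        projections=projections,
        truth=truth,
    )


def _generate_roster(rng: np.random.Generator, ids, gp_fte, year) -> pd.DataFrame:
    rows = []
    for pid, fte in zip(ids, gp_fte):
        n_gp = max(1, int(np.round(fte / 0.75 + rng.normal(0, 0.5))))
        raw = rng.gamma(4.0, 1.0, n_gp)
        ftes = raw / raw.sum() * fte
        ages = np.clip(rng.normal(47, 9.5, n_gp), 25, 70)
        genders = np.where(rng.random(n_gp) < 0.52, "F", "M")
        roles = rng.choice(GP_ROLES, size=n_gp, p=GP_ROLE_WEIGHTS)
        for j in range(n_gp):
            rows.append({"practice_id": pid, "gp_id": f"{pid}G{j:02d}",
                         "year": year, "age": float(np.round(ages[j], 1)),
                         "gender": genders[j], "fte": float(np.round(ftes[j], 3)),
                         "role": roles[j]})
    return pd.DataFrame(rows)


def generate_gpps_responses(
    panel: pd.DataFrame,
    truth: Truth,
    rng_or_seed: np.random.Generator | int,
    wave: str = "baseline",
    respondents_per_practice: float = 125.0,
) -> pd.DataFrame:
    """Respondent-level survey draws from the true mixed logistic model.

    One row per respondent: practice id, the three item responses (labels
    that dichotomise back to the generating binary draw) and the five
    case-mix covariates. Zero requested respondents yields an empty table
    with the schema intact.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else substream(int(rng_or_seed), f"gpps_{wave}")
    effects = (truth.practice_effects_baseline if wave == "baseline"
               else truth.practice_effects_followup)
    eff = truth.casemix_effects
    cols = (["practice_id"] + CASEMIX_SCHEMA + list(DEFAULT_ITEM_INTERCEPTS))
    if respondents_per_practice == 0:
        return pd.DataFrame(columns=cols)

    frames = []
    for pid, prac_q in zip(panel["practice_id"], panel["imd_quintile"]):
        n = rng.poisson(respondents_per_practice)
        if n == 0:
            continue
        age_band = rng.choice(RESPONDENT_AGE_BANDS, size=n,
                              p=[0.10, 0.16, 0.16, 0.17, 0.16, 0.15, 0.10])
        gender = np.where(rng.random(n) < 0.55, "F", "M")
        ethnicity = np.where(rng.random(n) < 0.85, "white", "minority")
        ltc = (rng.random(n) < 0.45).astype(int)
        dq = np.clip(prac_q + rng.integers(-1, 2, size=n), 1, 5)
        lp_cov = (np.array([eff["age_band"][b] for b in age_band])
                  + np.array([eff["gender"][g] for g in gender])
                  + np.array([eff["ethnicity"][e] for e in ethnicity])
                  + np.array([eff["long_term_condition"][v] for v in ltc])
                  + np.array([eff["deprivation_quintile"][int(q)] for q in dq]))
        out = {"practice_id": pid, "age_band": age_band, "gender": gender,
               "ethnicity": ethnicity, "long_term_condition": ltc,
               "deprivation_quintile": dq}
        for item, intercept in truth.item_intercepts.items():
            lp = intercept + effects.loc[pid, item] + lp_cov
            pos = rng.random(n) < expit(lp)
            out[item] = _label_responses(rng, item, pos)
        frames.append(pd.DataFrame(out))
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


CASEMIX_SCHEMA = ["age_band", "gender", "ethnicity", "long_term_condition",
                  "deprivation_quintile"]

_POSITIVE_LABELS = {
    "access": (["yes", "yes_but_later"], [0.8, 0.2]),
    "continuity": (["always", "almost_always", "a_lot"], [0.4, 0.35, 0.25]),
    "satisfaction": (["very_good", "fairly_good"], [0.55, 0.45]),
}
_NEGATIVE_LABELS = {
    "access": (["no", "cant_remember"], [0.85, 0.15]),
    "continuity": (["some", "never"], [0.7, 0.3]),
    "satisfaction": (["neither", "fairly_poor", "very_poor"], [0.5, 0.3, 0.2]),
}


def _label_responses(rng, item, positive: np.ndarray) -> np.ndarray:
    labels = np.empty(len(positive), dtype=object)
    pos_lab, pos_p = _POSITIVE_LABELS[item]
    neg_lab, neg_p = _NEGATIVE_LABELS[item]
    n_pos = int(positive.sum())
    labels[positive] = rng.choice(pos_lab, size=n_pos, p=pos_p)
    labels[~positive] = rng.choice(neg_lab, size=len(positive) - n_pos, p=neg_p)
    return labels


def generate_intention_survey(
    roster: pd.DataFrame,
    truth: Truth,
    response_rate: float,
    rng_or_seed: np.random.Generator | int,
) -> pd.DataFrame:
    """Career-intention census: each GP responds independently.

    Responders report an intention category drawn from their true leave
    probability; non-responders appear with a missing intention.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else substream(int(rng_or_seed), "intentions")
    if not (0.0 <= response_rate <= 1.0):
        raise ConfigurationError("response_rate must lie in [0, 1]")
    if roster.empty:
        raise ConfigurationError("roster is empty")

    remain = truth.gp_remain_probability.reindex(roster["gp_id"]).to_numpy()
    leave = 1.0 - remain
    responded = rng.random(len(roster)) < response_rate
    r = rng.random(len(roster))
    cat = np.select(
        [r < 0.5 * leave, r < leave, r < leave + 0.15],
        ["quit_within_2y", "quit_within_5y", "reduce_hours"],
        default="no_change")
    intention = np.where(responded, cat, None)
    return pd.DataFrame({
        "gp_id": roster["gp_id"].to_numpy(),
        "practice_id": roster["practice_id"].to_numpy(),
        "responded": responded.astype(int),
        "intention": intention,
    })
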