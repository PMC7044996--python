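"""Expected proportion of GP FTE remaining in patient care in five years.

Two estimators are provided. The demographic method looks up, for each GP
on a practice's roster, the probability that a GP of that age and gender is
still in patient care after five years, and takes the FTE-weighted mean.
The survey method replaces that lookup with the GP's own stated career
intention where a survey response exists, falling back to the demographic
lookup for non-responders (fallback is per-individual, preserving FTE
weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigurationError, DataError
from .strata import GP_AGE_BANDS, gp_age_band

__all__ = [
    "SurvivalTable",
    "IntentionMapping",
    "default_survival_table",
    "default_intention_mapping",
    "expected_remaining_demographic",
    "expected_remaining_survey",
    "compare_retention_methods",
]

INTENTION_CATEGORIES = ["quit_within_2y", "quit_within_5y", "reduce_hours", "no_change"]


@dataclass(frozen=True)
class SurvivalTable:
    """P(still in patient care in 5 years) per GP age band x gender."""

    probabilities: pd.Series  # MultiIndex (gender, age_band) or dict-backed

    def __post_init__(self) -> None:
        p = self.probabilities
        if ((p < 0) | (p > 1)).any():
            raise DataError("SurvivalTable probabilities must lie in [0, 1]")

    def lookup(self, gender: str, age: float) -> float:
        band = gp_age_band(age)
        try:
            return float(self.probabilities.loc[(gender, band)])
        except KeyError:
            raise DataError(f"SurvivalTable has no cell for ({gender}, {band})")

    def lookup_many(self, genders: pd.Series, ages: pd.Series) -> pd.Series:
        bands = ages.map(gp_age_band)
        idx = pd.MultiIndex.from_arrays([genders, bands])
        return pd.Series(self.probabilities.reindex(idx).to_numpy(),
                         index=genders.index)


@dataclass(frozen=True)
class IntentionMapping:
    """Map survey intention categories to retention contributions.

    Each category maps to ``(remain_probability, fte_fraction)``. A
    ``remain_probability`` of None means "use the demographic fallback for
    this GP"; ``fte_fraction`` scales the retained FTE (e.g. a stated
    intention to reduce hours retains a fraction of the post).
    """

    mapping: dict[str, tuple[float | None, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, (p, frac) in self.mapping.items():
            if p is not None and not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"IntentionMapping probability for {cat!r} outside [0, 1]")
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(
                    f"IntentionMapping fte_fraction for {cat!r} outside [0, 1]")


def default_survival_table() -> SurvivalTable:
    """Smoothly decreasing remain-probability with age.

    Retention is near-certain for GPs in their late 20s and falls steeply
    past 55; women carry a small mid-career reduction (career breaks).
    Values are explicit configuration.
    """
    rows = {}
    for g in ["F", "M"]:
        for band in GP_AGE_BANDS:
            a = 67.0 if band == "65+" else (int(band.split("-")[0]) + 2)
            p = 1.0 / (1.0 + np.exp((a - 59.0) / 5.5))
            p = 0.10 + 0.88 * p
            if g == "F" and 35 <= a <= 49:
                p -= 0.03
            rows[(g, band)] = round(float(p), 4)
    s = pd.Series(rows)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["gender", "age_band"])
    return SurvivalTable(s)


def default_intention_mapping() -> IntentionMapping:
    # quit within 5 but not 2 years -> 0.5 on a uniform-timing argument;
    # reduce-hours retains 60% of the post; no_change defers to demographics
    return IntentionMapping({
        "quit_within_2y": (0.0, 1.0),
        "quit_within_5y": (0.5, 1.0),
        "reduce_hours": (None, 0.6),
        "no_change": (None, 1.0),
    })


def _fte_weighted(contrib: pd.Series, fte: pd.Series, practice: pd.Series) -> pd.Series:
    num = (contrib * fte).groupby(practice).sum()
    den = fte.groupby(practice).sum()
    return num / den


def expected_remaining_demographic(
    roster: pd.DataFrame, table: SurvivalTable
) -> pd.DataFrame:
    """FTE-weighted mean remain-probability per practice.

    ``roster`` needs columns practice_id, gp_id, age, gender, fte.
    """
    if roster.empty:
        raise DataError("roster is empty")
    p = table.lookup_many(roster["gender"], roster["age"])
    if p.isna().any():
        raise DataError("roster GP outside survival table coverage")
    est = _fte_weighted(p, roster["fte"], roster["practice_id"])
    return pd.DataFrame({
        "practice_id": est.index,
        "method": "demographic",
        "expected_remaining": est.to_numpy(),
        "coverage": 0.0,
    }).reset_index(drop=True)


def expected_remaining_survey(
    roster: pd.DataFrame,
    survey: pd.DataFrame,
    mapping: IntentionMapping,
    fallback: SurvivalTable,
) -> pd.DataFrame:
    """Survey-based retention with per-GP demographic fallback.

    ``survey`` has columns gp_id, intention (NaN = non-responder). Coverage
    reports the fraction of practice FTE carrying a survey response.
    """
    if roster.empty:
        raise DataError("roster is empty")
    merged = roster.merge(survey[["gp_id", "intention"]], on="gp_id", how="left")
    responded = merged["intention"].notna()
    cats = set(merged.loc[responded, "intention"].unique())
    unmapped = cats - set(mapping.mapping)
    if unmapped:
        raise ConfigurationError(f"unmapped intention categories: {sorted(unmapped)}")

    fallback_p = fallback.lookup_many(merged["gender"], merged["age"])
    contrib = fallback_p.copy()
    for cat, (p, frac) in mapping.mapping.items():
        mask = responded & (merged["intention"] == cat)
        base = fallback_p[mask] if p is None else p
        contrib[mask] = base * frac

    est = _fte_weighted(contrib, merged["fte"], merged["practice_id"])
    cov = _fte_weighted(responded.astype(float), merged["fte"], merged["practice_id"])
    return pd.DataFrame({
        "practice_id": est.index,
        "method": "survey",
        "expected_remaining": est.to_numpy(),
        "coverage": cov.reindex(est.index).to_numpy(),
    }).reset_index(drop=True)


def compare_retention_methods(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation and per-practice deltas between two estimates."""
    merged = a.merge(b, on="practice_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise DataError("fewer than 3 shared practices")
    rho = float(spearmanr(merged["expected_remaining_a"],
                          merged["expected_remaining_b"]).statistic)
    merged["delta"] = merged["expected_remaining_a"] - merged["expected_remaining_b"]
    return rho, merged[["practice_id", "expected_remaining_a",
                        "expected_remaining_b", "delta"]]
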