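"""Demography-weighted list sizes, workload per GP FTE and practice exclusions.

Workload is defined from the registered population rather than recorded
visits: visit counts are bounded by the workforce available and so cannot
capture unmet demand. Each practice's list is reweighted by relative
consultation workload per gender x 5-year age band (consultations run
longer, on average, for the very young, the old and for women), then scaled
by a deprivation factor, and finally divided by GP full-time equivalents.

The exclusion rules mirror standard practice-level data cleaning: drop tiny
lists, drop practices recording less than half a GP FTE (almost certainly a
data error), and trim the extreme tails of the workload-per-FTE
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, SchemaError
from .strata import AGE_MIDPOINTS, STRATA, stratum_age_band, stratum_gender

__all__ = [
    "WeightTable",
    "DeprivationAdjustment",
    "default_weight_table",
    "compute_weighted_list",
    "deprivation_adjust",
    "workload_per_fte",
    "apply_exclusions",
    "compute_workload_records",
]

#: GP FTE floor below which a practice is treated as a data error
MIN_GP_FTE = 0.5
#: fraction trimmed from each tail of the workload-per-FTE distribution
TRIM_FRACTION = 0.025
#: minimum registered list size
MIN_LIST_SIZE = 1000


@dataclass(frozen=True)
class WeightTable:
    """Relative consultation workload per gender x age-band stratum.

    Weights are dimensionless multipliers on patient counts. They should be
    normalised so that the population-weighted mean weight is 1 over a
    reference population, making the weighted list of an average-structure
    practice equal its raw list.
    """

    weights: pd.Series  # index = STRATA

    def __post_init__(self) -> None:
        missing = set(STRATA) - set(self.weights.index)
        if missing:
            raise SchemaError(f"WeightTable missing strata: {sorted(missing)[:4]}...")
        if (self.weights <= 0).any():
            bad = self.weights.index[self.weights <= 0][0]
            raise DataError(f"WeightTable weight for stratum {bad!r} must be > 0")

    def normalised(self, reference: pd.Series) -> "WeightTable":
        """Rescale so the reference-population-weighted mean weight is 1."""
        ref = reference.reindex(self.weights.index)
        if ref.isna().any():
            raise SchemaError("reference population does not cover all strata")
        mean = float((self.weights * ref).sum() / ref.sum())
        return WeightTable(self.weights / mean)


@dataclass(frozen=True)
class DeprivationAdjustment:
    """Multiplicative uplift on the weighted list per IMD quintile.

    Quintile 1 (least deprived) is the reference with factor 1; higher
    quintiles carry higher health need per registered patient.
    """

    factors: dict[int, float] = field(
        default_factory=lambda: {1: 1.00, 2: 1.05, 3: 1.10, 4: 1.15, 5: 1.20}
    )

    def __post_init__(self) -> None:
        if set(self.factors) != {1, 2, 3, 4, 5}:
            raise DataError("DeprivationAdjustment must map quintiles 1..5")
        if any(f <= 0 for f in self.factors.values()):
            raise DataError("DeprivationAdjustment factors must be > 0")
        if self.factors[1] != 1.0:
            raise DataError("DeprivationAdjustment reference quintile 1 must be 1.0")


def default_weight_table() -> WeightTable:
    """U-shaped age curve with a female uplift, un-normalised.

    The curve is high for under-5s, dips through working age and rises
    steeply from retirement age; women get a 10% uplift. Values are
    explicit configuration, not estimates, and callers normalise against
    their own reference population.
    """
    w = {}
    for s in STRATA:
        a = AGE_MIDPOINTS[stratum_age_band(s)]
        base = 0.75 + 0.9 * np.exp(-a / 9.0) + 1.3 / (1.0 + np.exp(-(a - 62.0) / 8.0))
        if stratum_gender(s) == "F":
            base *= 1.10
        w[s] = base
    return WeightTable(pd.Series(w).reindex(STRATA))


def compute_weighted_list(strata_counts: pd.DataFrame, weights: WeightTable) -> pd.Series:
    """Sum of stratum count x stratum weight per practice.

    ``strata_counts`` is wide (index = practice_id, one column per stratum).
    """
    missing = set(weights.weights.index) ^ set(strata_counts.columns)
    extra = set(strata_counts.columns) - set(weights.weights.index)
    if extra or (set(weights.weights.index) - set(strata_counts.columns)):
        raise SchemaError(f"strata/weights cell mismatch: {sorted(missing)[:4]}")
    w = weights.weights.reindex(strata_counts.columns)
    return strata_counts.mul(w, axis=1).sum(axis=1)


def deprivation_adjust(
    weighted_list: pd.Series, imd_quintile: pd.Series, adj: DeprivationAdjustment
) -> pd.Series:
    """Multiply each practice's weighted list by its quintile factor."""
    q = imd_quintile.reindex(weighted_list.index)
    unknown = set(q.dropna().unique()) - set(adj.factors)
    if unknown or q.isna().any():
        raise DataError(f"unknown IMD quintile values: {sorted(unknown)} "
                        f"(missing: {int(q.isna().sum())})")
    return weighted_list * q.map(adj.factors)


def workload_per_fte(adjusted_weighted_list: float | pd.Series,
                     gp_fte: float | pd.Series) -> tuple:
    """Adjusted weighted patients per GP FTE, plus the per-1000 covariate.

    Callers must have applied the FTE exclusion first; an FTE below the
    0.5 floor is a contract violation, not a data condition handled here.
    """
    fte = np.asarray(gp_fte, dtype=float)
    if np.any(fte < MIN_GP_FTE):
        raise ContractError(
            "gp_fte below the 0.5 exclusion floor; apply_exclusions must run first")
    ratio = adjusted_weighted_list / gp_fte
    return ratio, ratio / 1000.0


def apply_exclusions(
    panel: pd.DataFrame,
    min_fte: float = MIN_GP_FTE,
    trim_fraction: float = TRIM_FRACTION,
    min_list: int = MIN_LIST_SIZE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a panel by list size, GP FTE floor and workload-tail trim.

    Order is fixed: (1) drop lists <= ``min_list``; (2) drop GP FTE below
    ``min_fte``; (3) drop the top and bottom ``trim_fraction`` of the
    remaining workload-per-FTE distribution (floor(f*n) practices per tail,
    ties broken by practice id). Returns the filtered panel and a per-step
    exclusion log.

    ``panel`` needs columns ``practice_id``, ``list_size``, ``gp_fte`` and
    ``workload_per_fte``.
    """
    log: dict[str, int] = {"rows_in": len(panel)}
    kept = panel[panel["list_size"] > min_list]
    log["dropped_small_list"] = len(panel) - len(kept)
    n0 = len(kept)
    kept = kept[kept["gp_fte"] >= min_fte]
    log["dropped_low_fte"] = n0 - len(kept)

    k = int(np.floor(trim_fraction * len(kept)))
    if trim_fraction > 0 and 2 * k >= len(kept):
        raise DataError("workload trim would empty the panel")
    if k > 0:
        order = kept.sort_values(["workload_per_fte", "practice_id"],
                                 kind="mergesort")
        drop_ids = pd.concat([order.head(k), order.tail(k)])["practice_id"]
        kept = kept[~kept["practice_id"].isin(set(drop_ids))]
    log["dropped_workload_trim"] = 2 * k
    log["rows_out"] = len(kept)
    return kept.copy(), log


def compute_workload_records(
    strata_counts: pd.DataFrame,
    imd_quintile: pd.Series,
    gp_fte: pd.Series,
    weights: WeightTable,
    adj: DeprivationAdjustment,
) -> pd.DataFrame:
    """Assemble per-practice workload records (pre-exclusion).

    Returns a frame indexed by practice id with ``weighted_list``,
    ``adjusted_weighted_list``, ``gp_fte`` and ``workload_per_fte``
    (NaN where FTE is below the exclusion floor — those rows exist only to
    be counted by ``apply_exclusions``).
    """
    wl = compute_weighted_list(strata_counts, weights)
    awl = deprivation_adjust(wl, imd_quintile, adj)
    fte = gp_fte.reindex(wl.index)
    eligible = fte >= MIN_GP_FTE
    wpf = pd.Series(np.nan, index=wl.index)
    wpf[eligible] = awl[eligible] / fte[eligible]
    return pd.DataFrame({
        "weighted_list": wl,
        "adjusted_weighted_list": awl,
        "gp_fte": fte,
        "workload_per_fte": wpf,
    })
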