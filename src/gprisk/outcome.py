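"""Undersupply classification: joint terciles of access and workload.

A practice is in "undersupply" when it sits in the lowest national third of
case-mix-adjusted access scores and simultaneously in the highest national
third of workload per GP FTE. Tercile cutpoints are computed once over the
full post-exclusion national panel and stored, so regional subsets can be
classified against national cutpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["tercile_assign", "assign_with_cutpoints", "classify_undersupply"]


def tercile_assign(values: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Label values 1/2/3 by empirical tercile; return labels and cutpoints.

    Cutpoints are the 1/3 and 2/3 quantiles (linear interpolation); ties at
    a cutpoint fall in the lower tercile.
    """
    v = values.dropna()
    if len(v) < 3:
        raise DataError("need at least 3 non-missing values for terciles")
    if v.nunique() == 1:
        raise DataError("all values identical; terciles undefined")
    q1, q2 = (float(q) for q in np.quantile(v.to_numpy(), [1 / 3, 2 / 3]))
    return assign_with_cutpoints(values, (q1, q2)), (q1, q2)


def assign_with_cutpoints(values: pd.Series, cutpoints: tuple[float, float]) -> pd.Series:
    q1, q2 = cutpoints
    labels = pd.Series(np.nan, index=values.index)
    ok = values.notna()
    labels[ok] = np.where(values[ok] <= q1, 1, np.where(values[ok] <= q2, 2, 3))
    return labels.astype("Int64")


def classify_undersupply(
    access_terciles: pd.Series, workload_terciles: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Undersupply flag plus the 3x3 access-by-workload grid.

    Inputs are tercile labels indexed by practice id; undersupply is
    (access tercile 1) AND (workload tercile 3).
    """
    if not access_terciles.index.equals(workload_terciles.index):
        a, w = set(access_terciles.index), set(workload_terciles.index)
        raise DataError(f"mismatched practice ids ({len(a ^ w)} unshared)")
    status = pd.DataFrame({
        "access_tercile": access_terciles,
        "workload_tercile": workload_terciles,
    })
    status["undersupply"] = (status["access_tercile"] == 1) & (status["workload_tercile"] == 3)
    grid = pd.crosstab(status["access_tercile"], status["workload_tercile"]).reindex(
        index=[1, 2, 3], columns=[1, 2, 3], fill_value=0)
    return status, grid
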