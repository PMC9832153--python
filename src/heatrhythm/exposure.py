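"""Temperature-exposure arithmetic for hot vs cool periods of the day.

Shifting activity from midday to morning/evening lowers the temperature
actually experienced.  For days whose daytime (6 AM - 10 PM) mean falls in a
given bin, this module summarises hourly temperature within the hot periods
(10 AM - 6 PM) and the cool periods (6 - 9 AM and 7 - 10 PM) and reports the
difference as the exposure reduction available from rescheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PanelValidationError
from .estimator import HOURS, PERIODS, HOT_PERIODS, COOL_PERIODS

HOT_HOURS = tuple(h for p in HOT_PERIODS for h in PERIODS[p])
COOL_HOURS = tuple(h for p in COOL_PERIODS for h in PERIODS[p])


@dataclass
class ExposureSummary:
    """Hot- and cool-period temperature statistics for one daily bin."""

    daily_bin: tuple[float, float]
    n_days: int
    hot_mean: float
    hot_median: float
    hot_iqr: tuple[float, float]
    cool_mean: float
    cool_median: float
    cool_iqr: tuple[float, float]
    reduction: float  # hot-period mean minus cool-period mean, degC

    def to_dict(self) -> dict:
        return {
            "daily_bin": list(self.daily_bin),
            "n_days": int(self.n_days),
            "hot_mean": float(self.hot_mean),
            "hot_median": float(self.hot_median),
            "hot_iqr": [float(v) for v in self.hot_iqr],
            "cool_mean": float(self.cool_mean),
            "cool_median": float(self.cool_median),
            "cool_iqr": [float(v) for v in self.cool_iqr],
            "reduction": float(self.reduction),
        }


def period_exposure(
    table: pd.DataFrame,
    daily_bin: tuple[float, float],
    hot_hours: tuple[int, ...] = HOT_HOURS,
    cool_hours: tuple[int, ...] = COOL_HOURS,
    weights: dict[int, float] | None = None,
) -> ExposureSummary:
    """Mean temperature in hot vs cool periods over days in ``daily_bin``.

    ``table`` needs (city-level or park-level) hourly rows with columns
    city_id/date/hour/temperature; duplicate park rows are collapsed so the
    summary is day-weighted, not park-weighted.  ``weights`` optionally
    weight hours by a within-day activity share for an activity-weighted
    variant of the exposure means.
    """
    cols = {"city_id", "date", "hour", "temperature"}
    if not cols <= set(table.columns):
        raise PanelValidationError(f"exposure table needs columns {sorted(cols)}")
    t = table.drop_duplicates(subset=["city_id", "date", "hour"])
    t = t[t["hour"].isin(HOURS)]
    daily = t.groupby(["city_id", "date"])["temperature"].mean()
    lo, hi = daily_bin
    keep = daily[(daily >= lo) & (daily < hi)].index
    if len(keep) == 0:
        raise PanelValidationError(
            f"no days with daytime mean temperature in [{lo}, {hi})"
        )
    sel = t.set_index(["city_id", "date"]).loc[keep].reset_index()

    def _stats(hours: tuple[int, ...]) -> tuple[float, float, tuple[float, float]]:
        sub = sel[sel["hour"].isin(hours)]
        x = sub["temperature"].to_numpy()
        if weights is not None:
            w = sub["hour"].map(weights).to_numpy(dtype=float)
            mean = float(np.average(x, weights=w))
        else:
            mean = float(x.mean())
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        return mean, float(med), (float(q25), float(q75))

    hot_mean, hot_med, hot_iqr = _stats(hot_hours)
    cool_mean, cool_med, cool_iqr = _stats(cool_hours)
    return ExposureSummary(
        daily_bin=daily_bin,
        n_days=len(keep),
        hot_mean=hot_mean,
        hot_median=hot_med,
        hot_iqr=hot_iqr,
        cool_mean=cool_mean,
        cool_median=cool_med,
        cool_iqr=cool_iqr,
        reduction=hot_mean - cool_mean,
    )
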