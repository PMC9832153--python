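"""Climate-change projection of activity quantity and timing.

The binned dose-response is smoothed with a natural cubic spline through the
bin midpoints (flat extrapolation beyond the terminal midpoints).  Projected
monthly warming deltas are disaggregated to hours by adding the same delta
to every hour of the baseline month, the spline converts projected hourly
temperatures to relative activity, and uncertainty is propagated over the
(climate model) x (coefficient quantile) grid - 21 models x 25 quantiles
giving 525 draws per cell-month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .errors import BinningError, PanelValidationError
from .estimator import FEModelFit, HOURS

logger = logging.getLogger("heatrhythm.projection")

SUMMER_MONTHS = (6, 7, 8)
WINTER_MONTHS = (12, 1, 2)


# ---------------------------------------------------------------------------
# Dose-response spline
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSpline:
    """Continuous log-scale dose-response f(T) from binned coefficients.

    Natural cubic spline (zero second derivative at the end knots) through
    (bin midpoint, beta); beyond the terminal midpoints the function is held
    constant at the terminal values.
    """

    knots_t: np.ndarray
    knots_beta: np.ndarray
    knots_se: np.ndarray | None = None
    _cs: CubicSpline = field(init=False, repr=False)

    def __post_init__(self):
        t = np.asarray(self.knots_t, dtype=float)
        b = np.asarray(self.knots_beta, dtype=float)
        if t.size < 4:
            raise BinningError(
                "natural cubic spline needs >=4 bins; use the quadratic "
                "polynomial fit for coarser grids"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots_t = t
        self.knots_beta = b
        self._cs = CubicSpline(t, b, bc_type="natural")

    def __call__(self, temperature) -> np.ndarray:
        t = np.clip(np.asarray(temperature, dtype=float),
                    self.knots_t[0], self.knots_t[-1])
        return self._cs(t)

    def shifted(self, z: float) -> "DoseResponseSpline":
        """Spline with every knot moved jointly to normal quantile z."""
        if self.knots_se is None:
            raise ValueError("no knot SEs available")
        return DoseResponseSpline(
            knots_t=self.knots_t,
            knots_beta=self.knots_beta + z * self.knots_se,
            knots_se=self.knots_se,
        )


def fit_spline(fit: FEModelFit) -> DoseResponseSpline:
    """Natural cubic spline through the fitted per-bin log effects."""
    table = fit.bin_table()
    return DoseResponseSpline(
        knots_t=table["midpoint"].to_numpy(),
        knots_beta=table["beta"].to_numpy(),
        knots_se=table["se"].to_numpy(),
    )


def spline_from_curve(
    midpoints: np.ndarray, beta: np.ndarray, se: np.ndarray | None = None
) -> DoseResponseSpline:
    """Spline through an arbitrary (temperature, value) curve, e.g. dt(T)."""
    return DoseResponseSpline(
        knots_t=np.asarray(midpoints, float),
        knots_beta=np.asarray(beta, float),
        knots_se=None if se is None else np.asarray(se, float),
    )


# ---------------------------------------------------------------------------
# Baseline and deltas
# ---------------------------------------------------------------------------

BASELINE_COLUMNS = ("cell", "month", "hour", "temperature")
DELTA_COLUMNS = ("model", "cell", "month", "delta")


def validate_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Check the hourly baseline covers all 17 hours x 12 months per cell."""
    missing = set(BASELINE_COLUMNS) - set(baseline.columns)
    if missing:
        raise PanelValidationError(f"baseline missing columns {sorted(missing)}")
    counts = baseline.groupby("cell").apply(
        lambda g: g[["month", "hour"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    bad = counts[counts < 12 * len(HOURS)]
    if len(bad):
        raise PanelValidationError(
            f"cells with incomplete month x hour coverage: {list(bad.index)}"
        )
    return baseline


def baseline_from_hourly(hourly: pd.DataFrame, cell_col: str = "city_id") -> pd.DataFrame:
    """Average an observed hourly series into the (cell, month, hour) baseline."""
    df = hourly[hourly["hour"].isin(HOURS)].copy()
    df["month"] = pd.to_datetime(df["date"]).dt.month
    out = (
        df.groupby([cell_col, "month", "hour"], as_index=False)["temperature"]
        .mean()
        .rename(columns={cell_col: "cell"})
    )
    return out


def disaggregate(
    baseline: pd.DataFrame, deltas: pd.DataFrame, model: str | None = None
) -> pd.DataFrame:
    """Projected hourly temperatures: baseline plus the month's delta.

    The same delta is added to every hour of a month (per-hour differential
    warming is not resolved by the inputs).  Missing months raise.
    """
    validate_baseline(baseline)
    d = deltas if model is None else deltas[deltas["model"] == model]
    if d.empty:
        raise PanelValidationError(f"no deltas for model {model!r}")
    months_by_cell = d.groupby("cell")["month"].nunique()
    if (months_by_cell < 12).any():
        raise PanelValidationError("delta set has incomplete month coverage")
    merged = baseline.merge(d[["cell", "month", "delta"]], on=["cell", "month"],
                            how="left", validate="many_to_one")
    if merged["delta"].isna().any():
        raise PanelValidationError("baseline cells missing from delta set")
    merged["temperature"] = merged["temperature"] + merged["delta"]
    return merged.drop(columns=["delta"])


# ---------------------------------------------------------------------------
# Projection of activity quantity and timing
# ---------------------------------------------------------------------------


def _mean_relative_activity(spline: DoseResponseSpline, df: pd.DataFrame) -> pd.Series:
    rel = np.exp(spline(df["temperature"].to_numpy()))
    return (
        df.assign(rel=rel).groupby(["cell", "month"])["rel"].mean()
    )


def project_activity(
    spline: DoseResponseSpline, baseline: pd.DataFrame, projected: pd.DataFrame
) -> pd.DataFrame:
    """Percentage-point change in activity per cell-month under warming.

    Relative activity e^f(T) is averaged over the 17 daytime hours for the
    baseline and projected series; the change is 100 * (proj - base) / base.
    """
    base = _mean_relative_activity(spline, baseline)
    proj = _mean_relative_activity(spline, projected)
    change = 100.0 * (proj - base) / base
    return change.rename("pct_change").reset_index()


def project_timeshift(
    dt_spline: DoseResponseSpline,
    baseline: pd.DataFrame,
    projected: pd.DataFrame,
    months: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Change in the activity time shift (minutes) per cell under warming.

    The dt(T) curve is evaluated at the daytime-mean temperature of each
    month's representative day and averaged over the requested months
    (default: all twelve); reported as projected minus baseline.
    """
    def monthly_dt(df: pd.DataFrame) -> pd.Series:
        means = df.groupby(["cell", "month"])["temperature"].mean()
        return pd.Series(dt_spline(means.to_numpy()), index=means.index)

    base = monthly_dt(baseline)
    proj = monthly_dt(projected)
    diff = (proj - base).rename("dt_change_minutes").reset_index()
    if months is not None:
        diff = diff[diff["month"].isin(months)]
    out = diff.groupby("cell", as_index=False)["dt_change_minutes"].mean()
    return out


@dataclass
class ProjectionResult:
    """Monte-Carlo projection distribution per cell-month.

    ``draws`` has shape (n_models * n_quantiles, n_cells, 12); ``table``
    carries mean and 2.5 / 97.5 percentile columns per cell-month.
    """

    cells: list[str]
    months: list[int]
    n_models: int
    n_quantiles: int
    draws: np.ndarray
    table: pd.DataFrame

    @property
    def n_draws(self) -> int:
        return self.n_models * self.n_quantiles


def monte_carlo(
    spline: DoseResponseSpline,
    baseline: pd.DataFrame,
    deltas: pd.DataFrame,
    n_quantiles: int = 25,
) -> ProjectionResult:
    """Propagate model and coefficient uncertainty through the projection.

    For each climate model and each of ``n_quantiles`` equally-spaced normal
    quantiles of the dose-response coefficients (moved jointly), the monthly
    percentage change is recomputed; the empirical 2.5 / 97.5 percentiles of
    the draws form the CI.  Models with incomplete month coverage are
    excluded with a warning.
    """
    validate_baseline(baseline)
    if spline.knots_se is None:
        raise ValueError("spline has no knot SEs; cannot sample quantiles")
    models = sorted(deltas["model"].unique())
    usable = []
    for m in models:
        d = deltas[deltas["model"] == m]
        if (d.groupby("cell")["month"].nunique() < 12).any():
            logger.warning("model %s has incomplete months; excluded", m)
            continue
        usable.append(m)
    if not usable:
        raise PanelValidationError("no climate model has complete month coverage")

    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    zs = stats.norm.ppf(probs)
    cells = sorted(baseline["cell"].unique())
    months = list(range(1, 13))

    base_by_month: dict[float, pd.Series] = {}
    draws = np.empty((len(usable) * n_quantiles, len(cells), 12))
    idx = pd.MultiIndex.from_product([cells, months], names=["cell", "month"])
    i = 0
    for m in usable:
        projected = disaggregate(baseline, deltas, model=m)
        for z in zs:
            s = spline.shifted(z)
            if z not in base_by_month:
                base_by_month[z] = _mean_relative_activity(s, baseline)
            base = base_by_month[z]
            proj = _mean_relative_activity(s, projected)
            change = (100.0 * (proj - base) / base).reindex(idx)
            draws[i] = change.to_numpy().reshape(len(cells), 12)
            i += 1

    mean = draws.mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "cell": np.repeat(cells, 12),
            "month": months * len(cells),
            "pct_change_mean": mean.ravel(),
            "pct_change_lo": lo.ravel(),
            "pct_change_hi": hi.ravel(),
        }
    )
    return ProjectionResult(
        cells=cells,
        months=months,
        n_models=len(usable),
        n_quantiles=n_quantiles,
        draws=draws,
        table=table,
    )
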