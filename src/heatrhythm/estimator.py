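"""Binned fixed-effects dose-response estimation for hourly activity panels.

The central model regresses log(visits + 1) for park *i* in city *c* at hour
*t* on indicator variables for 5 degC temperature bins (20-25 degC omitted as
the comfort reference), weather/pollution/holiday controls, and four
fixed-effect dimensions: park, hour-of-day, day-of-week (or calendar date),
and city-by-month.  Fixed effects are absorbed by alternating within-group
demeaning; inference uses a CR1 cluster-robust sandwich grouped by city.

Variants implemented alongside the main fit:

* daily aggregates (min / mean / max daytime temperature),
* period-of-day regressions on binned daily mean temperature,
* within-day hourly profiles by daily-temperature group (1 PM reference),
* stratified fits with terminal bins merged above 30 degC / below 0 degC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import (
    BinningError,
    CollinearityError,
    ConvergenceError,
    PanelValidationError,
)

logger = logging.getLogger("heatrhythm.estimator")

#: Hours of the day retained in every analysis (6 AM .. 10 PM inclusive).
HOURS = np.arange(6, 23)

#: Default weather / pollution / holiday controls.
DEFAULT_COVARIATES = (
    "precipitation",
    "wind_speed",
    "humidity",
    "pressure",
    "cloud",
    "aqi",
    "holiday",
)

#: Period-of-day definitions.  The hot set is the union of noon and late
#: afternoon (the 2-3 PM hour is assigned to noon for contiguity); the cool
#: set is morning plus evening.
PERIODS: dict[str, tuple[int, ...]] = {
    "morning": tuple(range(6, 10)),
    "noon": tuple(range(10, 15)),
    "late_afternoon": tuple(range(15, 19)),
    "evening": tuple(range(19, 23)),
}

HOT_PERIODS = ("noon", "late_afternoon")
COOL_PERIODS = ("morning", "evening")


# ---------------------------------------------------------------------------
# Temperature bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinSpec:
    """Temperature binning rule.

    Bins are half-open intervals ``[a, b)`` on a grid of ``width`` degC with
    open-ended terminal bins below the first and above the last interior
    break.  ``merge_below`` / ``merge_above`` collapse everything outside
    those limits into the terminal bins (the stratified-analysis convention).
    Explicit ``edges`` override the grid; values outside explicit edges raise
    :class:`~heatrhythm.errors.BinningError`.
    """

    width: float = 5.0
    reference: tuple[float, float] = (20.0, 25.0)
    merge_below: float | None = None
    merge_above: float | None = None
    edges: tuple[float, ...] | None = None

    def resolve(self, temperatures: np.ndarray) -> "ResolvedBins":
        """Materialise bin breaks covering the observed temperature range."""
        t = np.asarray(temperatures, dtype=float)
        if t.size == 0:
            raise BinningError("cannot resolve bins on an empty temperature vector")
        if self.edges is not None:
            edges = np.asarray(self.edges, dtype=float)
            if edges.size < 3 or np.any(np.diff(edges) <= 0):
                raise BinningError("explicit edges must be >=3 strictly increasing values")
            return ResolvedBins(
                breaks=edges[1:-1],
                width=float(np.median(np.diff(edges))),
                reference=self.reference,
                hard_limits=(float(edges[0]), float(edges[-1])),
            )
        lo = np.floor(t.min() / self.width) * self.width
        hi = np.ceil(t.max() / self.width) * self.width
        if hi <= lo:
            hi = lo + self.width
        breaks = np.arange(lo + self.width, hi, self.width)
        if breaks.size == 0:
            breaks = np.array([lo + self.width])
        if self.merge_below is not None:
            breaks = breaks[breaks >= self.merge_below]
        if self.merge_above is not None:
            breaks = breaks[breaks <= self.merge_above]
        if breaks.size == 0:
            # all data beyond a merge boundary: keep that boundary as the
            # single break so the two terminal bins remain defined
            fallback = self.merge_above if self.merge_above is not None else self.merge_below
            breaks = np.array([float(fallback)])
        return ResolvedBins(
            breaks=breaks,
            width=self.width,
            reference=self.reference,
            hard_limits=None,
        )


@dataclass(frozen=True)
class ResolvedBins:
    """Concrete bin breaks for a specific sample."""

    breaks: np.ndarray
    width: float
    reference: tuple[float, float]
    hard_limits: tuple[float, float] | None = None

    @property
    def n_bins(self) -> int:
        return len(self.breaks) + 1

    @property
    def labels(self) -> list[str]:
        b = self.breaks
        out = [f"<{b[0]:g}"]
        out += [f"{a:g}-{c:g}" for a, c in zip(b[:-1], b[1:])]
        out.append(f">{b[-1]:g}")
        return out

    @property
    def reference_index(self) -> int:
        mid = 0.5 * (self.reference[0] + self.reference[1])
        return int(np.searchsorted(self.breaks, mid, side="right"))

    @property
    def reference_label(self) -> str:
        return self.labels[self.reference_index]

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints; open terminal bins use edge -/+ half a bin width."""
        b = self.breaks
        mids = np.empty(self.n_bins)
        mids[0] = b[0] - self.width / 2.0
        mids[-1] = b[-1] + self.width / 2.0
        if self.n_bins > 2:
            mids[1:-1] = 0.5 * (b[:-1] + b[1:])
        return mids

    def assign(self, temperatures: np.ndarray) -> np.ndarray:
        t = np.asarray(temperatures, dtype=float)
        if self.hard_limits is not None:
            lo, hi = self.hard_limits
            bad = (t < lo) | (t >= hi)
            if bad.any():
                raise BinningError(
                    f"{int(bad.sum())} temperatures outside explicit bin coverage "
                    f"[{lo:g}, {hi:g})"
                )
        return np.searchsorted(self.breaks, t, side="right")


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the fixed-effects regression.

    ``temperature`` is either a :class:`BinSpec` or the string ``"poly2"``
    (quadratic polynomial robustness variant).  ``time_fe`` selects
    day-of-week (default) or calendar-date fixed effects; exactly one is
    active.  ``fe_dims`` lists the absorbed dimensions in order.
    """

    temperature: BinSpec | str = field(default_factory=BinSpec)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    time_fe: str = "dow"  # "dow" | "date"
    cluster: str = "city_id"
    fe_dims: tuple[str, ...] = ("park", "hour", "time", "city_month")
    absorb_tol: float = 1e-8
    max_sweeps: int = 10_000

    def __post_init__(self):
        if self.time_fe not in ("dow", "date"):
            raise ValueError("time_fe must be 'dow' or 'date'")
        if isinstance(self.temperature, str) and self.temperature != "poly2":
            raise ValueError("temperature must be a BinSpec or 'poly2'")

    def daily(self) -> "ModelSpec":
        """Variant for park-day aggregates (hour FE dropped)."""
        return replace(self, fe_dims=tuple(d for d in self.fe_dims if d != "hour"))


@dataclass
class DesignMatrices:
    """Outcome, regressors, FE id columns and cluster ids for one fit."""

    y: np.ndarray
    X: pd.DataFrame
    fe_codes: list[np.ndarray]
    fe_names: list[str]
    fe_levels: list[int]
    cluster_codes: np.ndarray
    n_clusters: int
    bins: ResolvedBins | None
    bin_columns: list[str]
    dropped_bins: list[str]


REQUIRED_COLUMNS = (
    "park_id",
    "city_id",
    "date",
    "hour",
    "visits",
    "temperature",
)


def validate_panel(panel: pd.DataFrame, covariates: Iterable[str] = ()) -> None:
    """Check VisitPanel invariants; raise PanelValidationError on violation."""
    needed = list(REQUIRED_COLUMNS) + [c for c in covariates if c not in REQUIRED_COLUMNS]
    missing = [c for c in needed if c not in panel.columns]
    if missing:
        raise PanelValidationError(f"panel is missing required columns: {missing}")
    hours = panel["hour"].to_numpy()
    bad = (hours < 6) | (hours > 22)
    if bad.any():
        rows = np.flatnonzero(bad)[:10].tolist()
        raise PanelValidationError(
            f"{int(bad.sum())} rows have hour outside [6, 22] (first rows: {rows})"
        )
    if (panel["visits"].to_numpy() < 0).any():
        raise PanelValidationError("negative visit counts present")
    for c in needed:
        if panel[c].isna().any():
            raise PanelValidationError(f"missing values in required column {c!r}")
    if panel.duplicated(subset=["park_id", "date", "hour"]).any():
        raise PanelValidationError("(park_id, date, hour) keys are not unique")


def _factorize(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, sort=True)
    return codes.astype(np.int64), len(uniques)


def _fe_code_columns(
    panel: pd.DataFrame, spec: ModelSpec, dims: Sequence[str]
) -> tuple[list[np.ndarray], list[str], list[int]]:
    dates = pd.to_datetime(panel["date"])
    codes, names, levels = [], [], []
    for dim in dims:
        if dim == "park":
            c, k = _factorize(panel["park_id"])
        elif dim == "hour":
            c, k = _factorize(panel["hour"])
        elif dim == "time":
            if spec.time_fe == "dow":
                c, k = _factorize(dates.dt.dayofweek)
            else:
                c, k = _factorize(dates)
        elif dim == "city_month":
            key = panel["city_id"].astype(str) + "#" + dates.dt.month.astype(str)
            c, k = _factorize(key)
        else:
            raise ValueError(f"unknown FE dimension {dim!r}")
        codes.append(c)
        names.append(dim if dim != "time" else spec.time_fe)
        levels.append(k)
    return codes, names, levels


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Construct log(visits + 1), temperature regressors and FE ids.

    Column ordering is deterministic: temperature terms first (bins in
    ascending order, reference omitted), then covariates in spec order.
    Empty non-reference bins are dropped with a logged warning.
    """
    validate_panel(panel, spec.covariates)
    y = np.log1p(panel["visits"].to_numpy(dtype=float))
    t = panel["temperature"].to_numpy(dtype=float)

    cols: dict[str, np.ndarray] = {}
    bins = None
    bin_columns: list[str] = []
    dropped: list[str] = []
    if isinstance(spec.temperature, BinSpec):
        bins = spec.temperature.resolve(t)
        codes = bins.assign(t)
        counts = np.bincount(codes, minlength=bins.n_bins)
        ref = bins.reference_index
        if counts[ref] == 0:
            raise BinningError(
                f"reference bin {bins.reference_label} has no observations"
            )
        for j, lab in enumerate(bins.labels):
            if j == ref:
                continue
            if counts[j] == 0:
                dropped.append(lab)
                continue
            cols[lab] = (codes == j).astype(float)
            bin_columns.append(lab)
        if dropped:
            logger.warning("dropped empty temperature bins: %s", dropped)
    else:  # quadratic polynomial
        center = float(t.mean())
        cols["temp_c"] = t - center
        cols["temp_c_sq"] = (t - center) ** 2
        bin_columns = ["temp_c", "temp_c_sq"]

    for c in spec.covariates:
        cols[c] = panel[c].to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=panel.index)
    fe_codes, fe_names, fe_levels = _fe_code_columns(panel, spec, spec.fe_dims)
    cluster_codes, n_clusters = _factorize(panel[spec.cluster])
    return DesignMatrices(
        y=y,
        X=X,
        fe_codes=fe_codes,
        fe_names=fe_names,
        fe_levels=fe_levels,
        cluster_codes=cluster_codes,
        n_clusters=n_clusters,
        bins=bins,
        bin_columns=bin_columns,
        dropped_bins=dropped,
    )


# ---------------------------------------------------------------------------
# Fixed-effect absorption (alternating projections)
# ---------------------------------------------------------------------------


def _subtract_group_means(M: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    """Demean M in place within groups; return max absolute adjustment."""
    k = M.shape[1]
    means = np.empty((counts.size, k))
    for j in range(k):
        means[:, j] = np.bincount(codes, weights=M[:, j], minlength=counts.size)
    means /= counts[:, None]
    adj = means[codes]
    M -= adj
    return float(np.abs(adj).max(initial=0.0))


def absorb_fixed_effects(
    y: np.ndarray,
    X: np.ndarray,
    fe_ids: Sequence[np.ndarray],
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterated within-group demeaning over every FE dimension.

    Sweeps across the dimensions until the maximum absolute adjustment in a
    full sweep falls below ``tol``.  Returns demeaned ``(y, X, n_sweeps)``.
    A single dimension reduces to one exact pass of group-mean subtraction.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    fe_ids = list(fe_ids)
    if not fe_ids:
        raise ValueError("at least one FE dimension required")
    M = np.column_stack([np.asarray(y, dtype=float), np.asarray(X, dtype=float)])
    counts = [
        np.bincount(c, minlength=int(c.max()) + 1).astype(float) for c in fe_ids
    ]
    last = np.inf
    for sweep in range(1, max_sweeps + 1):
        delta = 0.0
        for codes, cnt in zip(fe_ids, counts):
            delta = max(delta, _subtract_group_means(M, codes, cnt))
        last = delta
        if delta < tol:
            return M[:, 0], M[:, 1:], sweep
    raise ConvergenceError(
        f"FE absorption did not converge in {max_sweeps} sweeps", residual=last
    )


# ---------------------------------------------------------------------------
# Fitting and cluster-robust inference
# ---------------------------------------------------------------------------


@dataclass
class FEModelFit:
    """Result of one fixed-effects regression.

    ``params`` / ``se`` are indexed by regressor name.  ``cov`` is the CR1
    cluster-robust covariance.  Percentage effects ``e^beta - 1`` and their
    CIs (endpoint-transformed Wald intervals) are exposed by
    :meth:`tidy` and :meth:`bin_table`.
    """

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int
    df_resid: int
    crit: float
    bins: ResolvedBins | None
    bin_columns: list[str]
    dropped_bins: list[str]
    sweeps: int
    spec: ModelSpec | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def tidy(self) -> pd.DataFrame:
        se = self.se
        lo = self.params - self.crit * se
        hi = self.params + self.crit * se
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "pct": np.expm1(self.params),
                "pct_low": np.expm1(lo),
                "pct_high": np.expm1(hi),
            }
        )

    def bin_table(self) -> pd.DataFrame:
        """Per-bin effects with the reference row pinned at exactly zero."""
        if self.bins is None:
            raise ValueError("fit has no binned temperature term")
        rows = []
        tidy = self.tidy()
        mids = self.bins.midpoints
        for j, lab in enumerate(self.bins.labels):
            if lab == self.bins.reference_label:
                rows.append((lab, mids[j], 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
            elif lab in tidy.index:
                r = tidy.loc[lab]
                rows.append(
                    (lab, mids[j], r.beta, r.se, r.ci_low, r.ci_high, r.pct,
                     r.pct_low, r.pct_high)
                )
        return pd.DataFrame(
            rows,
            columns=["bin", "midpoint", "beta", "se", "ci_low", "ci_high",
                     "pct", "pct_low", "pct_high"],
        ).set_index("bin")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "df_resid": int(self.df_resid),
            "crit": float(self.crit),
            "sweeps": int(self.sweeps),
            "reference_bin": self.bins.reference_label if self.bins else None,
            "bin_midpoints": (
                dict(zip(self.bins.labels, self.bins.midpoints.tolist()))
                if self.bins
                else None
            ),
            "dropped_bins": list(self.dropped_bins),
        }


def _cluster_covariance(
    Xd: np.ndarray,
    resid: np.ndarray,
    cluster_codes: np.ndarray,
    n_clusters: int,
    k_model: int,
) -> tuple[np.ndarray, int]:
    """CR1 sandwich: (X'X)^-1 [sum_g s_g s_g'] (X'X)^-1 with the
    G/(G-1) * (N-1)/(N-K) small-sample factor.  ``k_model`` counts estimated
    parameters including absorbed fixed effects."""
    n = Xd.shape[0]
    XtX = Xd.T @ Xd
    S = np.zeros((n_clusters, Xd.shape[1]))
    np.add.at(S, cluster_codes, Xd * resid[:, None])
    meat = S.T @ S
    bread = linalg.inv(XtX)
    G = n_clusters
    dof = max(n - k_model, 1)
    factor = (G / (G - 1)) * ((n - 1) / dof)
    return factor * bread @ meat @ bread, dof


def _critical_value(n_clusters: int, level: float = 0.95) -> float:
    alpha = 0.5 * (1 - level)
    if n_clusters < 50:
        return float(stats.t.ppf(1 - alpha, df=n_clusters - 1))
    return float(stats.norm.ppf(1 - alpha))


def fit(panel: pd.DataFrame, spec: ModelSpec | None = None) -> FEModelFit:
    """Fit the binned (or polynomial) fixed-effects model with clustered SEs."""
    spec = spec or ModelSpec()
    design = build_design(panel, spec)
    if design.n_clusters < 2:
        raise PanelValidationError("clustered inference needs >=2 clusters")
    yd, Xd, sweeps = absorb_fixed_effects(
        design.y,
        design.X.to_numpy(),
        design.fe_codes,
        tol=spec.absorb_tol,
        max_sweeps=spec.max_sweeps,
    )
    names = list(design.X.columns)
    q, r, piv = linalg.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    scale = max(float(diag.max(initial=0.0)), 1.0)
    bad = diag < max(Xd.shape) * np.finfo(float).eps * scale
    if bad.any():
        culprits = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise CollinearityError(
            f"regressors collinear after FE absorption: {culprits}"
        )
    beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
    resid = yd - Xd @ beta
    # Absorbed-parameter count: group means per dimension minus the
    # redundant overall means shared between dimensions (approximation).
    k_absorbed = sum(design.fe_levels) - (len(design.fe_levels) - 1)
    k_model = len(names) + k_absorbed
    cov, dof = _cluster_covariance(
        Xd, resid, design.cluster_codes, design.n_clusters, k_model
    )
    return FEModelFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_obs=len(yd),
        n_clusters=design.n_clusters,
        df_resid=dof,
        crit=_critical_value(design.n_clusters),
        bins=design.bins,
        bin_columns=design.bin_columns,
        dropped_bins=design.dropped_bins,
        sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# Daily aggregation and analysis variants
# ---------------------------------------------------------------------------


def aggregate_daily(panel: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Collapse to one row per park-date.

    Visits are summed, temperature reduced by ``stat`` over the 6 AM - 10 PM
    window, covariates averaged (holiday kept as the day's flag).
    """
    if stat not in ("min", "mean", "max"):
        raise ValueError("stat must be one of min/mean/max")
    validate_panel(panel)
    covs = [c for c in DEFAULT_COVARIATES if c in panel.columns and c != "holiday"]
    agg = {"visits": "sum", "temperature": stat, "city_id": "first"}
    for c in covs:
        agg[c] = "mean"
    if "holiday" in panel.columns:
        agg["holiday"] = "max"
    extra = [
        c for c in ("urban", "region", "park_category", "income_tier")
        if c in panel.columns
    ]
    for c in extra:
        agg[c] = "first"
    daily = panel.groupby(["park_id", "date"], as_index=False, sort=True).agg(agg)
    n_hours = panel.groupby(["park_id", "date"], sort=True).size()
    incomplete = int((n_hours < len(HOURS)).sum())
    if incomplete:
        logger.info("%d park-dates have fewer than 17 in-window hours", incomplete)
    return daily


def daily_mean_temperature(panel: pd.DataFrame) -> pd.DataFrame:
    """Daytime (6 AM - 10 PM) mean temperature per park-date."""
    return (
        panel.groupby(["park_id", "date"], as_index=False, sort=True)
        .agg(daily_mean=("temperature", "mean"), city_id=("city_id", "first"))
    )


def fit_daily(
    panel: pd.DataFrame, spec: ModelSpec | None = None, stat: str = "mean"
) -> FEModelFit:
    """Fit the daily-aggregate variant of the main model."""
    spec = spec or ModelSpec()
    daily = aggregate_daily(panel, stat=stat)
    return fit(_as_daily_panel(daily), spec.daily())


def _as_daily_panel(daily: pd.DataFrame) -> pd.DataFrame:
    # Re-attach a constant in-window hour so panel validation passes; the
    # hour FE is not part of daily specs.
    out = daily.copy()
    out["hour"] = 12
    return out


def fit_periods(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    periods: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, FEModelFit]:
    """Period-of-day regressions on binned daily mean temperature.

    For each period, visits are summed over the period's hours per park-date
    and log(sum + 1) is regressed on bins of the full-day (6 AM - 10 PM) mean
    temperature plus controls and park / time / city-month fixed effects.
    """
    spec = spec or ModelSpec()
    periods = dict(periods or PERIODS)
    window = set(HOURS.tolist())
    for name, hours in periods.items():
        if len(hours) == 0:
            raise ValueError(f"period {name!r} is empty")
        if not set(hours) <= window:
            raise ValueError(f"period {name!r} has hours outside [6, 22]")
    dm = daily_mean_temperature(panel)
    results: dict[str, FEModelFit] = {}
    for name, hours in periods.items():
        sub = panel[panel["hour"].isin(list(hours))]
        daily = aggregate_daily(sub, stat="mean")
        daily = daily.drop(columns=["temperature"]).merge(
            dm[["park_id", "date", "daily_mean"]], on=["park_id", "date"]
        )
        daily = daily.rename(columns={"daily_mean": "temperature"})
        results[name] = fit(_as_daily_panel(daily), spec.daily())
    return results


DAILY_GROUP_BINS = BinSpec(
    width=5.0, reference=(15.0, 20.0), merge_below=0.0, merge_above=30.0
)


@dataclass
class WithinDayProfile:
    """Per-hour relative activity by daily-temperature group.

    For each group, ``beta`` holds the hour-dummy coefficients relative to
    1 PM (the 1 PM entry is exactly zero) and ``se`` the clustered standard
    errors; ``exp(beta)`` is the relative within-day activity magnitude.
    """

    hours: np.ndarray
    beta: dict[str, np.ndarray]
    se: dict[str, np.ndarray]

    @property
    def groups(self) -> list[str]:
        return list(self.beta)

    def rel(self, group: str) -> np.ndarray:
        return np.exp(self.beta[group])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for h, b, s in zip(self.hours, self.beta[g], self.se[g]):
                rows.append((g, int(h), float(b), float(s), float(np.exp(b))))
        return pd.DataFrame(rows, columns=["group", "hour", "beta", "se", "rel"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WithinDayProfile":
        hours = np.sort(df["hour"].unique())
        beta, se = {}, {}
        for g, sub in df.groupby("group", sort=False):
            sub = sub.sort_values("hour")
            beta[g] = sub["beta"].to_numpy(dtype=float)
            se[g] = sub["se"].to_numpy(dtype=float)
        return cls(hours=hours, beta=beta, se=se)


def assign_daily_groups(
    panel: pd.DataFrame, daily_bins: BinSpec = DAILY_GROUP_BINS
) -> tuple[pd.DataFrame, ResolvedBins]:
    """Attach the daily-temperature group label of each row's park-date."""
    dm = daily_mean_temperature(panel)
    resolved = daily_bins.resolve(dm["daily_mean"].to_numpy())
    codes = resolved.assign(dm["daily_mean"].to_numpy())
    labels = np.asarray(resolved.labels)
    dm = dm.assign(daily_group=labels[codes])
    merged = panel.merge(
        dm[["park_id", "date", "daily_mean", "daily_group"]],
        on=["park_id", "date"],
        how="left",
    )
    return merged, resolved


def fit_hourly_profile(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    temp_groups: Sequence[str] | None = None,
    daily_bins: BinSpec = DAILY_GROUP_BINS,
) -> WithinDayProfile:
    """Hour-dummy coefficients (1 PM reference) per daily-temperature group.

    Replaces the temperature bins of the main model with hour-of-day dummies,
    fit separately on the days of each group; park, time and city-month fixed
    effects are retained (the hour FE is what is being estimated).
    """
    spec = spec or ModelSpec()
    tagged, resolved = assign_daily_groups(panel, daily_bins)
    groups = list(temp_groups) if temp_groups is not None else [
        g for g in resolved.labels if (tagged["daily_group"] == g).any()
    ]
    fe_dims = tuple(d for d in spec.fe_dims if d != "hour")
    beta: dict[str, np.ndarray] = {}
    ses: dict[str, np.ndarray] = {}
    for g in groups:
        sub = tagged[tagged["daily_group"] == g]
        if sub[spec.cluster].nunique() < 2:
            if temp_groups is not None:
                raise PanelValidationError(
                    f"group {g!r} spans fewer than two clusters"
                )
            logger.warning("group %r spans <2 clusters; skipped", g)
            continue
        present = np.sort(sub["hour"].unique())
        missing = sorted(set(HOURS.tolist()) - set(present.tolist()))
        if missing:
            raise PanelValidationError(
                f"group {g!r} lacks hours {missing}; cannot fit a full profile"
            )
        cols = {f"h{h}": (sub["hour"] == h).astype(float) for h in HOURS if h != 13}
        X = pd.DataFrame(cols, index=sub.index)
        for c in spec.covariates:
            X[c] = sub[c].to_numpy(dtype=float)
        y = np.log1p(sub["visits"].to_numpy(dtype=float))
        fe_codes, _, fe_levels = _fe_code_columns(sub, spec, fe_dims)
        cluster_codes, n_clusters = _factorize(sub[spec.cluster])
        yd, Xd, _ = absorb_fixed_effects(
            y, X.to_numpy(), fe_codes, tol=spec.absorb_tol, max_sweeps=spec.max_sweeps
        )
        # A covariate can be degenerate inside a group subsample (e.g. no
        # holidays on >30 degC days); drop it rather than abort the profile.
        norms = np.linalg.norm(Xd, axis=0)
        keep = norms > 1e-8 * np.sqrt(len(yd))
        degenerate = [c for c, k in zip(X.columns, keep) if not k]
        if degenerate:
            if any(c.startswith("h") and c[1:].isdigit() for c in degenerate):
                raise PanelValidationError(
                    f"group {g!r}: hour dummies degenerate after absorption"
                )
            logger.warning("group %r: dropping degenerate covariates %s", g, degenerate)
            Xd = Xd[:, keep]
            X = X.loc[:, keep]
        b, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ b
        k_absorbed = sum(fe_levels) - (len(fe_levels) - 1)
        cov, _ = _cluster_covariance(
            Xd, resid, cluster_codes, n_clusters, X.shape[1] + k_absorbed
        )
        coef = pd.Series(b, index=X.columns)
        sd = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
        bvec = np.array([coef.get(f"h{h}", 0.0) for h in HOURS])
        svec = np.array([sd.get(f"h{h}", 0.0) for h in HOURS])
        beta[g] = bvec
        ses[g] = svec
    return WithinDayProfile(hours=HOURS.copy(), beta=beta, se=ses)


MERGED_BINS = BinSpec(width=5.0, reference=(20.0, 25.0), merge_below=0.0, merge_above=30.0)


def fit_stratified(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    strata_column: str = "urban",
) -> dict:
    """Independent merged-bin fits per stratum of ``strata_column``.

    Strata with fewer than two clusters are skipped with a warning.
    """
    spec = spec or ModelSpec()
    if strata_column not in panel.columns:
        raise PanelValidationError(f"strata column {strata_column!r} not in panel")
    merged_spec = replace(spec, temperature=MERGED_BINS)
    out = {}
    for value, sub in panel.groupby(strata_column, sort=True):
        if sub[spec.cluster].nunique() < 2:
            logger.warning(
                "stratum %s=%r has <2 clusters; skipped", strata_column, value
            )
            continue
        out[value] = fit(sub, merged_spec)
    return out
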