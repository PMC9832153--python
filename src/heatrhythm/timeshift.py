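"""Activity time-shift statistic with Monte-Carlo confidence intervals.

On hot days people move outdoor activity toward the evening.  The statistic
asks: after what clock time on a hot day is the remaining amount of outdoor
activity equal to the amount remaining after a reference hour (8 PM by
default) on comfortable 15-20 degC days?  The delay is

    r(ref; base) * q(base) = r(ref + dt; T) * q(T)

where r(h) is the share of the day's activity occurring after hour h
(integrated from the within-day hourly profile) and q(T) the relative daily
activity quantity.  The hourly profile is treated as a piecewise-constant
density on the unit intervals [k, k+1), k = 6..21, which makes r piecewise
linear and the root exact.

Uncertainty: both inputs are estimated curves.  Each is moved jointly to 25
equally-spaced quantiles of its coefficients' normal sampling distribution;
the shift is re-solved on the 25 x 25 grid and the empirical 2.5 / 97.5
percentiles form the confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import BinningError, UnsolvableShiftError
from .estimator import FEModelFit, HOURS, WithinDayProfile

logger = logging.getLogger("heatrhythm.timeshift")

N_HOURS = len(HOURS)


def activity_share_after(rel: np.ndarray, h: float) -> float:
    """Share r(h) of the day's activity occurring after continuous hour h.

    ``rel`` holds the relative activity magnitudes e^beta for hours 6..22;
    the values for hours 6..21 act as densities on [k, k+1) and the hour-22
    value closes the window at 10 PM.  r(6) = 1, r(22) = 0, and r is
    monotone non-increasing and piecewise linear.
    """
    rel = np.asarray(rel, dtype=float)
    if rel.size != N_HOURS:
        raise ValueError(f"profile must cover all {N_HOURS} hours 6..22")
    if not (6.0 <= h <= 22.0):
        raise ValueError(f"hour {h} outside the activity window [6, 22]")
    dens = rel[: N_HOURS - 1]
    total = dens.sum()
    if total <= 0:
        raise ValueError("profile has no mass")
    k = min(int(math.floor(h)), 21)
    after_full = dens[k - 5 :].sum()  # intervals starting at k+1 and later
    partial = dens[k - 6] * (k + 1.0 - h)
    return float(min(max((after_full + partial) / total, 0.0), 1.0))


def _breakpoint_shares(rel: np.ndarray) -> np.ndarray:
    """r evaluated at the integer breakpoints 6..22 (length 17)."""
    dens = np.asarray(rel, dtype=float)[: N_HOURS - 1]
    total = dens.sum()
    cum_after = np.concatenate([np.cumsum(dens[::-1])[::-1], [0.0]])
    return cum_after / total


@dataclass
class DailyQuantityCurve:
    """Relative daily activity magnitude per daily-temperature bin.

    ``q`` is normalised to exactly 1 at the 15-20 degC baseline;
    ``se_log_q`` is the sampling SE of log q (0 at the baseline).
    """

    q: dict[str, float]
    se_log_q: dict[str, float]
    baseline: str = "15-20"

    def __post_init__(self):
        if self.baseline not in self.q:
            raise BinningError(f"baseline bin {self.baseline!r} missing from curve")
        if abs(self.q[self.baseline] - 1.0) > 1e-12:
            raise ValueError("baseline quantity must be exactly 1")
        if any(v <= 0 for v in self.q.values()):
            raise ValueError("all quantity ratios must be positive")

    def to_dict(self) -> dict:
        return {
            "q": {k: float(v) for k, v in self.q.items()},
            "se_log_q": {k: float(v) for k, v in self.se_log_q.items()},
            "baseline": self.baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DailyQuantityCurve":
        return cls(q=dict(d["q"]), se_log_q=dict(d["se_log_q"]), baseline=d["baseline"])


def daily_quantity_curve(
    daily_fit: FEModelFit, baseline: str = "15-20"
) -> DailyQuantityCurve:
    """Turn a daily binned fit into relative quantities q(T) = e^(b_T - b_base).

    The SE of log q uses the clustered covariance of the two coefficients, so
    the baseline entry is exactly 1 with zero SE.
    """
    table = daily_fit.bin_table()
    if baseline not in table.index:
        raise BinningError(f"daily fit has no {baseline!r} bin")
    b_base = float(table.loc[baseline, "beta"])
    cov = daily_fit.cov
    q: dict[str, float] = {}
    se: dict[str, float] = {}
    for lab in table.index:
        b = float(table.loc[lab, "beta"])
        q[lab] = math.exp(b - b_base)
        var = 0.0
        for name, sgn in ((lab, 1.0), (baseline, -1.0)):
            if name in cov.index:
                var += cov.loc[name, name]
        if lab in cov.index and baseline in cov.index:
            var -= 2.0 * cov.loc[lab, baseline]
        se[lab] = math.sqrt(max(var, 0.0)) if lab != baseline else 0.0
    return DailyQuantityCurve(q=q, se_log_q=se, baseline=baseline)


@dataclass
class TimeShiftResult:
    """Solved activity time shift, in minutes after the reference hour."""

    dt_minutes: float
    ref_hour: float
    baseline_group: str
    comparison_group: str
    ci_minutes: tuple[float, float] | None = None
    n_draws: int = 0
    n_unsolvable: int = 0
    high_unsolvable_warning: bool = False
    draws: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "dt_minutes": float(self.dt_minutes),
            "ref_hour": float(self.ref_hour),
            "baseline_group": self.baseline_group,
            "comparison_group": self.comparison_group,
            "ci_minutes": (
                None
                if self.ci_minutes is None
                else [float(self.ci_minutes[0]), float(self.ci_minutes[1])]
            ),
            "n_draws": int(self.n_draws),
            "n_unsolvable": int(self.n_unsolvable),
            "high_unsolvable_warning": bool(self.high_unsolvable_warning),
        }


def _solve(
    rel_base: np.ndarray,
    rel_comp: np.ndarray,
    q_comp: float,
    ref_hour: float,
    q_base: float = 1.0,
) -> float:
    """Exact root of the shift equation on the piecewise-linear share curve."""
    target = q_base * activity_share_after(rel_base, ref_hour)
    v = q_comp * _breakpoint_shares(rel_comp)  # values at hours 6..22
    if target > v[0] + 1e-12:
        raise UnsolvableShiftError(
            f"remaining-activity target {target:.5f} exceeds the comparison "
            f"day's total {v[0]:.5f}; no solution in [6, 22]"
        )
    idx = int(np.flatnonzero(v <= target + 1e-15)[0])
    if idx == 0:
        h_star = 6.0
    else:
        v0, v1 = v[idx - 1], v[idx]
        frac = 0.0 if v0 == v1 else (v0 - target) / (v0 - v1)
        h_star = (idx - 1 + 6) + frac
    return (h_star - ref_hour) * 60.0


def solve_timeshift(
    profile_base: np.ndarray,
    profile_comp: np.ndarray,
    q_comp: float,
    ref_hour: float = 20.0,
    q_base: float = 1.0,
    baseline_group: str = "15-20",
    comparison_group: str = "",
) -> TimeShiftResult:
    """Point estimate of the time shift between two within-day profiles.

    ``profile_*`` are relative-magnitude vectors e^beta over hours 6..22.
    Negative shifts (earlier equivalent time) are permitted; an unattainable
    target raises :class:`UnsolvableShiftError`.
    """
    if comparison_group == baseline_group:
        dt = 0.0
    else:
        dt = _solve(profile_base, profile_comp, q_comp, ref_hour, q_base)
    return TimeShiftResult(
        dt_minutes=dt,
        ref_hour=ref_hour,
        baseline_group=baseline_group,
        comparison_group=comparison_group,
    )


def timeshift_ci(
    profile: WithinDayProfile,
    q_curve: DailyQuantityCurve,
    comparison_group: str,
    baseline_group: str = "15-20",
    ref_hour: float = 20.0,
    n_quantiles: int = 25,
) -> TimeShiftResult:
    """Time shift with a Monte-Carlo CI over coefficient quantiles.

    The within-day pattern (both groups' hour coefficients, moved jointly)
    and the daily quantity curve each take 25 equally-spaced quantiles of
    their normal sampling distributions; the shift is re-solved on the
    n_quantiles x n_quantiles grid.  Unsolvable cells are excluded with a
    logged count; more than 10% unsolvable sets a warning flag.
    """
    for g in (baseline_group, comparison_group):
        if g not in profile.beta:
            raise BinningError(f"profile group {g!r} unavailable; not extrapolating")
    if comparison_group not in q_curve.q:
        raise BinningError(f"quantity bin {comparison_group!r} unavailable")

    b_base, s_base = profile.beta[baseline_group], profile.se[baseline_group]
    b_comp, s_comp = profile.beta[comparison_group], profile.se[comparison_group]
    log_q = math.log(q_curve.q[comparison_group])
    se_q = q_curve.se_log_q[comparison_group]

    point = solve_timeshift(
        np.exp(b_base), np.exp(b_comp), math.exp(log_q),
        ref_hour=ref_hour,
        baseline_group=baseline_group,
        comparison_group=comparison_group,
    ).dt_minutes

    probs = (np.arange(1, n_quantiles + 1)) / (n_quantiles + 1)
    z = stats.norm.ppf(probs)
    draws = []
    n_unsolvable = 0
    for zi in z:
        rb = np.exp(b_base + zi * s_base)
        rc = np.exp(b_comp + zi * s_comp)
        for zj in z:
            qv = math.exp(log_q + zj * se_q)
            try:
                draws.append(_solve(rb, rc, qv, ref_hour))
            except UnsolvableShiftError:
                n_unsolvable += 1
    n_total = n_quantiles * n_quantiles
    if n_unsolvable:
        logger.info("%d / %d quantile-grid cells unsolvable", n_unsolvable, n_total)
    arr = np.asarray(draws)
    if arr.size == 0:
        raise UnsolvableShiftError("every quantile-grid cell was unsolvable")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return TimeShiftResult(
        dt_minutes=point,
        ref_hour=ref_hour,
        baseline_group=baseline_group,
        comparison_group=comparison_group,
        ci_minutes=(min(lo, point), max(hi, point)),
        n_draws=n_total,
        n_unsolvable=n_unsolvable,
        high_unsolvable_warning=n_unsolvable > 0.1 * n_total,
        draws=arr,
    )
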