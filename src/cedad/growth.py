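"""Growth prognosis, exponential regression of count series, segment comparison.

Cell-count series are fitted by ordinary least squares of log2(count) on
time, so the slope is directly the per-day growth exponent ``g`` on the
same scale as the assay-derived exponent ``d + log2(V)``, with a
t-distribution 95% CI on the slope and a pointwise 95% band on the mean
curve.  Comparing the regression slope before and after a split day
against the assay prognosis reveals secondary treatment effects: growth
that slows only after the measurement window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rates import RateEstimates, fold_change

__all__ = [
    "GrowthCurve",
    "ExponentialFit",
    "SegmentComparison",
    "prognosis",
    "fit_exponential",
    "doubling_time",
    "compare_segments",
]


@dataclass
class GrowthCurve:
    """Predicted cell numbers over time with a 95% band."""

    times: np.ndarray
    n_pred: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    source: str
    N0: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.times, "n_pred": self.n_pred, "lower": self.lower, "upper": self.upper}
        )


@dataclass
class ExponentialFit:
    """Log-linear least-squares fit of a count series."""

    N0: float
    g: float
    g_ci: tuple[float, float]
    n_obs: int
    df_resid: int
    t_range: tuple[float, float]
    _result: object = None

    def predict(self, times) -> GrowthCurve:
        """Evaluate the fitted curve with a pointwise 95% mean band."""
        times = np.asarray(times, dtype=float)
        X = sm.add_constant(times, has_constant="add")
        pred = self._result.get_prediction(X)
        frame = pred.summary_frame(alpha=0.05)
        return GrowthCurve(
            times=times,
            n_pred=2.0 ** frame["mean"].to_numpy(),
            lower=2.0 ** frame["mean_ci_lower"].to_numpy(),
            upper=2.0 ** frame["mean_ci_upper"].to_numpy(),
            source="counts",
            N0=self.N0,
        )


@dataclass
class SegmentComparison:
    """Side-by-side growth exponents over the full/early/late windows.

    ``secondary_effect`` is True when the late-segment slope CI lies
    entirely below the early-segment slope CI (growth slowed after the
    split day), False when the CIs overlap, and None when a segment is
    not estimable.
    """

    full: ExponentialFit | None
    early: ExponentialFit | None
    late: ExponentialFit | None
    split_day: float
    cedad_g: float | None
    cedad_g_ci: tuple[float, float] | None
    secondary_effect: bool | None


def prognosis(rates: RateEstimates, N0: float, times) -> GrowthCurve:
    """Project cell numbers from the assay's division and death rates.

    ``n_pred(t) = N0 * 2**((d + log2 V) * t)``; the band propagates the
    bootstrap CI of the growth exponent when available (otherwise it
    collapses onto the point curve).
    """
    if not N0 > 0:
        raise ValueError("N0 must be > 0")
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    n_pred = N0 * np.array([fold_change(rates.d, rates.V, t) for t in times])
    g_lo, g_hi = rates.ci.get("g", (rates.g, rates.g))
    lower = N0 * 2.0 ** (g_lo * times)
    upper = N0 * 2.0 ** (g_hi * times)
    return GrowthCurve(times, n_pred, lower, upper, source="cedad", N0=float(N0))


def _effective_counts(series: pd.DataFrame) -> pd.DataFrame:
    df = series.copy()
    if "split_factor" in df.columns:
        df["count"] = df["count"] * df["split_factor"]
    return df


def fit_exponential(
    series: pd.DataFrame, t_range: tuple[float, float] | None = None
) -> ExponentialFit:
    """Least-squares exponential regression of a count series.

    Fits log2(count) ~ day by OLS over ``t_range`` (inclusive; default
    the full span).  Replicate wells enter as independent observations;
    a ``split_factor`` column, when present, multiplies counts before
    fitting (passaging correction).
    """
    df = _effective_counts(series)
    if t_range is not None:
        a, b = t_range
        df = df[(df["day"] >= a) & (df["day"] <= b)]
    if df.empty or df["day"].nunique() < 2:
        raise ValueError("need counts at >= 2 distinct time points in range")
    if (df["count"] <= 0).any():
        raise ValueError("counts must be positive for log-linear regression")

    t = df["day"].to_numpy(dtype=float)
    y = np.log2(df["count"].to_numpy(dtype=float))
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return ExponentialFit(
        N0=float(2.0 ** res.params[0]),
        g=float(res.params[1]),
        g_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n_obs=len(df),
        df_resid=int(res.df_resid),
        t_range=(float(t.min()), float(t.max())),
        _result=res,
    )


def doubling_time(g: float) -> float:
    """Population doubling time in hours, T_d = 24 / g.

    Negative for a declining population (interpret the magnitude as a
    halving time); undefined at g = 0.
    """
    if g == 0:
        raise ValueError("doubling time undefined at zero growth")
    return 24.0 / g


def compare_segments(
    series: pd.DataFrame,
    rates: RateEstimates | None = None,
    split_day: float = 2.0,
) -> SegmentComparison:
    """Compare growth before and after ``split_day`` and against the assay.

    Fits exponents over the full range, the early segment (start to
    split) and the late segment (split to end); the split-day counts
    belong to both segments.  Flags a secondary effect when the late 95%
    slope CI sits entirely below the early one.  Invariant to rescaling
    of the counts (cells vs cells/ml).
    """
    df = _effective_counts(series)
    tmin, tmax = float(df["day"].min()), float(df["day"].max())

    def _try(rng):
        try:
            return fit_exponential(series, rng)
        except ValueError:
            return None

    full = _try((tmin, tmax))
    early = _try((tmin, split_day))
    late = _try((split_day, tmax))

    secondary = None
    if early is not None and late is not None:
        lo_e, hi_l = early.g_ci[0], late.g_ci[1]
        if np.isfinite(lo_e) and np.isfinite(hi_l):
            secondary = bool(hi_l < lo_e)
    return SegmentComparison(
        full=full,
        early=early,
        late=late,
        split_day=float(split_day),
        cedad_g=None if rates is None else rates.g,
        cedad_g_ci=None if rates is None else rates.ci.get("g"),
        secondary_effect=secondary,
    )
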