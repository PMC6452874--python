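"""Selection coefficients from competition assays, and doubling times.

Two strains mixed 1:1 and grown together diverge exponentially; the log2
ratio of their abundances is linear in time with slope equal to the
difference in growth rates (doublings/h):

    log2(N_agg/N_sol)(t) = log2(N0_agg/N0_sol) + t * (omega_agg - omega_sol)

The selection coefficient is that slope converted to natural-log units,

    S = ln(2) * (omega_agg - omega_sol)    [per hour],

estimated here by ordinary least squares on the log2-ratio time series
(:class:`SelectionModel`).  Strain abundances come from qPCR: a standard
dilution series calibrates Ct against log10 gene copies per strain
(:func:`fit_standard_curve`), and Ct values are inverted through that
curve (:func:`quantify_copies`).  Culture dilutions cancel in the ratio,
so absolute copy numbers are never compared across timepoints.

Doubling times of individually grown strains are read off OD600 growth
curves via a smoothing spline on ln(OD): tau = ln2 / max slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import make_smoothing_spline

from .synthetic import CompetitionSeries

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify_copies",
    "ct_from_copies",
    "log2_ratio_series",
    "SelectionModel",
    "SelectionResults",
    "estimate_selection_coefficient",
    "per_replicate_estimates",
    "DoublingTimeResult",
    "doubling_time_from_growth_curve",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r2: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10**(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(log10_copies, ct) -> StandardCurve:
    """Least-squares calibration from a dilution series.

    Requires at least three points with non-zero spread in log10 copies.
    A non-negative slope yields a curve flagged invalid (``valid`` False)
    rather than an exception, mirroring a failed amplification run.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("log10_copies must not all be equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return StandardCurve(slope=float(slope), intercept=float(intercept), r2=r2)


def quantify_copies(ct, curve: StandardCurve):
    """Invert Ct through a standard curve: copies = 10**((ct - intercept)/slope)."""
    if not curve.valid:
        raise ValueError("standard curve invalid (slope must be negative)")
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def ct_from_copies(copies, curve: StandardCurve):
    """Forward map copies -> Ct on the same calibration line."""
    if not curve.valid:
        raise ValueError("standard curve invalid (slope must be negative)")
    return curve.slope * np.log10(np.asarray(copies, dtype=float)) + curve.intercept


def log2_ratio_series(series: CompetitionSeries) -> pd.DataFrame:
    """Per-timepoint log2(copies_agg / copies_sol) of one replicate."""
    if np.any(series.copies_agg <= 0) or np.any(series.copies_sol <= 0):
        raise ValueError("copy numbers must be strictly positive")
    return pd.DataFrame(
        {
            "time_h": series.times,
            "log2_ratio": np.log2(series.copies_agg / series.copies_sol),
            "replicate": series.replicate,
        }
    )


class SelectionModel:
    """OLS model of the log2 strain ratio against time.

    Parameters
    ----------
    times : array-like
        Sampling times in hours (replicates pooled into one vector).
    log2_ratios : array-like
        log2(N_agg / N_sol) at each time.

    Fitting returns a :class:`SelectionResults` whose ``S`` is the slope
    in log2 units per hour multiplied by ln 2 (natural-log selection
    coefficient per hour).
    """

    def __init__(self, times, log2_ratios):
        self.times = np.asarray(times, dtype=float)
        self.log2_ratios = np.asarray(log2_ratios, dtype=float)
        if self.times.size != self.log2_ratios.size:
            raise ValueError("times and log2_ratios must have equal length")
        if np.unique(self.times).size < 2:
            raise ValueError("need >= 2 distinct times to estimate a slope")

    @classmethod
    def from_series(cls, series: "CompetitionSeries | list[CompetitionSeries]") -> "SelectionModel":
        """Pool the log2 ratios of one or more replicates into one model."""
        if isinstance(series, CompetitionSeries):
            series = [series]
        frames = [log2_ratio_series(s) for s in series]
        pooled = pd.concat(frames, ignore_index=True)
        return cls(pooled["time_h"], pooled["log2_ratio"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_h",
                       ratio_col: str = "log2_ratio") -> "SelectionModel":
        return cls(df[time_col], df[ratio_col])

    def fit(self) -> "SelectionResults":
        X = sm.add_constant(self.times)
        res = sm.OLS(self.log2_ratios, X).fit()
        slope = float(res.params[1])
        se = float(res.bse[1])
        fitted = res.fittedvalues
        ss_tot = float(np.sum((self.log2_ratios - self.log2_ratios.mean()) ** 2))
        ss_res = float(np.sum((self.log2_ratios - fitted) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return SelectionResults(
            slope_log2=slope,
            intercept_log2=float(res.params[0]),
            se_slope=se,
            r2=r2,
            n_points=int(self.times.size),
            _sm_results=res,
        )


@dataclass
class SelectionResults:
    """Estimated selection coefficient with uncertainty and fit quality.

    ``S = slope_log2 * ln 2`` (per hour) holds to full precision;
    ``se_S`` is the OLS slope standard error on the same scale.
    """

    slope_log2: float
    intercept_log2: float
    se_slope: float
    r2: float
    n_points: int
    _sm_results: object = None

    @property
    def S(self) -> float:
        return self.slope_log2 * LN2

    @property
    def se_S(self) -> float:
        return self.se_slope * LN2

    def summary(self) -> str:
        lines = [
            "Selection coefficient (log2-ratio OLS)",
            "--------------------------------------",
            f"n points          {self.n_points:>10d}",
            f"slope (log2/h)    {self.slope_log2:>10.5f}",
            f"S (1/h)           {self.S:>10.5f}",
            f"se(S) (1/h)       {self.se_S:>10.5f}",
            f"R^2               {self.r2:>10.4f}",
        ]
        return "\n".join(lines)


def estimate_selection_coefficient(times, log2_ratios) -> SelectionResults:
    """Convenience wrapper: fit a :class:`SelectionModel` in one call."""
    return SelectionModel(times, log2_ratios).fit()


def per_replicate_estimates(series_list: "list[CompetitionSeries]") -> pd.DataFrame:
    """Optional per-replicate mode: one fit per replicate plus their mean.

    Returns a table with one row per replicate (S, se, r2, n) and the
    across-replicate mean S in the ``S_mean`` column attribute-style
    (same value repeated), for reporting alongside the pooled fit.
    """
    rows = []
    for s in series_list:
        r = SelectionModel.from_series(s).fit()
        rows.append({"replicate": s.replicate, "S_per_h": r.S, "se_S": r.se_S,
                     "r2": r.r2, "n": r.n_points})
    out = pd.DataFrame(rows)
    out["S_mean"] = out["S_per_h"].mean()
    return out


@dataclass
class DoublingTimeResult:
    """Doubling time from a growth curve; ``grew`` is False when the
    maximum specific growth rate is non-positive (tau undefined)."""

    tau: float | None
    mu_max: float
    grew: bool


def doubling_time_from_growth_curve(times, od, smoothing: float | None = None
                                    ) -> DoublingTimeResult:
    """Doubling time via a smoothing spline on ln(OD600).

    A cubic smoothing spline is fitted to ln(OD) against time (penalty
    ``smoothing``; ``None`` selects it by generalised cross-validation).
    The maximum of its first derivative over the observed range is the
    maximum specific growth rate mu_max (1/h); tau = ln2 / mu_max.
    Cultures held in exponential phase attain mu_max over most of the
    curve, so the maximum-derivative rule reads off the exponential rate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 points for a spline fit")
    if np.any(y <= 0):
        raise ValueError("OD values must be positive for a log fit")
    spl = make_smoothing_spline(t, np.log(y), lam=smoothing)
    grid = np.linspace(t[0], t[-1], 512)
    mu = spl.derivative()(grid)
    mu_max = float(mu.max())
    if mu_max <= 1e-12:
        return DoublingTimeResult(tau=None, mu_max=mu_max, grew=False)
    return DoublingTimeResult(tau=LN2 / mu_max, mu_max=mu_max, grew=True)
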