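"""Gompertz smoothing and germination-rate regression (estimation stages 1–2).

Stage 1 smooths each dish's cumulative germination curve with a 3-parameter
Gompertz sigmoid, G(t) = A·exp(−exp(−k·(t − T_i))), and reads percentile
times off the fitted curve analytically.  Stage 2 regresses the germination
rate GR(g) = 1/t(g) of each population percentile g on the water potential
of the medium; under the hydrotime model the relation is linear with common
slope 1/theta_H across percentiles, and its ψ-axis intercept is the
percentile's base water potential psi_b(g).  The regression of recovered
psi_b(g) on the standard normal quantile of g then yields psi_b50
(intercept at g = 0.5) and sigma_psib (slope).

Percentiles are fractions of *viable* seeds, not of the final germinated
count, consistent with the threshold-distribution reading of g; percentiles
above a dish's asymptote are "not reached" at that water potential and are
dropped from that percentile's regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtri

from .core_model import HydrotimeParams, model_r2
from .synthetic_data import TimeCourse

__all__ = [
    "DEFAULT_PERCENTILES",
    "GompertzFit",
    "RateLine",
    "ParallelismSummary",
    "RateRegressionEstimate",
    "GompertzFitError",
    "fit_gompertz",
    "time_to_percentile",
    "fit_rate_line",
    "assess_parallelism",
    "estimate_by_rate_regression",
]

#: Percentile grid 5%…90% in steps of 5%.
DEFAULT_PERCENTILES: tuple[float, ...] = tuple(
    np.round(np.arange(0.05, 0.901, 0.05), 2)
)


class GompertzFitError(RuntimeError):
    """Gompertz fit failed; carries the initial values that were tried."""

    def __init__(self, message: str, p0: tuple[float, float, float] | None = None):
        super().__init__(message if p0 is None else f"{message} (initial values {p0})")
        self.p0 = p0


@dataclass(frozen=True)
class GompertzFit:
    """Fitted Gompertz curve G(t) = A·exp(−exp(−k·(t − T_i))) for one dish.

    asymptote A ∈ (0, 1] is the final germination fraction, rate k (1/day)
    the shape parameter, inflection_time T_i (days) where G = A/e.
    """

    asymptote: float
    rate: float
    inflection_time: float
    r2: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.asymptote * np.exp(-np.exp(-self.rate * (t - self.inflection_time)))


def _gompertz(t, a, k, ti):
    return a * np.exp(-np.exp(-k * (t - ti)))


def _initial_values(days: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starts: A = final fraction, T_i = first day reaching half
    of final, k = 4 / (t90 − t10 estimate) with a floor of 0.05."""
    a0 = float(y[-1])
    t_half = float(days[np.argmax(y >= 0.5 * a0)])
    t10 = float(days[np.argmax(y >= 0.1 * a0)])
    t90 = float(days[np.argmax(y >= 0.9 * a0)])
    k0 = 4.0 / (t90 - t10) if t90 > t10 else 1.0
    return a0, max(k0, 0.05), max(t_half, float(days[0]))


def fit_gompertz(tc: TimeCourse) -> GompertzFit:
    """Least-squares Gompertz fit of one dish's cumulative fraction curve.

    Raises
    ------
    GompertzFitError
        If the dish recorded no germination, has fewer than four scoring
        days, or the optimizer fails to converge (the error carries the
        initial values used).
    """
    if tc.days.size < 4:
        raise GompertzFitError(
            f"need ≥ 4 scoring days to fit a Gompertz curve, got {tc.days.size}"
        )
    y = tc.fractions
    if np.all(tc.cum_germinated == 0):
        raise GompertzFitError(
            f"no germination recorded for {tc.population} rep {tc.replicate} "
            f"at {tc.psi} MPa; nothing to fit"
        )
    p0 = _initial_values(tc.days, y)
    try:
        popt, _ = optimize.curve_fit(
            _gompertz,
            tc.days,
            y,
            p0=p0,
            bounds=([1e-6, 1e-4, 1e-6], [1.0, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise GompertzFitError(f"Gompertz fit did not converge: {exc}", p0=p0) from exc
    a, k, ti = (float(v) for v in popt)
    try:
        r2 = model_r2(y, _gompertz(tc.days, a, k, ti))
    except ValueError:  # constant observed curve (e.g. single step at day 1)
        r2 = float("nan")
    return GompertzFit(asymptote=a, rate=k, inflection_time=ti, r2=r2)


def time_to_percentile(fit: GompertzFit, g: float) -> float:
    """Day at which the fitted curve reaches fraction ``g`` of viable seeds.

    Analytic inversion ``t(g) = T_i − ln(−ln(g/A))/k``.  Returns NaN when
    the percentile is never reached (``g ≥ A``).
    """
    if not 0.0 < g < 1.0:
        raise ValueError(f"percentile fraction must lie in (0, 1), got {g}")
    if g >= fit.asymptote:
        return float("nan")
    return fit.inflection_time - math.log(-math.log(g / fit.asymptote)) / fit.rate


@dataclass(frozen=True)
class RateLine:
    """Linear GR(g)-vs-ψ relation for one population percentile ``g``.

    ``psi_b_g`` is the ψ-axis intercept (where GR = 0), i.e. the base water
    potential of fraction g.  A line with non-positive slope is physically
    invalid (rates must increase with water potential) and is retained for
    diagnostics but excluded from theta_H pooling.
    """

    g: float
    slope: float
    intercept: float
    psi_b_g: float
    r2: float
    points: tuple[tuple[float, float], ...]

    @property
    def valid(self) -> bool:
        return self.slope > 0


def fit_rate_line(points: Sequence[tuple[float, float]], g: float) -> RateLine:
    """OLS regression of germination rate on water potential for fraction g.

    ``points`` are (psi, GR(g)) pairs; non-finite rates are dropped.  At
    least two distinct water potentials are required.
    """
    pts = [(float(p), float(r)) for p, r in points if np.isfinite(r)]
    psis = np.array([p for p, _ in pts])
    rates = np.array([r for _, r in pts])
    if np.unique(psis).size < 2:
        raise ValueError(
            f"need ≥ 2 distinct water potentials with finite rates for g={g}, "
            f"got {np.unique(psis).size}"
        )
    res = stats.linregress(psis, rates)
    slope, intercept = float(res.slope), float(res.intercept)
    psi_b_g = -intercept / slope if slope > 0 else float("nan")
    return RateLine(
        g=float(g),
        slope=slope,
        intercept=intercept,
        psi_b_g=psi_b_g,
        r2=float(res.rvalue) ** 2,
        points=tuple(pts),
    )


@dataclass(frozen=True)
class ParallelismSummary:
    """Pooled slope of the percentile rate lines and its dispersion.

    When the lines are parallel (the hydrotime assumption) their common
    slope is 1/theta_H; cv is the population coefficient of variation of
    the individual slopes, a descriptive diagnostic of parallelism.
    """

    common_slope: float
    cv: float
    theta_H: float
    n_lines: int


def assess_parallelism(lines: Iterable[RateLine]) -> ParallelismSummary:
    """Mean slope across valid percentile lines, its CV, and theta_H = 1/slope."""
    slopes = np.array([ln.slope for ln in lines if ln.valid])
    if slopes.size < 2:
        raise ValueError("need ≥ 2 valid (positive-slope) rate lines")
    mean_slope = float(slopes.mean())
    cv = float(slopes.std(ddof=0) / mean_slope)
    return ParallelismSummary(
        common_slope=mean_slope,
        cv=cv,
        theta_H=1.0 / mean_slope,
        n_lines=int(slopes.size),
    )


@dataclass(frozen=True)
class RateRegressionEstimate:
    """Stage 1–2 parameter estimate with its intermediate objects."""

    params: HydrotimeParams
    parallelism: ParallelismSummary
    lines: tuple[RateLine, ...]
    gompertz_fits: Mapping[float, GompertzFit]


def estimate_by_rate_regression(
    timecourses: Sequence[TimeCourse],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> RateRegressionEstimate:
    """Full stage 1–2 estimate from one replicate's multi-ψ time courses.

    Fits a Gompertz curve per water potential, extracts percentile rates,
    regresses each percentile's rate on ψ, pools the slopes into theta_H,
    takes psi_b50 from the g = 0.5 line's ψ-axis intercept (falling back to
    the intercept of the psi_b(g)-vs-Φ⁻¹(g) regression if the median line
    is invalid), and sigma_psib from the slope of that same regression.

    Water potentials where a dish shows no germination are skipped;
    percentiles not reached at a given ψ are dropped from that g's
    regression.
    """
    fits: dict[float, GompertzFit] = {}
    for tc in timecourses:
        try:
            fits[tc.psi] = fit_gompertz(tc)
        except GompertzFitError:
            continue  # e.g. no germination at the most negative psi
    if len(fits) < 2:
        raise ValueError("need Gompertz fits at ≥ 2 water potentials")

    lines: list[RateLine] = []
    for g in percentiles:
        pts = []
        for psi, fit in sorted(fits.items()):
            t_g = time_to_percentile(fit, g)
            if np.isfinite(t_g) and t_g > 0:
                pts.append((psi, 1.0 / t_g))
        psis = {p for p, _ in pts}
        if len(psis) >= 2:
            lines.append(fit_rate_line(pts, g))
    par = assess_parallelism(lines)

    valid = [ln for ln in lines if ln.valid]
    probit = np.array([ndtri(ln.g) for ln in valid])
    psi_b = np.array([ln.psi_b_g for ln in valid])
    if valid and np.unique(probit).size >= 2:
        reg = stats.linregress(probit, psi_b)
        sigma = float(reg.slope)
        psi_b50_fallback = float(reg.intercept)
    else:
        sigma, psi_b50_fallback = float("nan"), float("nan")

    median_lines = [ln for ln in valid if abs(ln.g - 0.5) < 1e-9]
    psi_b50 = median_lines[0].psi_b_g if median_lines else psi_b50_fallback

    params = HydrotimeParams(
        theta_H=par.theta_H,
        psi_b50=psi_b50,
        sigma_psib=sigma if np.isfinite(sigma) and sigma > 0 else float("nan"),
    ) if np.isfinite(psi_b50) and np.isfinite(sigma) and sigma > 0 else None
    if params is None:
        raise ValueError(
            "rate-regression stage could not recover a full parameter triple "
            f"(psi_b50={psi_b50}, sigma={sigma})"
        )
    return RateRegressionEstimate(
        params=params,
        parallelism=par,
        lines=tuple(lines),
        gompertz_fits=fits,
    )
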