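"""Per-replicate nonlinear least-squares hydrotime fitting (stage 3).

Each replicate (dish k of a population observed at every water potential)
contributes one fitting unit: all (ψ, day, cumulative fraction) observations
are pooled and

    Σ [ y_obs − Φ((ψ − theta_H/t − psi_b50) / sigma_psib) ]²

is minimized over (theta_H, psi_b50, sigma_psib) with theta_H > 0 and
sigma_psib > 0.  The objective is least squares on the fraction scale
through the normal CDF — well-defined at y = 0 and y = 1, so no probit
clipping is needed.  Warm starts come from the rate-regression stages
(:func:`~hydrotime.curve_fitting.estimate_by_rate_regression`), with a
mid-range fallback of (20 MPa·d, −2.5 MPa, 0.6 MPa) when those stages fail.

Population summaries are replicate means with SD / SE dispersion, the
quantities a parameter table for seed-lot comparison reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .core_model import HydrotimeParams, model_r2, predict_cumulative_fraction
from .curve_fitting import estimate_by_rate_regression
from .synthetic_data import TimeCourse

__all__ = [
    "FALLBACK_INIT",
    "ReplicateFit",
    "PopulationSummary",
    "FitConvergenceError",
    "fit_hydrotime_replicate",
    "fit_experiment",
    "summarize_population",
    "predicted_curves",
]

#: Mid-range fallback initial values used when the rate-regression warm
#: start cannot be computed.
FALLBACK_INIT = HydrotimeParams(theta_H=20.0, psi_b50=-2.5, sigma_psib=0.6)


class FitConvergenceError(RuntimeError):
    """NLS did not converge; carries the initial values and best-so-far."""

    def __init__(self, message: str, init: HydrotimeParams, best: np.ndarray):
        super().__init__(f"{message} (init {init}, best-so-far {best})")
        self.init = init
        self.best = best


@dataclass(frozen=True)
class ReplicateFit:
    """Hydrotime parameters fitted to one replicate across water potentials.

    ``r2`` is the coefficient of determination of observed vs predicted
    cumulative fractions pooled over all water potentials and scoring days.
    """

    population: str
    replicate: int
    params: HydrotimeParams
    r2: float
    n_obs: int


@dataclass(frozen=True)
class PopulationSummary:
    """Replicate mean ± dispersion of each hydrotime parameter.

    ``*_sd`` is the sample standard deviation across replicate fits (0 when
    only one replicate is available) and ``*_se = sd/√n``.
    """

    population: str
    n_replicates: int
    theta_H_mean: float
    theta_H_sd: float
    theta_H_se: float
    psi_b50_mean: float
    psi_b50_sd: float
    psi_b50_se: float
    sigma_psib_mean: float
    sigma_psib_sd: float
    sigma_psib_se: float
    r2_mean: float


def _pool_observations(
    timecourses: Sequence[TimeCourse],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    psi, t, y = [], [], []
    for tc in timecourses:
        psi.append(np.full(tc.days.size, tc.psi))
        t.append(tc.days)
        y.append(tc.fractions)
    return np.concatenate(psi), np.concatenate(t), np.concatenate(y)


def _clip_init(p: HydrotimeParams) -> HydrotimeParams:
    """Keep warm starts inside a sane box so the optimizer starts in-bounds."""
    return HydrotimeParams(
        theta_H=float(np.clip(p.theta_H, 0.5, 500.0)),
        psi_b50=float(np.clip(p.psi_b50, -20.0, -1e-3)),
        sigma_psib=float(np.clip(p.sigma_psib, 0.01, 10.0)),
    )


def fit_hydrotime_replicate(
    timecourses: Sequence[TimeCourse],
    init: HydrotimeParams | None = None,
) -> ReplicateFit:
    """Fit (theta_H, psi_b50, sigma_psib) to one replicate's time courses.

    ``timecourses`` are the dishes of a single population replicate at ≥ 2
    distinct water potentials.  When ``init`` is None the rate-regression
    stages provide the starting point, with :data:`FALLBACK_INIT` as a
    last resort.  The result is deterministic given data and init.

    Raises
    ------
    ValueError
        Fewer than two distinct water potentials (the parameters are not
        identifiable from a single ψ level), or no germination at all.
    FitConvergenceError
        The optimizer stopped without convergence.
    """
    # canonical order makes the result bit-identical under input reordering
    timecourses = sorted(timecourses, key=lambda tc: (tc.psi, tc.replicate))
    psis = {tc.psi for tc in timecourses}
    if len(psis) < 2:
        raise ValueError(
            "parameters not identifiable: need time courses at ≥ 2 distinct "
            f"water potentials, got {sorted(psis)}"
        )
    psi_obs, t_obs, y_obs = _pool_observations(timecourses)
    if np.all(y_obs == 0):
        raise ValueError("no germination recorded in any dish; nothing to fit")

    if init is None:
        try:
            init = estimate_by_rate_regression(timecourses).params
        except (ValueError, RuntimeError):
            init = FALLBACK_INIT
    init = _clip_init(init)

    def residuals(x: np.ndarray) -> np.ndarray:
        theta, b50, sigma = x
        return y_obs - ndtr((psi_obs - theta / t_obs - b50) / sigma)

    res = optimize.least_squares(
        residuals,
        x0=[init.theta_H, init.psi_b50, init.sigma_psib],
        bounds=([1e-8, -np.inf, 1e-8], [np.inf, np.inf, np.inf]),
        method="trf",
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=10000,
    )
    if res.status <= 0:
        raise FitConvergenceError("hydrotime NLS did not converge", init, res.x)
    params = HydrotimeParams(*(float(v) for v in res.x))
    r2 = model_r2(y_obs, y_obs - residuals(res.x))
    tc0 = timecourses[0]
    return ReplicateFit(
        population=tc0.population,
        replicate=tc0.replicate,
        params=params,
        r2=r2,
        n_obs=int(y_obs.size),
    )


def summarize_population(fits: Sequence[ReplicateFit]) -> PopulationSummary:
    """Aggregate replicate fits of one population into mean ± SD (SE)."""
    if len(fits) == 0:
        raise ValueError("no replicate fits to summarize")
    pops = {f.population for f in fits}
    if len(pops) != 1:
        raise ValueError(f"fits span multiple populations: {sorted(pops)}")
    n = len(fits)

    def stats_of(values: list[float]) -> tuple[float, float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        return float(arr.mean()), sd, sd / np.sqrt(n)

    th = stats_of([f.params.theta_H for f in fits])
    b50 = stats_of([f.params.psi_b50 for f in fits])
    sg = stats_of([f.params.sigma_psib for f in fits])
    return PopulationSummary(
        population=fits[0].population,
        n_replicates=n,
        theta_H_mean=th[0], theta_H_sd=th[1], theta_H_se=th[2],
        psi_b50_mean=b50[0], psi_b50_sd=b50[1], psi_b50_se=b50[2],
        sigma_psib_mean=sg[0], sigma_psib_sd=sg[1], sigma_psib_se=sg[2],
        r2_mean=float(np.mean([f.r2 for f in fits])),
    )


def fit_experiment(
    timecourses: Sequence[TimeCourse],
    init: HydrotimeParams | None = None,
) -> tuple[list[ReplicateFit], list[PopulationSummary]]:
    """Fit every (population, replicate) unit in a score sheet.

    Replicate k of a population at each water potential is one fitting unit
    (index pairing).  Returns replicate fits and per-population summaries,
    both in sorted (population, replicate) order.
    """
    groups: dict[tuple[str, int], list[TimeCourse]] = {}
    for tc in timecourses:
        groups.setdefault((tc.population, tc.replicate), []).append(tc)
    fits = [
        fit_hydrotime_replicate(group, init=init)
        for _, group in sorted(groups.items())
    ]
    by_pop: dict[str, list[ReplicateFit]] = {}
    for f in fits:
        by_pop.setdefault(f.population, []).append(f)
    summaries = [summarize_population(v) for _, v in sorted(by_pop.items())]
    return fits, summaries


def predicted_curves(
    source: HydrotimeParams | ReplicateFit | PopulationSummary,
    psi_levels: Sequence[float],
    days: Sequence[float],
) -> pd.DataFrame:
    """Model cumulative-fraction table over a ψ × day grid (for plots / QC).

    ``source`` may be a parameter triple, a replicate fit, or a population
    summary (whose replicate-mean parameters are used).  Columns: psi_MPa,
    day, predicted_fraction; nondecreasing along days within each water
    potential.
    """
    if isinstance(source, ReplicateFit):
        params = source.params
    elif isinstance(source, PopulationSummary):
        params = HydrotimeParams(
            source.theta_H_mean, source.psi_b50_mean, source.sigma_psib_mean
        )
    else:
        params = source
    days = np.asarray(days, dtype=float)
    frames = []
    for psi in psi_levels:
        frames.append(
            pd.DataFrame(
                {
                    "psi_MPa": float(psi),
                    "day": days,
                    "predicted_fraction": predict_cumulative_fraction(
                        params, float(psi), days
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
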