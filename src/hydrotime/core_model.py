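"""Closed-form mathematics of the hydrotime germination model.

The hydrotime model is a threshold model for the timing of seed germination
under water stress (Gummerson-type).  Each seed carries a *base water
potential* ``psi_b`` — the minimum water potential of the incubation medium
at which that seed can still germinate — and ``psi_b`` varies across seeds
of a population as ``Normal(psi_b50, sigma_psib)``.  A seed germinates once
it has accumulated a fixed amount of supra-threshold "hydrotime",

    theta_H = (psi - psi_b(g)) * t_g        [MPa * day]

so the germination time of population fraction ``g`` at medium water
potential ``psi`` is ``t_g = theta_H / (psi - psi_b(g))`` and the
germination rate ``GR(g) = 1/t_g`` is linear in ``psi``.  Combining the two
with the normal threshold distribution gives the cumulative germination
fraction at time ``t``:

    F(t; psi) = Phi((psi - theta_H/t - psi_b50) / sigma_psib)

with ``Phi`` the standard normal CDF.  Units are MPa for water potentials
and days for time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "HydrotimeParams",
    "base_potential_of_fraction",
    "germination_time",
    "germination_rate",
    "predict_cumulative_fraction",
    "predict_final_fraction",
    "model_r2",
]


@dataclass(frozen=True)
class HydrotimeParams:
    """Population-level parameter triple of the hydrotime model.

    Attributes
    ----------
    theta_H : float
        Hydrotime constant, MPa·day.  The amount of water potential in
        excess of a seed's threshold that must be accumulated over time
        before radicle protrusion.  Must be positive.
    psi_b50 : float
        Median base water potential of the population, MPa.  Typically
        negative; must be finite.
    sigma_psib : float
        Standard deviation of base water potentials across seeds, MPa.
        Must be positive; governs the spread of germination times and the
        sub-maximal final germination at low water potential.
    """

    theta_H: float
    psi_b50: float
    sigma_psib: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_H) and self.theta_H > 0):
            raise ValueError(f"theta_H must be positive and finite, got {self.theta_H}")
        if not (np.isfinite(self.sigma_psib) and self.sigma_psib > 0):
            raise ValueError(
                f"sigma_psib must be positive and finite, got {self.sigma_psib}"
            )
        if not np.isfinite(self.psi_b50):
            raise ValueError(f"psi_b50 must be finite, got {self.psi_b50}")


def _check_fraction(g: float) -> float:
    g = float(g)
    if not 0.0 < g < 1.0:
        raise ValueError(f"population fraction g must lie in (0, 1), got {g}")
    return g


def base_potential_of_fraction(params: HydrotimeParams, g: float) -> float:
    """Base water potential of population fraction ``g``, in MPa.

    ``psi_b(g) = psi_b50 + sigma_psib * Phi^-1(g)``: the threshold below
    which fraction ``g`` of the population cannot germinate.

    Raises
    ------
    ValueError
        If ``g`` is outside the open interval (0, 1).
    """
    g = _check_fraction(g)
    return params.psi_b50 + params.sigma_psib * float(ndtri(g))


def germination_time(params: HydrotimeParams, psi: float, g: float) -> float:
    """Time (days) for fraction ``g`` to germinate at water potential ``psi``.

    ``t_g = theta_H / (psi - psi_b(g))``.  When ``psi`` is at or below the
    fraction's threshold the seed never germinates and ``inf`` is returned
    (a legitimate model outcome, not an error: the simulator relies on it).
    """
    psi_b_g = base_potential_of_fraction(params, g)
    driving = psi - psi_b_g
    if driving <= 0.0:
        return float("inf")
    return params.theta_H / driving


def germination_rate(params: HydrotimeParams, psi: float, g: float) -> float:
    """Germination rate ``GR(g) = 1/t_g`` in 1/day; zero at or below threshold.

    ``GR(g) = max(0, (psi - psi_b(g)) / theta_H)`` — linear in ``psi`` above
    the threshold, which is the relation the rate-regression stage exploits.
    """
    psi_b_g = base_potential_of_fraction(params, g)
    return max(0.0, (psi - psi_b_g) / params.theta_H)


def predict_cumulative_fraction(params: HydrotimeParams, psi: float, t):
    """Model cumulative germination fraction at time ``t`` (days).

    ``F(t) = Phi((psi - theta_H/t - psi_b50) / sigma_psib)`` for ``t > 0``;
    0 for ``t <= 0`` by convention.  Nondecreasing in both ``t`` and ``psi``
    and converges to :func:`predict_final_fraction` as ``t → ∞``.

    ``t`` may be a scalar or an array; the return matches its shape.
    """
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        arg = (psi - params.theta_H / t_arr - params.psi_b50) / params.sigma_psib
    frac = np.where(t_arr > 0.0, ndtr(arg), 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(frac)
    return frac


def predict_final_fraction(params: HydrotimeParams, psi: float) -> float:
    """Maximal germinable fraction at ``psi``: ``Phi((psi - psi_b50)/sigma_psib)``.

    The fraction of seeds whose base water potential lies below ``psi``;
    the ``t → ∞`` limit of :func:`predict_cumulative_fraction`.
    """
    return float(ndtr((psi - params.psi_b50) / params.sigma_psib))


def model_r2(observed, predicted) -> float:
    """Coefficient of determination of predictions against observations.

    ``R² = 1 − Σ(y_obs − y_pred)² / Σ(y_obs − ȳ_obs)²``.  Equals 1 iff the
    predictions are exact and may be negative for predictions worse than the
    observed mean.

    Raises
    ------
    ValueError
        If the sequences differ in length, have fewer than two elements, or
        the observations are all identical (zero total sum of squares).
    """
    y_obs = np.asarray(observed, dtype=float)
    y_pred = np.asarray(predicted, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError(
            f"observed and predicted must have equal length, got {y_obs.shape} vs {y_pred.shape}"
        )
    if y_obs.size < 2:
        raise ValueError("need at least two observations to compute R²")
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² is undefined: observed values are all identical")
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot
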