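"""Simulation of interval-censored germination experiments.

Generates dish-level cumulative germination time courses under the hydrotime
model, with the experimental structure of a standard multi-water-potential
germination assay: several PEG-controlled water potentials, replicate Petri
dishes per population × potential, a fixed number of viable seeds per dish,
and scoring of radicle protrusion every few days for a fixed duration.

Default design: four water potentials (0, −0.8, −1, −1.6 MPa), four
replicate dishes, 40 viable seeds per dish, scoring every 2 days for
80 days at constant (optimal) temperature.

Censoring convention: a germination event occurring in the half-open
interval (day_{k-1}, day_k] is recorded at day_k, so the count at a scoring
day is exactly the number of seeds whose continuous germination time is
≤ that day.  The fitting stages predict the model CDF at the same scoring
days, so simulator and fitter share one convention and no half-interval
bias is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .core_model import HydrotimeParams

__all__ = [
    "DEFAULT_PSI_LEVELS",
    "ExperimentDesign",
    "TimeCourse",
    "simulate_experiment",
    "write_scoresheet",
    "SCORESHEET_COLUMNS",
]

#: Water potentials (MPa) of the reference experimental design.
DEFAULT_PSI_LEVELS: tuple[float, ...] = (0.0, -0.8, -1.0, -1.6)

#: Required columns of the long-format germination score sheet.
SCORESHEET_COLUMNS = (
    "population",
    "replicate",
    "psi_MPa",
    "day",
    "cum_germinated",
    "n_viable",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a germination experiment.

    Parameters
    ----------
    rng_seed : int
        Seed of the pseudo-random stream; per-dish substreams are derived
        from it deterministically, so replicate dishes are reproducible
        individually.
    psi_levels : sequence of float
        Water potentials of the incubation media, MPa (all ≤ 0).
    n_replicates : int
        Petri dishes per population × water potential.
    seeds_per_dish : int
        Target number of viable seeds per dish.
    viability : float
        Probability that a sown seed is viable, in (0, 1].  When < 1 the
        number of sown seeds is inflated to ``seeds_per_dish / viability``
        and the realised viable count is binomial; dead seeds are carried
        in ``n_dead`` but never enter germination fractions.
    scoring_interval : float
        Days between scoring observations.
    duration : float
        Total length of the experiment, days.
    """

    rng_seed: int
    psi_levels: tuple[float, ...] = DEFAULT_PSI_LEVELS
    n_replicates: int = 4
    seeds_per_dish: int = 40
    viability: float = 1.0
    scoring_interval: float = 2.0
    duration: float = 80.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi_levels", tuple(float(p) for p in self.psi_levels))
        if len(self.psi_levels) == 0:
            raise ValueError("psi_levels must be nonempty")
        if any(p > 0 for p in self.psi_levels):
            raise ValueError("experimental water potentials must be ≤ 0 MPa")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if self.seeds_per_dish < 1:
            raise ValueError("seeds_per_dish must be ≥ 1")
        if not 0.0 < self.viability <= 1.0:
            raise ValueError("viability must lie in (0, 1]")
        if not 0.0 < self.scoring_interval <= self.duration:
            raise ValueError("need 0 < scoring_interval ≤ duration")

    @property
    def scoring_days(self) -> np.ndarray:
        """The scoring grid: interval, 2·interval, … up to the duration."""
        n = int(np.floor(self.duration / self.scoring_interval + 1e-9))
        return self.scoring_interval * np.arange(1, n + 1)

    def with_seed(self, rng_seed: int) -> "ExperimentDesign":
        """Copy of this design with a different random seed."""
        return replace(self, rng_seed=int(rng_seed))


@dataclass(eq=False)
class TimeCourse:
    """One dish's interval-censored cumulative germination record.

    ``cum_germinated`` is stored as float so that noise-free, model-derived
    "expected count" curves can be represented exactly; simulated records
    hold integers.
    """

    population: str
    replicate: int
    psi: float
    days: np.ndarray
    cum_germinated: np.ndarray
    n_viable: int
    n_dead: int = 0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cum_germinated = np.asarray(self.cum_germinated, dtype=float)
        if self.days.shape != self.cum_germinated.shape:
            raise ValueError("days and cum_germinated must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("scoring days must be strictly increasing")
        if np.any(np.diff(self.cum_germinated) < 0):
            raise ValueError("cumulative germination counts must be nondecreasing")
        if np.any(self.cum_germinated < 0) or np.any(self.cum_germinated > self.n_viable):
            raise ValueError("cumulative counts must lie in [0, n_viable]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeCourse):
            return NotImplemented
        return (
            self.population == other.population
            and self.replicate == other.replicate
            and self.psi == other.psi
            and self.n_viable == other.n_viable
            and self.n_dead == other.n_dead
            and np.array_equal(self.days, other.days)
            and np.array_equal(self.cum_germinated, other.cum_germinated)
        )

    @property
    def fractions(self) -> np.ndarray:
        """Cumulative germinated fraction of viable seeds at each scoring day."""
        return self.cum_germinated / self.n_viable


def simulate_experiment(
    params: HydrotimeParams,
    design: ExperimentDesign,
    population_label: str = "pop",
) -> list[TimeCourse]:
    """Simulate one population's germination experiment under the hydrotime model.

    For every dish, each viable seed draws its base water potential
    ``psi_b ~ Normal(psi_b50, sigma_psib)`` and germinates at continuous
    time ``theta_H / (psi - psi_b)`` if ``psi > psi_b``, otherwise never.
    Counts are recorded at each scoring day (right-endpoint censoring).

    Fully reproducible: the same ``design.rng_seed`` yields bit-identical
    output.  Returns one :class:`TimeCourse` per dish, in (psi level,
    replicate) order, replicates numbered from 1.
    """
    root = np.random.SeedSequence(design.rng_seed)
    streams = root.spawn(len(design.psi_levels) * design.n_replicates)
    days = design.scoring_days
    out: list[TimeCourse] = []
    k = 0
    for psi in design.psi_levels:
        for rep in range(1, design.n_replicates + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            if design.viability < 1.0:
                n_sown = int(round(design.seeds_per_dish / design.viability))
                n_viable = int(rng.binomial(n_sown, design.viability))
                n_dead = n_sown - n_viable
            else:
                n_viable, n_dead = design.seeds_per_dish, 0
            psi_b = rng.normal(params.psi_b50, params.sigma_psib, size=n_viable)
            with np.errstate(divide="ignore"):
                t_germ = np.where(
                    psi > psi_b, params.theta_H / (psi - psi_b), np.inf
                )
            cum = (t_germ[None, :] <= days[:, None]).sum(axis=1)
            out.append(
                TimeCourse(
                    population=population_label,
                    replicate=rep,
                    psi=float(psi),
                    days=days.copy(),
                    cum_germinated=cum,
                    n_viable=n_viable,
                    n_dead=n_dead,
                )
            )
    return out


def timecourses_to_frame(timecourses: Iterable[TimeCourse]) -> pd.DataFrame:
    """Long-format score-sheet DataFrame (one row per dish × scoring day)."""
    rows = []
    for tc in timecourses:
        for day, cum in zip(tc.days, tc.cum_germinated):
            rows.append(
                {
                    "population": tc.population,
                    "replicate": tc.replicate,
                    "psi_MPa": tc.psi,
                    "day": day,
                    "cum_germinated": cum,
                    "n_viable": tc.n_viable,
                    "n_dead": tc.n_dead,
                }
            )
    if not rows:
        raise ValueError("no time courses to write")
    df = pd.DataFrame(rows)
    # keep counts integral in the CSV when they are integral in memory
    for col in ("cum_germinated",):
        if np.all(df[col] == np.round(df[col])):
            df[col] = df[col].astype(int)
    return df


def write_scoresheet(timecourses: Iterable[TimeCourse], destination) -> None:
    """Write time courses as the long-format germination score-sheet CSV.

    Columns: population, replicate, psi_MPa, day, cum_germinated, n_viable,
    n_dead.  Round-trips losslessly through the score-sheet reader.
    """
    df = timecourses_to_frame(timecourses)
    df.to_csv(destination, index=False)
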