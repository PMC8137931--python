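"""Readers, writers and packaged reference tables.

The long-format germination score sheet (one row per dish × scoring day)
is the package's interchange format: columns ``population, replicate,
psi_MPa, day, cum_germinated, n_viable`` plus an optional ``n_dead`` count
that is carried but ignored by fitting.  Water potential is a signed MPa
value (0, −0.8, …), decimals use a dot, encoding is UTF-8, header row
mandatory.

Two reference tables are packaged: per-population site characteristics
(location, altitude, site mean precipitation, thousand-seed weight, soil
and floristic class) and the published per-population hydrotime parameter
estimates for nine Patagonian *Festuca pallescens* populations, transcribed
verbatim (the ``*_disp`` columns hold the printed ± dispersions without
committing to SD vs SE, which the source table does not state).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .core_model import HydrotimeParams
from .hydrotime_fit import PopulationSummary, ReplicateFit
from .synthetic_data import SCORESHEET_COLUMNS, TimeCourse

__all__ = [
    "ScoresheetError",
    "read_scoresheet",
    "load_fixture",
    "fixture_params",
    "write_fitted_parameters",
    "read_fitted_parameters",
]

#: Column order of the fitted-parameters CSV.
FITTED_COLUMNS = (
    "population",
    "replicate",
    "theta_H_MPa_d",
    "psi_b50_MPa",
    "sigma_psib_MPa",
    "r2",
)


class ScoresheetError(ValueError):
    """A score-sheet file violated the dialect; message lists row numbers."""


def read_scoresheet(path) -> list[TimeCourse]:
    """Read and validate a germination score-sheet CSV.

    Returns one :class:`TimeCourse` per (population, replicate, psi_MPa)
    group, sorted.  Violations — missing columns, duplicate scoring rows,
    decreasing cumulative counts, counts above ``n_viable``, inconsistent
    ``n_viable`` within a dish — are reported with 1-based file row
    numbers (header = row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in SCORESHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ScoresheetError(f"missing required columns: {missing}")
    if "n_dead" not in df.columns:
        df["n_dead"] = 0
    df["_row"] = df.index + 2  # 1-based file rows, after the header

    problems: list[str] = []
    out: list[TimeCourse] = []
    for (pop, rep, psi), grp in df.groupby(
        ["population", "replicate", "psi_MPa"], sort=True
    ):
        grp = grp.sort_values("day")
        dup = grp["day"].duplicated()
        if dup.any():
            rows = grp.loc[dup, "_row"].tolist()
            problems.append(
                f"duplicate (population, replicate, psi, day) at rows {rows}"
            )
            continue
        days = grp["day"].to_numpy(float)
        cum = grp["cum_germinated"].to_numpy(float)
        n_viable = grp["n_viable"].to_numpy()
        if np.unique(n_viable).size > 1:
            problems.append(
                f"inconsistent n_viable for {pop} rep {rep} at {psi} MPa "
                f"(rows {grp['_row'].tolist()})"
            )
            continue
        bad = np.where(np.diff(cum) < 0)[0]
        if bad.size:
            rows = grp["_row"].to_numpy()[bad + 1].tolist()
            problems.append(f"cumulative count decreases at rows {rows}")
            continue
        over = grp["_row"][cum > n_viable[0]].tolist()
        if over:
            problems.append(f"cum_germinated exceeds n_viable at rows {over}")
            continue
        out.append(
            TimeCourse(
                population=str(pop),
                replicate=int(rep),
                psi=float(psi),
                days=days,
                cum_germinated=cum,
                n_viable=int(n_viable[0]),
                n_dead=int(grp["n_dead"].iloc[0]),
            )
        )
    if problems:
        raise ScoresheetError("; ".join(problems))
    return out


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name, indexed by population.

    ``"table1"`` — site characteristics (coordinates in signed decimal
    degrees, altitude m, site mean precipitation mm, thousand-seed weight
    g, soil/floristic labels).  ``"table2"`` — published hydrotime
    parameter estimates (ψb50, θ_H, σψb with printed ± dispersions and
    multiple-comparison letters, plus mean fit R²).  Exactly nine
    populations each: PHA, PHB, SRA, SRB, PA, PB, JA, JB, SA.
    """
    if name not in {"table1", "table2"}:
        raise ValueError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")
    with resources.files("hydrotime.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh).set_index("population")


def fixture_params(population: str) -> HydrotimeParams:
    """Published hydrotime parameter triple of one reference population."""
    row = load_fixture("table2").loc[population]
    return HydrotimeParams(
        theta_H=float(row["theta_H_MPa_d"]),
        psi_b50=float(row["psi_b50_MPa"]),
        sigma_psib=float(row["sigma_psib_MPa"]),
    )


def write_fitted_parameters(
    fits: Iterable[ReplicateFit],
    summaries: Iterable[PopulationSummary],
    destination,
) -> pd.DataFrame:
    """Write the fitted-parameters CSV: replicate rows, then summary rows.

    Summary rows carry ``replicate = "mean"`` and hold replicate means.
    Returns the DataFrame that was written.
    """
    rows = [
        {
            "population": f.population,
            "replicate": f.replicate,
            "theta_H_MPa_d": f.params.theta_H,
            "psi_b50_MPa": f.params.psi_b50,
            "sigma_psib_MPa": f.params.sigma_psib,
            "r2": f.r2,
        }
        for f in fits
    ] + [
        {
            "population": s.population,
            "replicate": "mean",
            "theta_H_MPa_d": s.theta_H_mean,
            "psi_b50_MPa": s.psi_b50_mean,
            "sigma_psib_MPa": s.sigma_psib_mean,
            "r2": s.r2_mean,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=list(FITTED_COLUMNS))
    df.to_csv(destination, index=False)
    return df


def read_fitted_parameters(path, replicates_only: bool = True) -> pd.DataFrame:
    """Read a fitted-parameters CSV; by default drop the summary rows."""
    df = pd.read_csv(path)
    missing = [c for c in FITTED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fitted-parameters file missing columns: {missing}")
    if replicates_only:
        df = df[df["replicate"].astype(str) != "mean"].copy()
        df["replicate"] = df["replicate"].astype(int)
    return df
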