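"""Compartment N-pool accounting.

The tracer mass balance needs, for every sampled compartment and year, the
size of its nitrogen pool m_pool (g N m⁻²).  Soil horizons and the moss layer
are treated as static pools supplied by the user; dwarf-shrub biomass pools
grow with age-dependent increments.  This module also computes the amount of
tracer applied (excess ¹⁵N per m² from a double-labelled ammonium-nitrate
dose) and leaching N fluxes from lysimeter records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "PLANT_COMPARTMENTS",
    "NON_ANNUAL_COMPARTMENTS",
    "GrowthModel",
    "TracerApplication",
    "LeachateRecord",
    "build_pool_series",
    "applied_excess_15n",
    "leaching_n_flux",
]

#: Closed vocabulary of ecosystem compartments.
COMPARTMENTS: tuple[str, ...] = (
    "current_year_shoots",
    "shoots_1_2yr",
    "calluna_old",
    "calluna_roots",
    "litter_current",
    "moss",
    "O_horizon",
    "A_horizon",
    "B_horizon",
    "leachate",
)

#: Vascular-plant compartments (aggregated as "above-ground biomass" + roots).
PLANT_COMPARTMENTS: tuple[str, ...] = (
    "current_year_shoots",
    "shoots_1_2yr",
    "calluna_old",
    "calluna_roots",
)

#: Compartments sampled only in the last two study years.
NON_ANNUAL_COMPARTMENTS: tuple[str, ...] = ("calluna_old", "calluna_roots")

# Atomic masses (g mol⁻¹) for the tracer-salt stoichiometry.
_M_15N = 15.0001
_M_14N = 14.0031
_M_H = 1.008
_M_O = 15.999


def validate_compartment(name: str) -> str:
    if name not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {name!r}; expected one of {COMPARTMENTS}")
    return name


@dataclass
class GrowthModel:
    """Age-dependent growth of a plant compartment's N pool.

    base_biomass : g dry mass m⁻² at the start year.
    annual_increment : fractional biomass growth per year; either a scalar or
        a mapping year -> fraction.
    n_content : N mass fraction of dry matter; scalar or mapping year -> value.
    """

    base_biomass: float
    annual_increment: float | Mapping[int, float] = 0.0
    n_content: float | Mapping[int, float] = 0.01

    def _increment(self, year: int) -> float:
        if isinstance(self.annual_increment, Mapping):
            try:
                return float(self.annual_increment[year])
            except KeyError:
                raise ValueError(f"growth increment undefined for year {year}") from None
        return float(self.annual_increment)

    def _n_content(self, year: int) -> float:
        if isinstance(self.n_content, Mapping):
            try:
                return float(self.n_content[year])
            except KeyError:
                raise ValueError(f"n_content undefined for year {year}") from None
        return float(self.n_content)

    def pool_mass(self, start_year: int, year: int) -> float:
        """N pool (g N m⁻²) after compounding growth from start_year to year."""
        if self.base_biomass < 0:
            raise ValueError("base biomass must be non-negative")
        biomass = self.base_biomass
        for y in range(start_year + 1, year + 1):
            inc = self._increment(y)
            if inc < 0:
                raise ValueError(f"negative growth increment in year {y}")
            biomass *= 1.0 + inc
        return biomass * self._n_content(year)


@dataclass
class TracerApplication:
    """A single ¹⁵N pulse: dose of double-labelled NH₄NO₃ and its label strength."""

    dose_mg_salt: float = 100.0
    label_atom_percent: float = 98.0
    ref_atom_percent: float = 0.3663
    per_m2: bool = True  # dose interpreted per square metre

    @property
    def applied_excess_g_m2(self) -> float:
        return applied_excess_15n(
            self.dose_mg_salt, self.label_atom_percent, self.ref_atom_percent
        )


@dataclass
class LeachateRecord:
    """One lysimeter collection interval."""

    start_date: str
    end_date: str
    volume_l_m2: float
    n_inorg_mg_l: float
    don_mg_l: float
    delta15n: float | None = None

    def __post_init__(self):
        if self.volume_l_m2 < 0:
            raise ValueError("leachate volume must be non-negative")
        if self.n_inorg_mg_l < 0 or self.don_mg_l < 0:
            raise ValueError("leachate N concentrations must be non-negative")


def build_pool_series(
    start_pools: Mapping[str, float] | pd.DataFrame,
    years: Iterable[int],
    growth: Mapping[str, GrowthModel] | None = None,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the complete (compartment × year) grid of N pool masses.

    Static compartments (everything without a :class:`GrowthModel`) carry
    their starting pool through all years; plant compartments grow per model.
    ``overrides`` — a frame with columns compartment, year, m_pool_gN_m2 —
    wins over both.  Raises if any requested cell ends up without a value.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("no years requested")
    start_year = years[0]
    growth = dict(growth or {})

    if isinstance(start_pools, pd.DataFrame):
        start_map = {
            validate_compartment(str(r.compartment)): float(r.m_pool_gN_m2)
            for r in start_pools.itertuples()
        }
    else:
        start_map = {validate_compartment(k): float(v) for k, v in start_pools.items()}

    override_map: dict[tuple[str, int], float] = {}
    if overrides is not None:
        for r in overrides.itertuples():
            override_map[(validate_compartment(str(r.compartment)), int(r.year))] = float(
                r.m_pool_gN_m2
            )

    compartments = sorted(set(start_map) | set(growth) | {c for c, _ in override_map})
    rows, gaps = [], []
    for comp in compartments:
        for year in years:
            if (comp, year) in override_map:
                m = override_map[(comp, year)]
            elif comp in growth:
                m = growth[comp].pool_mass(start_year, year)
            elif comp in start_map:
                m = start_map[comp]
            else:
                gaps.append((comp, year))
                continue
            if m < 0:
                raise ValueError(f"negative pool mass for {comp} in {year}")
            rows.append({"compartment": comp, "year": year, "m_pool_gN_m2": m})
    if gaps:
        raise ValueError(f"no pool value or growth rule for cells: {gaps}")
    return pd.DataFrame(rows)


def applied_excess_15n(
    dose_mg_salt: float,
    label_atom_percent: float,
    ref_atom_percent: float = 0.3663,
) -> float:
    """Excess ¹⁵N applied (g m⁻²) from a dose of double-labelled ¹⁵NH₄¹⁵NO₃.

    The salt's molar mass is computed from the stated label atom fraction
    (both N positions labelled); the N mass in the dose is then multiplied by
    the atom-percent excess of the label over the reference abundance.
    """
    if dose_mg_salt < 0:
        raise ValueError("dose must be non-negative")
    if label_atom_percent <= ref_atom_percent:
        raise ValueError("label atom percent must exceed the reference abundance")
    a = label_atom_percent / 100.0
    m_n = a * _M_15N + (1.0 - a) * _M_14N
    molar_mass = 2.0 * m_n + 4.0 * _M_H + 3.0 * _M_O
    n_mass_g_m2 = dose_mg_salt / 1000.0 * (2.0 * m_n / molar_mass)
    return n_mass_g_m2 * (label_atom_percent - ref_atom_percent) / 100.0


def leaching_n_flux(records: Sequence[LeachateRecord]) -> tuple[pd.DataFrame, float]:
    """N flux (g N m⁻²) per collection interval and its total.

    flux = leachate volume × total N concentration (inorganic + DON); the
    annual total is the plain sum over intervals.
    """
    rows = []
    for rec in records:
        flux = rec.volume_l_m2 * (rec.n_inorg_mg_l + rec.don_mg_l) / 1000.0
        rows.append(
            {
                "start_date": rec.start_date,
                "end_date": rec.end_date,
                "n_flux_gN_m2": flux,
            }
        )
    frame = pd.DataFrame(rows, columns=["start_date", "end_date", "n_flux_gN_m2"])
    total = float(frame["n_flux_gN_m2"].sum()) if len(frame) else 0.0
    return frame, total
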