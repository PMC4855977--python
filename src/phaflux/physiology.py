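"""Chemostat growth stoichiometry: Pirt maintenance fit, yields, carbon balance.

At steady state in a chemostat the specific growth rate equals the dilution
rate D, and the specific substrate uptake follows the Pirt relation

    q_s = mu / Y_true + m_s

whose intercept is the maintenance coefficient m_s and whose reciprocal
slope is the true (maintenance-free) biomass yield.  The regression is run
on the mass-scale rates as printed; the intercept is converted to mmol
using the glycerol molar mass.  The ATP equivalent of substrate
maintenance follows m_ATP = (0.3939 + 2.33 P/O) * m_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import (
    BIOMASS_G_PER_CMOL,
    GLYCEROL_MOLAR_MASS,
    PHA_LUMP_CARBON,
    PHA_LUMP_MASS,
)

__all__ = [
    "ChemostatObservation",
    "PirtFit",
    "CarbonBalance",
    "PhysiologyError",
    "fit_pirt",
    "maintenance_atp",
    "observed_yield",
    "pha_yield",
    "carbon_recovery",
    "read_observations",
]


class PhysiologyError(ValueError):
    """Invalid physiological input or degenerate design."""


@dataclass
class ChemostatObservation:
    """One chemostat steady state.

    Rates are specific (per gCDW per hour); at least one of the mass- or
    molar-scale glycerol uptake rates must be present, and when both are
    they must agree through the glycerol molar mass within 1 %.
    """

    dilution_rate: float  # h^-1, equals mu at steady state
    biomass_conc: float | None = None  # g L^-1
    q_glycerol_mass: float | None = None  # g gCDW^-1 h^-1
    q_glycerol_molar: float | None = None  # mmol gCDW^-1 h^-1
    q_co2: float | None = None  # mmol gCDW^-1 h^-1
    q_co2_sd: float | None = None
    q_succinate: float | None = None  # mmol gCDW^-1 h^-1
    q_malate: float | None = None  # mmol gCDW^-1 h^-1
    pha_fraction: float = 0.0  # weight fraction of CDW, in [0, 1)
    y_xs_residual: float | None = None  # gCDW (excl. PHA) per g glycerol
    residual_glycerol: float | None = None  # g L^-1
    residual_ammonium: float | None = None  # mg L^-1
    limitation: str = "carbon"  # carbon | nitrogen
    condition: str = ""

    def __post_init__(self):
        if self.dilution_rate <= 0:
            raise PhysiologyError("dilution_rate must be positive")
        if not (0 <= self.pha_fraction < 1):
            raise PhysiologyError("pha_fraction must lie in [0, 1)")
        if self.limitation not in ("carbon", "nitrogen"):
            raise PhysiologyError(
                f"limitation must be 'carbon' or 'nitrogen', got {self.limitation!r}"
            )
        for name in ("q_glycerol_mass", "q_glycerol_molar", "q_co2",
                     "q_succinate", "q_malate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise PhysiologyError(f"{name} must be non-negative")
        if self.q_glycerol_mass is None and self.q_glycerol_molar is None:
            raise PhysiologyError("a glycerol uptake rate is required")
        if self.q_glycerol_mass is not None and self.q_glycerol_molar is not None:
            implied = self.q_glycerol_mass * 1000.0 / GLYCEROL_MOLAR_MASS
            if self.q_glycerol_molar > 0 and not math.isclose(
                implied, self.q_glycerol_molar, rel_tol=0.01
            ):
                raise PhysiologyError(
                    "mass- and molar-scale glycerol uptake disagree by more "
                    f"than 1 %: {implied:.4f} vs {self.q_glycerol_molar:.4f}"
                )

    @property
    def glycerol_uptake_molar(self) -> float | None:
        """Molar uptake, derived from the mass rate when needed (mmol gCDW^-1 h^-1)."""
        if self.q_glycerol_molar is not None:
            return self.q_glycerol_molar
        if self.q_glycerol_mass is not None:
            return self.q_glycerol_mass * 1000.0 / GLYCEROL_MOLAR_MASS
        return None

    @property
    def glycerol_uptake_mass(self) -> float | None:
        if self.q_glycerol_mass is not None:
            return self.q_glycerol_mass
        if self.q_glycerol_molar is not None:
            return self.q_glycerol_molar * GLYCEROL_MOLAR_MASS / 1000.0
        return None


@dataclass
class PirtFit:
    """Maintenance coefficient and true yield from the Pirt regression."""

    m_s: float  # mmol gCDW^-1 h^-1 (converted from the mass-scale intercept)
    m_s_mass: float  # g gCDW^-1 h^-1 (fitted intercept)
    y_true: float  # gCDW per g glycerol (reciprocal slope)
    slope: float  # (gCDW/g)^-1, mass scale
    r_squared: float
    se_m_s: float  # standard error of m_s, molar scale
    se_slope: float
    n: int
    negative_intercept: bool = False


def fit_pirt(observations: list[ChemostatObservation]) -> PirtFit:
    """Ordinary least squares of q_glycerol (mass scale) against mu (= D).

    Requires at least two observations at distinct dilution rates, each
    with a glycerol uptake rate.  A negative fitted intercept is returned
    with ``negative_intercept`` set, not clamped.
    """
    mu = []
    q = []
    for obs in observations:
        qm = obs.glycerol_uptake_mass
        if qm is None:
            raise PhysiologyError(
                f"observation at D={obs.dilution_rate} lacks a glycerol uptake rate"
            )
        mu.append(obs.dilution_rate)
        q.append(qm)
    if len(set(mu)) < 2:
        raise PhysiologyError(
            "Pirt regression needs at least 2 distinct dilution rates"
        )
    res = stats.linregress(mu, q)
    slope = float(res.slope)
    intercept = float(res.intercept)
    if slope <= 0:
        raise PhysiologyError(
            f"non-positive Pirt slope ({slope:.4g}); data inconsistent with "
            "a positive true yield"
        )
    n = len(mu)
    to_molar = 1000.0 / GLYCEROL_MOLAR_MASS
    se_intercept = float(res.intercept_stderr) if n >= 3 else float("nan")
    se_slope = float(res.stderr) if n >= 3 else float("nan")
    return PirtFit(
        m_s=intercept * to_molar,
        m_s_mass=intercept,
        y_true=1.0 / slope,
        slope=slope,
        r_squared=float(res.rvalue) ** 2,
        se_m_s=se_intercept * to_molar,
        se_slope=se_slope,
        n=n,
        negative_intercept=intercept < 0,
    )


def maintenance_atp(m_s: float, p_o_ratio: float) -> float:
    """ATP maintenance (mmol ATP gCDW^-1 h^-1) from substrate maintenance.

    m_ATP = (0.3939 + 2.33 * P/O) * m_s, with m_s in mmol gCDW^-1 h^-1.
    """
    if m_s < 0 or p_o_ratio < 0:
        raise PhysiologyError("m_s and P/O ratio must be non-negative")
    return (0.3939 + 2.33 * p_o_ratio) * m_s


def observed_yield(obs: ChemostatObservation) -> float:
    """Observed biomass yield D / q_glycerol (g biomass per g glycerol)."""
    qm = obs.glycerol_uptake_mass
    if qm is None or qm <= 0:
        raise PhysiologyError("observed yield needs a positive glycerol uptake")
    return obs.dilution_rate / qm


def pha_yield(y_xs_residual: float, pha_fraction: float) -> float:
    """PHA yield on substrate (g PHA per g glycerol).

    The printed biomass yield excludes PHA; the total-CDW yield is
    ``y_xs_residual / (1 - f)`` and the PHA share of it is ``f``.
    """
    if not (0 <= pha_fraction < 1):
        raise PhysiologyError("pha_fraction must lie in [0, 1)")
    total_yield = y_xs_residual / (1.0 - pha_fraction)
    return total_yield * pha_fraction


@dataclass
class CarbonBalance:
    """Itemized specific carbon balance of one steady state (C-mmol gCDW^-1 h^-1)."""

    c_in: float
    c_out: float
    recovery: float
    components: dict[str, float]


def carbon_recovery(
    obs: ChemostatObservation,
    biomass_c_content: float = BIOMASS_G_PER_CMOL,
    pha_lump_mass: float = PHA_LUMP_MASS,
    pha_lump_carbon: float = float(PHA_LUMP_CARBON),
) -> CarbonBalance:
    """Carbon recovery c_out / c_in on the specific-rate (per gCDW) basis.

    Carbon in is 3 C per glycerol taken up; carbon out sums CO2, biomass
    (27 g per C-mol), PHA (9.82 C per 167.7 g lump unit, from the weight
    fraction and D) and 4 C per succinate/malate secreted.
    """
    q = obs.glycerol_uptake_molar
    if q is None:
        raise PhysiologyError("carbon balance needs a glycerol uptake rate")
    if obs.q_co2 is None:
        raise PhysiologyError(
            "carbon balance needs a CO2 evolution rate (missing measurement)"
        )
    c_in = 3.0 * q
    f = obs.pha_fraction
    pha_rate_mass = obs.dilution_rate * f / (1.0 - f)  # g PHA gCDW^-1 h^-1
    components = {
        "glycerol": c_in,
        "co2": obs.q_co2,
        "biomass": obs.dilution_rate * 1000.0 / biomass_c_content,
        "pha": pha_rate_mass * 1000.0 / pha_lump_mass * pha_lump_carbon,
        "succinate": 4.0 * (obs.q_succinate or 0.0),
        "malate": 4.0 * (obs.q_malate or 0.0),
    }
    c_out = sum(v for k, v in components.items() if k != "glycerol")
    return CarbonBalance(
        c_in=c_in, c_out=c_out, recovery=c_out / c_in, components=components
    )


_NUMERIC_COLUMNS = {
    "dilution_rate": "dilution_rate",
    "biomass": "biomass_conc",
    "q_glycerol_mass": "q_glycerol_mass",
    "q_glycerol_mmol": "q_glycerol_molar",
    "q_glycerol_sd": None,  # informational; not stored
    "q_co2": "q_co2",
    "q_co2_sd": "q_co2_sd",
    "q_succinate": "q_succinate",
    "q_malate": "q_malate",
    "pha_fraction": "pha_fraction",
    "y_xs_residual": "y_xs_residual",
    "residual_glycerol": "residual_glycerol",
    "residual_ammonium": "residual_ammonium",
}


def read_observations(path: str | Path) -> list[ChemostatObservation]:
    """Read chemostat observations from a TSV table (``NA`` = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")
    if "dilution_rate" not in df.columns:
        raise PhysiologyError(f"{path}: missing required column 'dilution_rate'")
    obs = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _NUMERIC_COLUMNS.items():
            if attr is None or col not in df.columns:
                continue
            v = row[col]
            if pd.notna(v):
                kwargs[attr] = float(v)
        if "pha_fraction" not in kwargs:
            kwargs["pha_fraction"] = 0.0
        if "limitation" in df.columns and pd.notna(row["limitation"]):
            kwargs["limitation"] = str(row["limitation"])
        if "condition" in df.columns and pd.notna(row["condition"]):
            kwargs["condition"] = str(row["condition"])
        obs.append(ChemostatObservation(**kwargs))
    return obs
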