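"""Flux balance analysis by linear programming (HiGHS via scipy).

Growth maximization under measured exchange-rate constraints, with a
parsimonious secondary objective (minimum total absolute flux at the fixed
optimum) to select among alternate optima, flux variability analysis as a
degeneracy diagnostic, and node-partition statistics (e.g. the glyoxylate
shunt fraction at the isocitrate node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from ._constants import (
    DEFAULT_PO_RATIO,
    GLYCEROL_MOLAR_MASS,
    PHA_LUMP_MASS,
)
from .network import MetabolicNetwork
from .physiology import ChemostatObservation, maintenance_atp

__all__ = [
    "FbaScenario",
    "FluxDistribution",
    "FbaError",
    "solve_fba",
    "scenario_from_observation",
    "flux_variability",
    "node_split",
]

_INF = float("inf")


class FbaError(ValueError):
    """Invalid FBA scenario or request."""


@dataclass
class FbaScenario:
    """Bounds and objective for one FBA problem.

    ``constraints`` maps reaction ids to either a fixed value or a
    ``(lower, upper)`` interval, in mmol gCDW^-1 h^-1 (the biomass sink is
    in h^-1).  ``maintenance_atp``, if set, fixes the ATP-hydrolysis
    maintenance flux.
    """

    constraints: dict[str, float | tuple[float, float]] = field(default_factory=dict)
    objective: str = "EX_biomass"
    maintenance_atp: float | None = None
    maintenance_reaction: str = "atp_maint"
    name: str = ""

    def bounds_for(self, rid: str) -> tuple[float, float] | None:
        c = self.constraints.get(rid)
        if c is None:
            return None
        if isinstance(c, tuple):
            lo, hi = c
        else:
            lo = hi = float(c)
        if lo > hi:
            raise FbaError(f"empty interval for reaction {rid!r}: ({lo}, {hi})")
        return lo, hi

    def validate(self, network: MetabolicNetwork) -> None:
        ids = set(network.reaction_ids)
        for rid in list(self.constraints) + [self.objective]:
            if rid not in ids:
                raise FbaError(f"scenario references unknown reaction {rid!r}")
        for rid in self.constraints:
            self.bounds_for(rid)


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its provenance."""

    flux: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    scenario: FbaScenario | None = None
    infeasibility_hint: list[str] = field(default_factory=list)

    def __getitem__(self, rid: str) -> float:
        return self.flux[rid]

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


def _assemble(network: MetabolicNetwork, scenario: FbaScenario):
    S, _, col_index = network.stoichiometric_matrix()
    n = S.shape[1]
    bounds = []
    for r in network.reactions:
        lo = -_INF if r.reversible else 0.0
        hi = _INF
        sc = scenario.bounds_for(r.id)
        if sc is not None:
            lo, hi = sc
        bounds.append((lo, hi))
    if scenario.maintenance_atp is not None:
        j = col_index.get(scenario.maintenance_reaction)
        if j is None:
            raise FbaError(
                f"maintenance reaction {scenario.maintenance_reaction!r} "
                "not in network"
            )
        bounds[j] = (scenario.maintenance_atp, scenario.maintenance_atp)
    return S, col_index, bounds


def _lp(c, A_eq, b_eq, bounds):
    return linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")


def solve_fba(
    network: MetabolicNetwork,
    scenario: FbaScenario,
    parsimonious: bool = True,
) -> FluxDistribution:
    """Maximize the scenario objective subject to S v = 0 and bounds.

    When ``parsimonious``, a second LP minimizes total absolute flux with
    the objective pinned at its optimum, selecting a canonical vector from
    any degenerate optimal face (the optimum itself is unchanged).
    """
    scenario.validate(network)
    S, col_index, bounds = _assemble(network, scenario)
    n = S.shape[1]
    obj_j = col_index[scenario.objective]
    c = np.zeros(n)
    c[obj_j] = -1.0
    res = _lp(c, S, np.zeros(S.shape[0]), bounds)
    if res.status == 3:
        return FluxDistribution({}, None, "unbounded", scenario)
    if res.status != 0:
        hint = _infeasibility_hint(network, scenario)
        return FluxDistribution({}, None, "infeasible", scenario, hint)
    opt = float(res.x[obj_j])
    x = res.x

    if parsimonious:
        # min sum |v|: variables [v, p, m] with v = p - m, p, m >= 0,
        # original bounds kept on v, objective pinned at the optimum
        m_rows = S.shape[0]
        A2 = np.zeros((m_rows + n, 3 * n))
        A2[:m_rows, :n] = S
        A2[m_rows:, :n] = np.eye(n)
        A2[m_rows:, n:2 * n] = -np.eye(n)
        A2[m_rows:, 2 * n:] = np.eye(n)
        b2 = np.zeros(m_rows + n)
        bounds2 = list(bounds)
        bounds2[obj_j] = (opt, opt)
        bounds2 += [(0.0, _INF)] * (2 * n)
        c2 = np.concatenate([np.zeros(n), np.ones(2 * n)])
        res2 = _lp(c2, A2, b2, bounds2)
        if res2.status == 0:
            x = res2.x[:n]

    flux = {r.id: float(x[col_index[r.id]]) for r in network.reactions}
    return FluxDistribution(flux, opt, "optimal", scenario)


def _infeasibility_hint(
    network: MetabolicNetwork, scenario: FbaScenario
) -> list[str]:
    """Constrained reactions whose individual relaxation restores feasibility."""
    hint = []
    for rid in scenario.constraints:
        relaxed = FbaScenario(
            constraints={k: v for k, v in scenario.constraints.items() if k != rid},
            objective=scenario.objective,
            maintenance_atp=scenario.maintenance_atp,
            maintenance_reaction=scenario.maintenance_reaction,
        )
        S, col_index, bounds = _assemble(network, relaxed)
        c = np.zeros(S.shape[1])
        res = _lp(c, S, np.zeros(S.shape[0]), bounds)
        if res.status == 0:
            hint.append(rid)
    return hint


def scenario_from_observation(
    obs: ChemostatObservation,
    po_ratio: float = DEFAULT_PO_RATIO,
    maintenance: float | None = None,
    pha_lump_mass: float = PHA_LUMP_MASS,
    fix_growth: bool = False,
    name: str = "",
) -> FbaScenario:
    """Build the FBA constraint set for one chemostat steady state.

    Glycerol uptake and organic-acid secretion are fixed at the measured
    rates; CO2 is constrained to measured +/- its standard deviation (one
    printed SD, defaulting to 0.1 when unreported); the PHA sink is fixed
    at ``D * f/(1-f) * 1000/M_PHA`` from the PHA weight fraction; the
    biomass objective is left free unless ``fix_growth``.  ``maintenance``
    defaults to the Pirt-derived ATP maintenance at 0.039 mmol gCDW^-1
    h^-1 and the given P/O ratio.
    """
    q = obs.glycerol_uptake_molar
    if q is None:
        raise FbaError("observation lacks a glycerol uptake rate")
    constraints: dict[str, float | tuple[float, float]] = {"EX_glycerol": q}
    constraints["EX_succinate"] = obs.q_succinate or 0.0
    constraints["EX_malate"] = obs.q_malate or 0.0
    if obs.q_co2 is not None:
        sd = obs.q_co2_sd if obs.q_co2_sd is not None else 0.1
        constraints["EX_co2"] = (obs.q_co2 - sd, obs.q_co2 + sd)
    f = obs.pha_fraction or 0.0
    pha_flux = obs.dilution_rate * f / (1.0 - f) * 1000.0 / pha_lump_mass
    constraints["EX_pha"] = pha_flux
    if fix_growth:
        constraints["EX_biomass"] = obs.dilution_rate
    if maintenance is None:
        maintenance = maintenance_atp(0.039, po_ratio)
    return FbaScenario(
        constraints=constraints,
        objective="EX_biomass",
        maintenance_atp=maintenance,
        name=name,
    )


def flux_variability(
    network: MetabolicNetwork,
    scenario: FbaScenario,
    at_optimum: float = 1.0,
    tolerance: float = 1e-6,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] flux with the objective held at its optimum.

    A width above ``tolerance`` marks the reaction as degenerate at the
    optimal face.  Raises :class:`FbaError` if the scenario is infeasible.
    """
    sol = solve_fba(network, scenario, parsimonious=False)
    if not sol.is_optimal:
        raise FbaError(f"scenario is {sol.status}; no variability to report")
    S, col_index, bounds = _assemble(network, scenario)
    obj_j = col_index[scenario.objective]
    opt = sol.objective_value
    lo_obj = at_optimum * opt if opt >= 0 else opt / at_optimum
    bounds = list(bounds)
    blo, bhi = bounds[obj_j]
    bounds[obj_j] = (max(blo, lo_obj), bhi)
    out = {}
    n = S.shape[1]
    for r in network.reactions:
        j = col_index[r.id]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _lp(c, S, np.zeros(S.shape[0]), bounds)
        c[j] = -1.0
        hi = _lp(c, S, np.zeros(S.shape[0]), bounds)
        out[r.id] = (
            float(lo.x[j]) if lo.status == 0 else -_INF,
            float(hi.x[j]) if hi.status == 0 else _INF,
        )
    return out


def node_split(
    dist: FluxDistribution,
    network: MetabolicNetwork,
    species_token: str,
    branch_reactions: list[str],
) -> dict[str, float]:
    """Fraction of a metabolite's total consumption taken by each branch.

    Consumption of the species through a reaction is ``-S[s,r] * v_r``
    when positive (reversible reactions count by their actual direction).
    Fractions are relative to total consumption over all reactions and
    therefore sum to 1 over a complete branch list.
    """
    if not dist.is_optimal:
        raise FbaError("node split requires an optimal flux distribution")
    total = 0.0
    consumption = {}
    for r in network.reactions:
        coef = r.stoichiometry.get(species_token)
        if coef is None:
            continue
        used = -float(coef) * dist.flux[r.id]
        if used > 0:
            consumption[r.id] = used
            total += used
    if total <= 0:
        raise FbaError(f"no consumption of {species_token!r} in this solution")
    missing = [rid for rid in branch_reactions if rid not in consumption]
    fractions = {rid: consumption.get(rid, 0.0) / total for rid in branch_reactions}
    return fractions
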