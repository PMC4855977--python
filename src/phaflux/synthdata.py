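"""Synthetic chemostat and mode data with the statistical structure the
analysis assumes.

Generators are pure functions of their parameters and seed.  Defaults
emulate the study design: eight dilution rates below the 0.22 h^-1 washout
bound, additive Gaussian noise on the mass-scale uptake rate of the
magnitude of the printed measurement SDs, and exchange-rate observations
derived from a known optimal flux distribution to close the FBA loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._constants import PHA_LUMP_MASS, WASHOUT_DILUTION_RATE
from .efm import ModeMatrix
from .fba import FluxDistribution
from .physiology import ChemostatObservation

__all__ = [
    "SimulationSpec",
    "SynthDataError",
    "simulate_chemostat",
    "simulate_measured_rates",
    "planted_mode_matrix",
]

#: dilution-rate grid of the glycerol-limited chemostat series (h^-1)
DEFAULT_DILUTION_GRID = (0.044, 0.066, 0.088, 0.109, 0.120, 0.141, 0.190, 0.210)


class SynthDataError(ValueError):
    """Invalid simulation specification."""


@dataclass
class SimulationSpec:
    """Parameters of a simulated Pirt chemostat series.

    ``m_true`` is the maintenance coefficient on the mass scale
    (g glycerol gCDW^-1 h^-1), ``noise_sd`` the absolute Gaussian SD on
    the mass-scale uptake rate (the printed rate SDs correspond to about
    0.01 on this scale).
    """

    m_true: float = 0.0036  # ~0.039 mmol gCDW^-1 h^-1
    y_true: float = 0.505
    dilution_grid: tuple[float, ...] = DEFAULT_DILUTION_GRID
    noise_sd: float = 0.01
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.y_true <= 0:
            raise SynthDataError("y_true must be positive")
        if self.noise_sd < 0:
            raise SynthDataError("noise_sd must be non-negative")


def simulate_chemostat(spec: SimulationSpec) -> list[ChemostatObservation]:
    """Draw chemostat observations from the Pirt line plus Gaussian noise.

    q = mu / Y + m + N(0, sd) per replicate; negative draws (possible only
    at extreme noise) are resampled so rates stay physical.  Dilution
    rates at or above washout (0.22 h^-1) are rejected.
    """
    for d in spec.dilution_grid:
        if not (0 < d < WASHOUT_DILUTION_RATE):
            raise SynthDataError(
                f"dilution rate {d} outside (0, {WASHOUT_DILUTION_RATE}) "
                "(washout)"
            )
    rng = np.random.default_rng(spec.seed)
    obs = []
    for _ in range(spec.n_replicates):
        for d in spec.dilution_grid:
            q = d / spec.y_true + spec.m_true
            if spec.noise_sd > 0:
                draw = q + rng.normal(0.0, spec.noise_sd)
                while draw <= 0:
                    draw = q + rng.normal(0.0, spec.noise_sd)
                q = draw
            obs.append(
                ChemostatObservation(
                    dilution_rate=d, q_glycerol_mass=q, limitation="carbon"
                )
            )
    return obs


def simulate_measured_rates(
    dist: FluxDistribution,
    rel_sd: float,
    seed: int,
    limitation: str = "nitrogen",
) -> ChemostatObservation:
    """Turn an optimal flux distribution into a noisy rate observation.

    Multiplicative Gaussian noise of relative SD ``rel_sd`` is applied to
    the exchange fluxes only (glycerol, CO2, succinate, malate); the
    dilution rate (biomass flux) and PHA content are carried over exactly,
    so scenario reconstruction + FBA can be tested for recovery of the
    planted internal flux pattern.
    """
    if not dist.is_optimal:
        raise SynthDataError("simulate_measured_rates requires an optimal solution")
    rng = np.random.default_rng(seed)

    def noisy(x: float) -> float:
        if rel_sd == 0 or x == 0:
            return x
        draw = x * (1.0 + rng.normal(0.0, rel_sd))
        while draw < 0:
            draw = x * (1.0 + rng.normal(0.0, rel_sd))
        return draw

    d = dist.flux["EX_biomass"]
    v_pha = dist.flux.get("EX_pha", 0.0)
    # EX_pha [mmol/gCDW/h] = D * f/(1-f) * 1000 / M_lump  =>  f
    x = v_pha * PHA_LUMP_MASS / 1000.0 / d if d > 0 else 0.0
    f = x / (1.0 + x)
    return ChemostatObservation(
        dilution_rate=d,
        q_glycerol_molar=noisy(dist.flux["EX_glycerol"]),
        q_co2=noisy(dist.flux["EX_co2"]),
        q_co2_sd=rel_sd * dist.flux["EX_co2"] if rel_sd > 0 else None,
        q_succinate=noisy(dist.flux.get("EX_succinate", 0.0)),
        q_malate=noisy(dist.flux.get("EX_malate", 0.0)),
        pha_fraction=f,
        limitation=limitation,
    )


def planted_mode_matrix(
    n_modes: int,
    n_reactions: int,
    planted: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    objective: str = "objective",
) -> ModeMatrix:
    """Mode-matrix test bed with known flux-vs-objective slopes.

    The objective column is uniform on (0, 1); each planted reaction is
    ``slope * objective + N(0, noise_sd)``; the remaining filler reactions
    are independent noise.  Reaction ids are ``R1..Rn`` plus the objective
    column.
    """
    if n_modes < 3:
        raise SynthDataError("need at least 3 modes")
    rng = np.random.default_rng(seed)
    obj = rng.uniform(0.0, 1.0, size=n_modes)
    ids = [f"R{i + 1}" for i in range(n_reactions)] + [objective]
    unknown = set(planted) - set(ids[:-1])
    if unknown:
        raise SynthDataError(f"planted ids not in matrix: {sorted(unknown)}")
    cols = {}
    for rid in ids[:-1]:
        if rid in planted:
            col = planted[rid] * obj + rng.normal(0.0, noise_sd, size=n_modes)
        else:
            col = rng.normal(0.5, 0.25 + noise_sd, size=n_modes)
        cols[rid] = col
    cols[objective] = obj
    modes = [
        tuple(Fraction(float(cols[rid][i])) for rid in ids)
        for i in range(n_modes)
    ]
    return ModeMatrix(reaction_ids=ids, modes=modes, normalized_to="synthetic")
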