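"""phaflux: chemostat stoichiometry, FBA and elementary-mode target
prediction for PHA-producing *Pseudomonas putida* KT2440 on glycerol."""

from importlib import resources

from .network import (
    MetabolicNetwork,
    Reaction,
    Species,
    load_network,
    parse_reaction,
    validate_network,
)
from .physiology import (
    ChemostatObservation,
    PirtFit,
    carbon_recovery,
    fit_pirt,
    maintenance_atp,
    observed_yield,
    pha_yield,
    read_observations,
)
from .fba import (
    FbaScenario,
    FluxDistribution,
    flux_variability,
    node_split,
    scenario_from_observation,
    solve_fba,
)
from .efm import (
    ModeMatrix,
    YieldPoint,
    enumerate_efms,
    normalize_modes,
    select_producing_modes,
    yield_space,
)
from .fluxdesign import TargetPotential, rank_targets, target_potentials
from .synthdata import (
    SimulationSpec,
    planted_mode_matrix,
    simulate_chemostat,
    simulate_measured_rates,
)

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data file (model and rate tables)."""
    return resources.files("phaflux") / "data" / name


def load_reference_network() -> MetabolicNetwork:
    """The packaged 62-reaction central-carbon network of P. putida KT2440."""
    return load_network(data_path("kt2440_glycerol_model.txt").read_text(encoding="utf-8"),
                        name="kt2440-glycerol")
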