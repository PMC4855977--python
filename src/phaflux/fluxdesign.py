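"""EFM-correlation target prediction (flux design).

Across the selected elementary modes (normalized to glycerol uptake), each
reaction's flux is correlated with the flux of the product objective (the
PHA sink).  Reactions whose Pearson correlation exceeds the cutoff at the
chosen significance are classified as amplification (positive r) or
attenuation (negative r) targets; the OLS slope of reaction flux on
objective flux is the target potential coefficient used for priority
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .efm import ModeMatrix

__all__ = ["TargetPotential", "FluxDesignError", "target_potentials", "rank_targets"]


class FluxDesignError(ValueError):
    """Invalid flux-design request."""


@dataclass
class TargetPotential:
    """Correlation-based engineering potential of one reaction."""

    reaction_id: str
    r: float  # Pearson correlation with the objective flux (nan if undefined)
    p_value: float
    slope: float  # target potential coefficient (flux per unit objective flux)
    classification: str  # amplification | attenuation | none
    n_modes: int
    pathway: str = ""


def target_potentials(
    modes: ModeMatrix,
    objective: str = "EX_pha",
    cutoff: float = 0.7,
    alpha: float = 0.05,
) -> list[TargetPotential]:
    """Per-reaction Pearson r, significance and OLS slope against the objective.

    Requires at least 3 modes.  Reactions (or an objective) without flux
    variance across modes get an undefined correlation and classification
    ``none``.  Classification requires ``|r| >= cutoff`` and
    ``p < alpha``.
    """
    if objective not in modes.reaction_ids:
        raise FluxDesignError(f"objective reaction {objective!r} not in mode matrix")
    n = len(modes)
    if n < 3:
        raise FluxDesignError(f"need at least 3 modes, got {n}")
    V = modes.values
    obj = V[:, modes.reaction_ids.index(objective)]
    obj_var = np.var(obj)
    pathways = {}
    if modes.network is not None:
        pathways = {r.id: r.pathway for r in modes.network.reactions}
    out = []
    for j, rid in enumerate(modes.reaction_ids):
        y = V[:, j]
        if obj_var == 0 or np.var(y) == 0:
            out.append(
                TargetPotential(rid, float("nan"), float("nan"), float("nan"),
                                "none", n, pathways.get(rid, ""))
            )
            continue
        r, p = stats.pearsonr(obj, y)
        slope = float(np.cov(obj, y, ddof=1)[0, 1] / np.var(obj, ddof=1))
        if abs(r) >= cutoff and p < alpha:
            cls = "amplification" if r > 0 else "attenuation"
        else:
            cls = "none"
        out.append(
            TargetPotential(rid, float(r), float(p), slope, cls, n,
                            pathways.get(rid, ""))
        )
    return out


def rank_targets(potentials: list[TargetPotential]) -> list[TargetPotential]:
    """Classified targets ordered by descending |slope|, ties broken by id.

    Amplification targets come first, then attenuation; unclassified
    reactions are dropped.
    """
    classified = [t for t in potentials if t.classification != "none"]
    order = {"amplification": 0, "attenuation": 1}
    return sorted(
        classified,
        key=lambda t: (order[t.classification], -abs(t.slope), t.reaction_id),
    )
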