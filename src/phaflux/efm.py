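"""Elementary flux mode enumeration and yield-space construction.

Enumeration uses the null-space variant of the double description method:
reversible reactions are split into forward/backward columns so every
variable is sign-constrained, an exact rational kernel basis of the split
stoichiometric matrix is arranged to carry an identity block on its free
rows, and the remaining non-negativity constraints are imposed one at a
time, combining adjacent positive/negative ray pairs.  Adjacency is
decided by the combinatorial zero-set test over the constraints imposed so
far, with bit-set supports.  All arithmetic is integer-exact; floats
appear only at output.

After enumeration, spurious two-cycles (forward+backward of one split
reversible reaction) are removed and mirrored images of fully reversible
modes are de-duplicated to one canonical sign (first nonzero flux
positive).  Both counting conventions are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._constants import species_carbon
from .network import MetabolicNetwork

__all__ = [
    "ModeMatrix",
    "YieldPoint",
    "EfmError",
    "enumerate_efms",
    "normalize_modes",
    "select_producing_modes",
    "yield_space",
]


class EfmError(ValueError):
    """Invalid request to the elementary-mode machinery."""


@dataclass
class ModeMatrix:
    """A set of flux modes over a fixed reaction ordering.

    ``modes`` holds one exact rational flux vector per mode, aligned with
    ``reaction_ids`` (identical to the source network's ordering).
    """

    reaction_ids: list[str]
    modes: list[tuple[Fraction, ...]]
    network: MetabolicNetwork | None = None
    normalized_to: str | None = None
    #: modes dropped by :func:`normalize_modes` for zero reference flux
    n_excluded_zero_reference: int = 0
    #: enumeration bookkeeping: number of modes supported entirely on
    #: reversible reactions (their mirror images were de-duplicated)
    n_fully_reversible: int = 0

    def __len__(self) -> int:
        return len(self.modes)

    @property
    def values(self) -> np.ndarray:
        """Float matrix, one row per mode."""
        return np.array([[float(v) for v in m] for m in self.modes])

    @property
    def supports(self) -> list[frozenset[str]]:
        return [
            frozenset(r for r, v in zip(self.reaction_ids, m) if v != 0)
            for m in self.modes
        ]

    def products(self, mode_index: int) -> frozenset[str]:
        """Boundary species secreted by a mode (positive exchange sink flux)."""
        if self.network is None:
            raise EfmError("mode matrix has no attached network")
        out = set()
        for rid, v in zip(self.reaction_ids, self.modes[mode_index]):
            if v == 0:
                continue
            rxn = self.network.reaction(rid)
            if not rxn.is_exchange:
                continue
            for tok, c in rxn.stoichiometry.items():
                # sink consumes the species from the cell: c < 0 with v > 0
                if c * v < 0:
                    out.add(tok)
        return frozenset(out)

    @property
    def count_mirrored_once(self) -> int:
        """Mode count with mirrored reversible modes counted once."""
        return len(self.modes)

    @property
    def count_mirrored_twice(self) -> int:
        """Mode count with both orientations of fully reversible modes."""
        return len(self.modes) + self.n_fully_reversible

    def flux(self, mode_index: int, rid: str) -> Fraction:
        return self.modes[mode_index][self.reaction_ids.index(rid)]


def _exact_kernel(
    rows: list[list[Fraction]], n: int
) -> tuple[list[list[Fraction]], list[int]]:
    """Kernel basis of the matrix (list of rows, n columns), exact.

    Returns ``(basis, free_columns)``; basis vector k has 1 at
    ``free_columns[k]`` and 0 at every other free column (identity block).
    """
    A = [row[:] for row in rows]
    m = len(A)
    pivots: list[int] = []
    r = 0
    for c in range(n):
        piv = None
        for i in range(r, m):
            if A[i][c] != 0:
                piv = i
                break
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        inv = A[r][c]
        A[r] = [x / inv for x in A[r]]
        for i in range(m):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [x - f * y for x, y in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -A[i][fc]
        basis.append(v)
    return basis, free


def _to_int_vector(v: list[Fraction]) -> list[int]:
    lcm = 1
    for x in v:
        lcm = lcm * x.denominator // math.gcd(lcm, x.denominator)
    ints = [int(x * lcm) for x in v]
    g = 0
    for x in ints:
        g = math.gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return ints


def _reduce(v: list[int]) -> list[int]:
    g = 0
    for x in v:
        g = math.gcd(g, abs(x))
        if g == 1:
            return v
    return v if g <= 1 else [x // g for x in v]


def _double_description(
    S_rows: list[list[Fraction]], n: int
) -> list[list[int]]:
    """Extreme rays of {x >= 0 : S x = 0} by the null-space DD algorithm."""
    kernel, free = _exact_kernel(S_rows, n)
    d = len(kernel)
    if d == 0:
        return []
    rays = [_to_int_vector(v) for v in kernel]
    id_cols = set(free)
    remaining = [j for j in range(n) if j not in id_cols]

    # zero-set masks over imposed constraints (start: identity columns)
    imposed = sorted(id_cols)
    bit_of = {j: i for i, j in enumerate(imposed)}

    def zmask(ray: list[int]) -> int:
        m = 0
        for j in imposed:
            if ray[j] == 0:
                m |= 1 << bit_of[j]
        return m

    masks = [zmask(r) for r in rays]

    while remaining:
        # heuristic: impose the constraint with the fewest +/- combinations
        best_j, best_cost, best_split = None, None, None
        for j in remaining:
            pos = neg = 0
            for r in rays:
                if r[j] > 0:
                    pos += 1
                elif r[j] < 0:
                    neg += 1
            cost = pos * neg
            if best_cost is None or cost < best_cost:
                best_j, best_cost, best_split = j, cost, (pos, neg)
            if cost == 0:
                break
        j = best_j
        remaining.remove(j)

        pos_idx = [i for i, r in enumerate(rays) if r[j] > 0]
        neg_idx = [i for i, r in enumerate(rays) if r[j] < 0]
        zero_idx = [i for i, r in enumerate(rays) if r[j] == 0]

        new_rays: list[list[int]] = []
        new_masks: list[int] = []
        bit = len(imposed)
        for i in zero_idx:
            new_rays.append(rays[i])
            new_masks.append(masks[i] | (1 << bit))
        for i in pos_idx:
            new_rays.append(rays[i])
            new_masks.append(masks[i])

        # adjacency: combine (p, n) iff no third ray's zero-set contains
        # zmask(p) & zmask(n)
        all_masks = masks
        nrays = len(rays)
        for ip in pos_idx:
            mp = masks[ip]
            rp = rays[ip]
            vjp = rp[j]
            for im in neg_idx:
                z = mp & masks[im]
                adjacent = True
                for k in range(nrays):
                    if k == ip or k == im:
                        continue
                    if z & all_masks[k] == z:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                rm = rays[im]
                vjm = rm[j]
                # combo = vjp * rm - vjm * rp  (positive multiple of each)
                combo = [vjp * b - vjm * a for a, b in zip(rp, rm)]
                combo = _reduce(combo)
                new_rays.append(combo)
                new_masks.append((z | (1 << bit)))
        # recompute masks of combined rays exactly (zeros may appear/vanish)
        imposed.append(j)
        bit_of[j] = bit
        fixed_masks = []
        for r, mguess in zip(new_rays, new_masks):
            m = 0
            for jj in imposed:
                if r[jj] == 0:
                    m |= 1 << bit_of[jj]
            fixed_masks.append(m)
        rays, masks = new_rays, fixed_masks

    return rays


def enumerate_efms(
    network: MetabolicNetwork, max_reactions: int = 128
) -> ModeMatrix:
    """Enumerate all elementary flux modes of ``network``.

    Reversible reactions are split for enumeration; the returned modes are
    expressed on the original (unsplit) reaction ordering.  Spurious
    two-cycles are removed and fully reversible modes are returned once,
    with canonical sign (first nonzero flux positive);
    ``count_mirrored_twice`` gives the count under the other convention.

    Raises :class:`EfmError` for networks larger than ``max_reactions``
    (combinatorial blow-up guard).
    """
    if len(network.reactions) > max_reactions:
        raise EfmError(
            f"network has {len(network.reactions)} reactions, exceeding the "
            f"enumeration bound of {max_reactions}"
        )
    S, _, _ = network.stoichiometric_matrix_exact()
    rxns = network.reactions
    n = len(rxns)

    # prune reactions that can carry no steady-state flux (species with no
    # producer or no consumer force zero); repeat to a fixed point
    active = [True] * n
    changed = True
    while changed:
        changed = False
        for si in range(len(S)):
            has_pos = has_neg = False
            for j in range(n):
                if not active[j] or S[si][j] == 0:
                    continue
                if rxns[j].reversible:
                    has_pos = has_neg = True
                elif S[si][j] > 0:
                    has_pos = True
                else:
                    has_neg = True
            if has_pos != has_neg:
                for j in range(n):
                    if active[j] and S[si][j] != 0:
                        active[j] = False
                        changed = True

    act_cols = [j for j in range(n) if active[j]]
    # split reversible reactions: columns (j, +1) and (j, -1)
    split_cols: list[tuple[int, int]] = []
    for j in act_cols:
        split_cols.append((j, +1))
        if rxns[j].reversible:
            split_cols.append((j, -1))
    S_split = [
        [S[i][j] * s for (j, s) in split_cols] for i in range(len(S))
    ]
    # drop all-zero rows
    S_split = [row for row in S_split if any(x != 0 for x in row)]

    rays = _double_description(S_split, len(split_cols))

    # recombine to network coordinates, drop two-cycles, canonicalize
    modes: list[tuple[Fraction, ...]] = []
    seen: set[tuple] = set()
    n_fully_rev = 0
    irrev_mask = [not rxns[j].reversible for j in range(n)]
    for ray in rays:
        v = [0] * n
        for (col_j, sgn), x in zip(split_cols, ray):
            v[col_j] += sgn * x
        support = [j for j in range(n) if v[j] != 0]
        if not support:
            continue  # spurious two-cycle
        vec = _reduce([v[j] for j in range(n)])
        fully_rev = not any(irrev_mask[j] for j in support)
        if fully_rev:
            # canonical sign: first nonzero positive
            first = next(x for x in vec if x != 0)
            if first < 0:
                vec = [-x for x in vec]
        key = tuple(vec)
        if key in seen:
            continue
        if fully_rev:
            mirror = tuple(-x for x in vec)
            if mirror in seen:
                continue
            n_fully_rev += 1
        seen.add(key)
        modes.append(tuple(Fraction(x) for x in vec))

    # deterministic ordering: by support bitset then lexicographic values
    order = sorted(
        range(len(modes)),
        key=lambda i: (
            tuple(1 if x != 0 else 0 for x in modes[i]),
            tuple(modes[i]),
        ),
    )
    modes = [modes[i] for i in order]
    return ModeMatrix(
        reaction_ids=[r.id for r in rxns],
        modes=modes,
        network=network,
        n_fully_reversible=n_fully_rev,
    )


def normalize_modes(modes: ModeMatrix, reference: str) -> ModeMatrix:
    """Scale every mode so the reference reaction carries unit flux.

    Modes with zero reference flux (internal/futile cycles) are excluded
    and counted in ``n_excluded_zero_reference``.
    """
    if reference not in modes.reaction_ids:
        raise EfmError(f"reference reaction {reference!r} not in mode matrix")
    ref = modes.reaction_ids.index(reference)
    kept: list[tuple[Fraction, ...]] = []
    excluded = 0
    for m in modes.modes:
        if m[ref] == 0:
            excluded += 1
            continue
        scale = m[ref]
        kept.append(tuple(v / scale for v in m))
    return ModeMatrix(
        reaction_ids=list(modes.reaction_ids),
        modes=kept,
        network=modes.network,
        normalized_to=reference,
        n_excluded_zero_reference=excluded,
        n_fully_reversible=modes.n_fully_reversible,
    )


def select_producing_modes(
    modes: ModeMatrix, required_products: set[str]
) -> ModeMatrix:
    """Keep modes secreting every named boundary species (positive sink flux)."""
    if modes.network is None:
        raise EfmError("mode matrix has no attached network")
    known = {tok for s in modes.network.species for tok in (s.token,)}
    required = set(required_products)
    unknown = {p for p in required if p not in known}
    if unknown:
        raise EfmError(f"unknown product species: {sorted(unknown)}")
    kept_idx = [
        i for i in range(len(modes))
        if required <= modes.products(i)
    ]
    return ModeMatrix(
        reaction_ids=list(modes.reaction_ids),
        modes=[modes.modes[i] for i in kept_idx],
        network=modes.network,
        normalized_to=modes.normalized_to,
        n_fully_reversible=modes.n_fully_reversible,
    )


@dataclass
class YieldPoint:
    """C-mol yields of one mode per C-mol glycerol taken up."""

    biomass_yield: float
    pha_yield: float
    mode_index: int


def yield_space(
    modes: ModeMatrix,
    biomass_reaction: str = "EX_biomass",
    pha_reaction: str = "EX_pha",
    biomass_cmmol_per_unit: float = 1000.0 / 27.0,
    pha_carbon: float = 9.82,
    glycerol_carbon: float = 3.0,
) -> list[YieldPoint]:
    """Biomass vs PHA carbon yields of glycerol-normalized modes.

    Requires the mode matrix to be normalized to the glycerol uptake
    reaction (1 mmol glycerol = 3 C-mmol in); the biomass sink is counted
    at the 27 g per C-mol convention, the PHA sink at 9.82 C per lump unit.
    """
    if modes.normalized_to is None:
        raise EfmError("yield_space requires glycerol-normalized modes")
    bi = modes.reaction_ids.index(biomass_reaction)
    pi = modes.reaction_ids.index(pha_reaction)
    points = []
    for i, m in enumerate(modes.modes):
        points.append(
            YieldPoint(
                biomass_yield=float(m[bi]) * biomass_cmmol_per_unit / glycerol_carbon,
                pha_yield=float(m[pi]) * pha_carbon / glycerol_carbon,
                mode_index=i,
            )
        )
    return points


def boundary_carbon_balance(modes: ModeMatrix, mode_index: int) -> tuple[Fraction, Fraction]:
    """Exact boundary carbon (in, out) of one mode, lumps at defined contents."""
    if modes.network is None:
        raise EfmError("mode matrix has no attached network")
    c_in = Fraction(0)
    c_out = Fraction(0)
    for rid, v in zip(modes.reaction_ids, modes.modes[mode_index]):
        if v == 0:
            continue
        rxn = modes.network.reaction(rid)
        if not rxn.is_exchange:
            continue
        for tok, c in rxn.stoichiometry.items():
            carbon = species_carbon(tok[:-3])
            flow = c * v * carbon
            if flow > 0:
                c_in += flow  # source injects species into the system
            else:
                c_out -= flow
    return c_in, c_out
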