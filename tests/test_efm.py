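import math
from fractions import Fraction

import numpy as np
import pytest

import phaflux as pf
from phaflux.efm import EfmError, boundary_carbon_balance
from phaflux.network import NetworkError

from _oracles import brute_force_efms


def _canonical_set(mode_matrix):
    """Modes as canonical integer tuples for set comparison."""
    out = set()
    for m in mode_matrix.modes:
        lcm = 1
        for v in m:
            lcm = lcm * v.denominator // math.gcd(lcm, v.denominator)
        ints = [int(v * lcm) for v in m]
        g = 0
        for v in ints:
            g = math.gcd(g, abs(v))
        out.add(tuple(v // g for v in ints))
    return out


def _random_toy(seed):
    """Small random network (7 reactions, 4 internal species) as model text."""
    rng = np.random.default_rng(seed)
    species = ["A", "B", "C", "D"]
    lines = ["in: -> A[c]", "out: D[c] ->"]
    for k in range(5):
        subs = rng.choice(species, size=rng.integers(1, 3), replace=False)
        prods = [s for s in rng.choice(species, size=rng.integers(1, 3), replace=False)
                 if s not in subs]
        if not prods:
            prods = [s for s in species if s not in subs][:1]
        arrow = "<->" if rng.random() < 0.4 else "->"
        left = " + ".join(f"{rng.integers(1, 3)} {s}[c]" for s in subs)
        right = " + ".join(f"{rng.integers(1, 3)} {s}[c]" for s in prods)
        lines.append(f"r{k}: {left} {arrow} {right}")
    return "\n".join(lines) + "\n"


class TestEnumerateToys:
    def test_linear_chain_single_mode(self, chain_network):
        mm = pf.enumerate_efms(chain_network)
        assert len(mm) == 1
        assert mm.modes[0] == (1, 1, 1)

    def test_diamond_two_modes(self, diamond_network):
        mm = pf.enumerate_efms(diamond_network)
        assert len(mm) == 2
        assert _canonical_set(mm) == {(1, 1, 0, 1), (1, 0, 1, 1)}

    def test_reversible_pair_no_spurious_two_cycle(self):
        net = pf.load_network("in: -> A[c]\nr: A[c] <-> B[c]\nout: B[c] ->\n")
        mm = pf.enumerate_efms(net)
        assert len(mm) == 1  # the two-cycle of the split reaction is removed

    def test_fully_reversible_mode_counted_once_with_mirror_bookkeeping(self):
        net = pf.load_network(
            "ex_a: A[c] <-> \nr: A[c] <-> B[c]\nex_b: B[c] <-> \n"
        )
        mm = pf.enumerate_efms(net)
        assert len(mm) == 1
        assert mm.n_fully_reversible == 1
        assert mm.count_mirrored_twice == 2
        first_nonzero = next(v for v in mm.modes[0] if v != 0)
        assert first_nonzero > 0  # canonical sign

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_subset_rank_brute_force(self, seed):
        try:
            net = pf.load_network(_random_toy(seed))
        except NetworkError:
            pytest.skip("random draw produced a duplicate reaction")
        mm = pf.enumerate_efms(net)
        oracle = set(brute_force_efms(net))
        assert _canonical_set(mm) == oracle, f"seed {seed}"

    def test_enumeration_deterministic(self, ref_network):
        text = pf.data_path("kt2440_glycerol_model.txt").read_text(encoding="utf-8")
        a = pf.enumerate_efms(pf.load_network(text))
        b = pf.enumerate_efms(pf.load_network(text))
        assert a.reaction_ids == b.reaction_ids
        assert a.modes == b.modes

    def test_size_guard(self, ref_network):
        with pytest.raises(EfmError, match="exceeding"):
            pf.enumerate_efms(ref_network, max_reactions=10)


class TestReferenceEnumeration:
    def test_mode_count_matches_published(self, ref_modes):
        assert ref_modes.count_mirrored_once == 1533

    def test_every_mode_at_steady_state_exact(self, ref_modes, ref_network):
        S, _, _ = ref_network.stoichiometric_matrix_exact()
        for m in ref_modes.modes[::97] + [ref_modes.modes[-1]]:
            for row in S:
                assert sum(c * v for c, v in zip(row, m)) == 0

    def test_irreversible_signs_respected(self, ref_modes, ref_network):
        irrev = [not r.reversible for r in ref_network.reactions]
        for m in ref_modes.modes:
            assert all(v >= 0 for v, ir in zip(m, irrev) if ir)

    def test_no_support_contains_another(self, ref_modes):
        # spot check on the smallest supports, where violations would appear
        sups = sorted(
            (frozenset(i for i, v in enumerate(m) if v != 0) for m in ref_modes.modes),
            key=len,
        )[:60]
        for i, a in enumerate(sups):
            for b in sups[:i]:
                assert not (b < a)

    def test_elementarity_rank_criterion(self, ref_modes, ref_network):
        S, _, _ = ref_network.stoichiometric_matrix()
        rng = np.random.default_rng(7)
        idx = rng.choice(len(ref_modes), size=40, replace=False)
        for i in idx:
            support = [j for j, v in enumerate(ref_modes.modes[i]) if v != 0]
            rank = np.linalg.matrix_rank(S[:, support])
            assert rank == len(support) - 1, f"mode {i}"


class TestNormalizeAndSelect:
    def test_scaling(self, diamond_network):
        mm = pf.enumerate_efms(diamond_network)
        norm = pf.normalize_modes(mm, "up")
        for m in norm.modes:
            assert m[norm.reaction_ids.index("up")] == 1

    def test_zero_reference_modes_excluded_and_counted(self):
        # a cofactor-style internal cycle has no flux through the uptake
        net = pf.load_network(
            "in: -> A[c]\nr: A[c] -> B[c]\nout: B[c] ->\n"
            "c1: X[c] -> Y[c]\nc2: Y[c] -> X[c]\n"
        )
        mm = pf.enumerate_efms(net)
        norm = pf.normalize_modes(mm, "in")
        assert norm.n_excluded_zero_reference == 1
        assert len(norm) == len(mm) - 1

    def test_unknown_reference_rejected(self, ref_modes):
        with pytest.raises(EfmError):
            pf.normalize_modes(ref_modes, "nope")

    def test_reference_modes_conserve_boundary_carbon(self, ref_modes_normalized):
        for i in range(0, len(ref_modes_normalized), 23):
            c_in, c_out = boundary_carbon_balance(ref_modes_normalized, i)
            assert c_in == c_out
            assert c_in == 3  # one glycerol in after normalization

    def test_select_requires_all_products(self, ref_modes_normalized):
        sel = pf.select_producing_modes(
            ref_modes_normalized,
            {"PHA[c]", "biomass[c]", "SUCC_ex[e]", "MAL_ex[e]"},
        )
        assert len(sel) > 0
        for i in range(len(sel)):
            prods = sel.products(i)
            assert {"PHA[c]", "biomass[c]", "SUCC_ex[e]", "MAL_ex[e]"} <= prods

    def test_empty_requirement_is_identity(self, ref_modes_normalized):
        sel = pf.select_producing_modes(ref_modes_normalized, set())
        assert len(sel) == len(ref_modes_normalized)

    def test_unknown_product_rejected(self, ref_modes_normalized):
        with pytest.raises(EfmError, match="unknown"):
            pf.select_producing_modes(ref_modes_normalized, {"XYZ[c]"})


class TestYieldSpace:
    def test_requires_normalization(self, ref_modes):
        with pytest.raises(EfmError, match="normalized"):
            pf.yield_space(ref_modes)

    def test_yields_nonnegative_and_carbon_bounded(self, ref_modes_normalized):
        pts = pf.yield_space(ref_modes_normalized)
        for p in pts:
            assert p.biomass_yield >= 0 and p.pha_yield >= 0
            # 27 g/C-mol slightly overcounts the lumped biomass carbon
            assert p.biomass_yield + p.pha_yield <= 1.0 + 0.005

    def test_full_oxidation_mode_at_origin(self, ref_modes_normalized):
        pts = pf.yield_space(ref_modes_normalized)
        assert min(p.biomass_yield + p.pha_yield for p in pts) == pytest.approx(0)

    def test_experimental_yield_below_mode_maximum(self, ref_modes_normalized):
        pts = pf.yield_space(ref_modes_normalized)
        max_pha = max(p.pha_yield for p in pts)
        # best observed PHA yield, in C-mol/C-mol
        from phaflux._constants import GLYCEROL_MOLAR_MASS, PHA_LUMP_CARBON, PHA_LUMP_MASS
        y_obs = 0.08 * GLYCEROL_MOLAR_MASS / PHA_LUMP_MASS * float(PHA_LUMP_CARBON) / 3
        assert max_pha > y_obs
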