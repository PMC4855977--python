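"""Physical constants and compound composition tables.

Carbon counts are per molecule of the species as it appears in the
stoichiometric model.  Conserved cofactor moieties (NAD(P)H, ATP/ADP,
ubiquinone, CoA) are bookkept as carbon-free: they cycle internally and
never cross the system boundary, so only the transferred group matters
(acetyl-CoA counts the 2 acetyl carbons, succinyl-CoA the 4 succinyl
carbons).
"""

from __future__ import annotations

from fractions import Fraction

#: Molar mass of glycerol, g mol^-1 (C3H8O3).
GLYCEROL_MOLAR_MASS = 92.09

#: Biomass elemental convention: grams of cell dry weight per C-mol.
BIOMASS_G_PER_CMOL = 27.0

#: C-mmol of carbon per gram cell dry weight (= 1000/27 ~ 37.04).
BIOMASS_CMMOL_PER_G = 1000.0 / BIOMASS_G_PER_CMOL

#: mcl-PHA monomer residue masses, g mol^-1 (3-hydroxyacyl units in the
#: polymer, i.e. monomer minus water): C8H14O2, C10H18O2, C12H22O2.
PHA_RESIDUE_MASS = {8: 142.20, 10: 170.25, 12: 198.30}

#: Lumped PHA composition (mol fraction of C8/C10/C12 residues per lump unit).
PHA_LUMP_COMPOSITION = {8: 0.17, 10: 0.75, 12: 0.08}

#: Mass of one lumped PHA unit, g mol^-1 (~167.73).
PHA_LUMP_MASS = sum(
    frac * PHA_RESIDUE_MASS[n] for n, frac in PHA_LUMP_COMPOSITION.items()
)

#: Carbon atoms per lumped PHA unit (0.75*10 + 0.17*8 + 0.08*12 = 9.82).
PHA_LUMP_CARBON = Fraction("9.82")

#: Default P/O ratio (ATP per reduced oxygen atom) for converting substrate
#: maintenance into ATP maintenance.
DEFAULT_PO_RATIO = 1.75

#: Dilution rate above which washout is observed for P. putida KT2440 on
#: glycerol (h^-1); used as the validity bound of chemostat simulations.
WASHOUT_DILUTION_RATE = 0.22

#: Carbon atoms per species (model naming).  Lumped pseudo-species (PHA,
#: biomass) are listed in LUMPED_SPECIES_CARBON instead.
SPECIES_CARBON: dict[str, int] = {
    "GLY": 3,
    "GLY-3P": 3,
    "DHAP": 3,
    "GAP": 3,
    "13-PG": 3,
    "3-PG": 3,
    "2-PG": 3,
    "PEP": 3,
    "PYR": 3,
    "G6P": 6,
    "F6P": 6,
    "FBP": 6,
    "6-P-Gluconate": 6,
    "KDPG": 6,
    "RIB-5P": 5,
    "RIBO-5P": 5,
    "XYL-5P": 5,
    "S7P": 7,
    "E4P": 4,
    "AcCoA": 2,
    "CIT": 6,
    "ICI": 6,
    "AKG": 5,
    "SUCC-CoA": 4,
    "SUCC": 4,
    "FUM": 4,
    "MAL": 4,
    "OAA": 4,
    "Glyoxy": 2,
    "CO2": 1,
    "FORMATE": 1,
    "FORMATE_ex": 1,
    "MAL_ex": 4,
    "SUCC_ex": 4,
    "C8-PHA": 8,
    "C10-PHA": 10,
    "C12-PHA": 12,
    # carbon-free species / conserved moieties
    "ATP": 0,
    "ADP": 0,
    "NAD": 0,
    "NADH": 0,
    "NADP": 0,
    "NADPH": 0,
    "Q": 0,
    "QH2": 0,
    "O2": 0,
    "NH3": 0,
    "SO4": 0,
    "H2S": 0,
    "ATPmaintenance": 0,
}

#: Effective carbon content of lumped pseudo-species, exact rationals.
#: PHA: 0.75*10 + 0.17*8 + 0.08*12.  Biomass: carbon of the precursor drain
#: of the biomass equation (36.887 C-mmol per unit ~ 1 gCDW), slightly below
#: the 1000/27 elemental convention.
LUMPED_SPECIES_CARBON: dict[str, Fraction] = {
    "PHA": PHA_LUMP_CARBON,
    "biomass": Fraction("36.887"),
}


def species_carbon(name: str) -> Fraction:
    """Carbon atoms of a species by base name (compartment stripped)."""
    if name in LUMPED_SPECIES_CARBON:
        return LUMPED_SPECIES_CARBON[name]
    try:
        return Fraction(SPECIES_CARBON[name])
    except KeyError:
        raise KeyError(f"no carbon count known for species {name!r}") from None
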