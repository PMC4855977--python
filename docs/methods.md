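# Methods

## Chemostat physiology

At steady state in a chemostat the specific growth rate equals the
dilution rate D, so the Pirt relation q_s = μ/Y_true + m_s is fitted by
ordinary least squares of the specific glycerol uptake rate against D.
The regression runs on the mass scale (g glycerol gCDW⁻¹ h⁻¹) exactly as
the rates are tabulated, and only the fitted intercept is converted to
mmol using a glycerol molar mass of 92.09 g mol⁻¹; fitting on the scale of
the recorded data avoids compounding rounding error through a prior unit
conversion. Standard errors are the usual t-based OLS errors with n − 2
degrees of freedom and no weighting, since the rate table carries no
per-point error model. A negative fitted intercept is reported with a
flag rather than clamped: it is a legitimate regression outcome on noisy
data and clamping would bias downstream maintenance estimates.

ATP maintenance is m_ATP = (0.3939 + 2.33·P/O)·m_s with P/O = 1.75 by
default (ATP per reduced oxygen atom in oxidative phosphorylation).

Carbon recovery is balanced on the specific-rate basis: carbon in is
3 C per glycerol; carbon out sums CO₂, biomass at 27 g per C-mol
(37.04 C-mmol gCDW⁻¹), PHA from the weight fraction f via the rate
D·f/(1 − f) and the lumped polymer composition, and 4 C per secreted
succinate or malate. Published per-row recoveries were evidently computed
from unrounded primary data; recomputation from rounded printed rates
reproduces them only as a band (93–105 % across the reference conditions,
with the nitrogen-limited high-dilution row at 94.5 %), so row-exact
reproduction is not claimed.

## The metabolic network

The reference model is the central-carbon network of *P. putida* KT2440
on glycerol: 62 reactions (11 transport source/sinks, 18 reversible),
54 species, with anabolism lumped into one biomass equation and mcl-PHA
lumped as 0.75 C10 + 0.17 C8 + 0.08 C12 3-hydroxyacyl residues
(9.82 C and 167.73 g per lump unit; residue masses 142.20, 170.25 and
198.30 g mol⁻¹ for C8/C10/C12 — the saturated C12 mass is used although a
minor C12:1 fraction is reported experimentally). The accompanying prose
states 63 reactions; the printed table contains 62, and the parser loads
what is printed rather than inventing the difference. One consequence is
that cytosolic formate has no producing reaction, so the formate secretion
branch is structurally blocked; the validator reports it as a dead end.

Coefficients are stored as exact rationals (decimal coefficients such as
16.548 become exact fractions), which makes the null-space computations
downstream exact. The parser accepts ASCII (`->`, `<->`) and typographic
(`→`, `↔`, `⟺`) arrows, bare and parenthesized coefficients, and repairs
a missing closing compartment bracket when unambiguous — all variants
that occur in the printed source. Compartments are labels only. The
biomass equation drains 36.887 C-mmol of precursor carbon per unit,
within 0.5 % of the 27 g/C-mol elemental convention, so one unit of
biomass flux ≈ 1 gCDW and the biomass sink flux is numerically the
specific growth rate.

Parallel reactions with identical equations but distinct explicit ids are
accepted (isozymes); a repeated equation without an id is rejected as an
accidental double entry.

## Flux balance analysis

Growth is maximized by linear programming (HiGHS) over S·v = 0 with
irreversibility bounds and scenario constraints. A chemostat observation
maps to a scenario as: glycerol uptake and organic-acid secretion fixed at
measured values; CO₂ constrained to measured ± one printed SD (an exactly
fixed CO₂ over-determines the balance given rounding of the printed
rates); the PHA sink fixed at D·f/(1 − f)·1000/167.73 mmol gCDW⁻¹ h⁻¹;
ATP maintenance fixed, defaulting to the Pirt-derived 0.175 at P/O 1.75;
the biomass objective left free (optionally pinned at D). All fluxes are
specific (mmol gCDW⁻¹ h⁻¹); node fractions and flux ratios, which are
normalization-invariant, are the reproduction surface.

Alternate optima are resolved by a parsimonious second LP that minimizes
total absolute flux with the objective pinned at its optimum, and every
scenario carries a flux-variability report (per-reaction min/max at the
optimum) so that degeneracy is stated rather than hidden.

A caveat this diagnostic exposes: under the nitrogen-limited constraint
sets the partitioning of isocitrate between isocitrate dehydrogenase and
the glyoxylate shunt is *not* determined by the optimum. The shunt
fraction can take any value in roughly [0, 96] % at maximal growth — even
at minimal total flux — because transhydrogenase and substrate cycles can
compensate the CO₂/NADPH differences between the two routes. The
parsimonious selection lands at 0 %; a minimum-Euclidean-norm selection
also lands at 0 %; blocking both transhydrogenases forces ~95 %; the
interior-point analytic center sits near 47 % with heavy futile cycling.
Published interior values for this split therefore reflect a particular
LP implementation's choice on the degenerate face, not a property of the
data, and this package reports the parsimonious value together with the
feasible range instead of tuning toward any particular point.

## Elementary flux modes

Enumeration uses the null-space variant of the double description method
with exact integer arithmetic throughout: reversible reactions are split
into forward/backward columns; an exact kernel basis of the split
stoichiometric matrix is arranged to carry an identity block on its free
columns; the remaining non-negativity constraints are imposed one at a
time (cheapest-constraint-first ordering), combining adjacent
positive/negative ray pairs under the combinatorial zero-set adjacency
test with bit-set supports. Reactions that cannot carry steady-state flux
(species with no producer or no consumer, applied to a fixed point) are
pruned first and restored as zero rows. Floats appear only at output.
Exactness is not a luxury here: the published mode count is reproduced
exactly (1533), which tolerance-based enumeration cannot guarantee.

Spurious two-cycles from the reversible split are removed, and the mirror
images of modes supported entirely on reversible reactions are
de-duplicated to a canonical orientation (first nonzero flux positive);
counts under both mirror conventions are reported. For the reference
network no fully reversible mode exists, so the conventions coincide.
Mode ordering is made deterministic by sorting on support pattern and
exact values. The enumeration refuses networks above a configurable size
bound (default 128 reactions): the double description method is
combinatorial and this implementation is written for compact
central-carbon models, not genome scale.

Modes are normalized to unit glycerol uptake (cofactor-only cycles with
zero reference flux are excluded and counted), and the yield space maps
each mode to (biomass yield, PHA yield) in C-mol per C-mol with glycerol
at 3 C, biomass at 37.04 C-mmol gCDW⁻¹ and the PHA lump at 9.82 C. The
small gap between 37.04 (elemental convention) and 36.887 (precursor
drain of the biomass equation) is why the carbon-sum invariant
biomass_yield + pha_yield ≤ 1 carries a 0.005 tolerance.

## Flux-design target prediction

Across the subset of modes that simultaneously secrete PHA, biomass,
succinate and malate (the products observed under nitrogen limitation),
each reaction's normalized flux is correlated with the PHA sink flux.
The cutoff of 0.7 is interpreted as |Pearson r| ≥ 0.7 — the correlation
reading of "regression coefficient" — with a two-sided t-test at
α = 0.05 and no multiple-testing correction; both r and the OLS slope
(the target potential coefficient) are reported so the alternative
slope-cutoff reading can be audited. Classified targets are ranked by
|slope| within amplification/attenuation, ties broken by reaction id;
the priority metric behind the published ranking is not stated, and
|slope| is recorded here as the package's assumption.

On the reference network this reproduces the published sign structure for
the Entner–Doudoroff pathway, oxidative PP pathway and upper EMP
(positive, amplification) and for lower glycolysis and the
TCA/glyoxylate/secretion group (negative), but the glyoxylate-shunt and
secretion reactions correlate at r = −0.644 (p = 0.024) on our 12-mode
co-producing subset — significant and negative, yet below the 0.7
classification cutoff. A one-reaction difference in the source network
(62 printed vs 63 stated reactions) plausibly shifts this boundary case.

## Synthetic data

The chemostat generator draws q = μ/Y_true + m_true + N(0, σ) on the mass
scale over the eight-point dilution grid of the reference design
(0.044–0.210 h⁻¹, below the 0.22 h⁻¹ washout bound), with σ defaulting to
0.01 g gCDW⁻¹ h⁻¹ — the magnitude implied by the printed rate SDs (about
0.15 mmol on an uptake of 2.47). Noise is additive Gaussian, truncated at
zero by resampling; defaults m_true = 0.0036 (mass scale, ≈ 0.039 mmol)
and Y_true = 0.505 mirror the fitted physiology. The rate generator
perturbs only the exchange fluxes of a known optimal flux distribution
(multiplicative Gaussian), never internal fluxes, closing the loop
scenario → FBA → observation → scenario. The planted mode matrix gives
flux-design tests a known answer. All generators are pure functions of
(parameters, seed).

What the generators do not emulate: correlated measurement error between
rates, systematic biomass-composition drift with growth rate, transient
(non-steady-state) behaviour, and replicate-level batch effects. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated error model, not robustness to violations of it.

## Numerical choices and limitations

- Steady state is accepted at ‖S·v‖∞ ≤ 1e−8 for LP solutions (exact for
  rational mode arithmetic); irreversible fluxes may undershoot zero by
  1e−9.
- FVA widths above 1e−6 mark a reaction as degenerate at the optimum.
- The Pirt fit requires ≥ 2 distinct dilution rates and reports standard
  errors only for n ≥ 3.
- Problem sizes: the packaged analyses run on the 62-reaction network
  (1533 modes, ~2 s enumeration); synthetic recovery studies use 200–500
  replicates of the 8-point design.
- No SBML import/export, no genome-scale models, no thermodynamic or
  13C constraints, no transcriptome integration; volumetric rates are out
  of scope because nitrogen-limited biomass concentrations are not
  tabulated.
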