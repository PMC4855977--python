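"""Plain-text stoichiometric network model: parsing, validation, S matrix.

The model format is one reaction per line::

    # comment
    [pathway: Citric acid cycle]
    gltA: AcCoA[c] + OAA[c] -> CIT[c]

``->``/``→`` denote irreversible reactions, ``<->``/``↔``/``⟺`` reversible
ones.  Coefficients may be bare (``2 ATP[c]``) or parenthesized
(``(1.33) ADP[c]``) and default to 1; an exchange reaction leaves one side
empty.  A missing closing bracket on a compartment tag is repaired when
unambiguous.  Coefficients are stored as exact rationals so that null-space
computations downstream stay exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from ._constants import species_carbon, LUMPED_SPECIES_CARBON

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "ReactionParseError",
    "parse_reaction",
    "format_reaction",
    "load_network",
    "stoichiometric_matrix",
    "validate_network",
]


class NetworkError(ValueError):
    """Structural problem in a metabolic network definition."""


class ReactionParseError(NetworkError):
    """Malformed reaction string; carries the offending position."""

    def __init__(self, message: str, text: str, position: int = 0):
        super().__init__(f"{message} at position {position}: {text!r}")
        self.text = text
        self.position = position


@dataclass(frozen=True)
class Species:
    """A metabolite in one compartment (c = cytosol, p = periplasm, e = extracellular)."""

    id: str
    compartment: str
    is_boundary: bool = False

    @property
    def token(self) -> str:
        return f"{self.id}[{self.compartment}]"


@dataclass
class Reaction:
    """One reaction: signed rational stoichiometry over species tokens."""

    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool
    pathway: str = ""
    is_exchange: bool = False

    def __post_init__(self):
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise NetworkError(f"reaction {self.id!r} has a zero coefficient")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    def __eq__(self, other):
        if not isinstance(other, Reaction):
            return NotImplemented
        return (
            self.id == other.id
            and self.stoichiometry == other.stoichiometry
            and self.reversible == other.reversible
            and self.is_exchange == other.is_exchange
        )


_ARROWS_REVERSIBLE = ("⟺", "↔", "<->", "<=>")
_ARROWS_IRREVERSIBLE = ("→", "->")

# species term: optional coefficient (bare or parenthesized), then NAME[x]
# with an optionally missing closing bracket.
_TERM_RE = re.compile(
    r"^(?:\((?P<pcoef>\d+(?:\.\d+)?|\d+/\d+)\)\s*|(?P<coef>\d+(?:\.\d+)?|\d+/\d+)\s+)?"
    r"(?P<name>[A-Za-z0-9][A-Za-z0-9_\-']*)\[(?P<cmpt>[a-z])\]?$"
)


def _split_arrow(text: str) -> tuple[str, str, bool]:
    for arrow in _ARROWS_REVERSIBLE:
        if arrow in text:
            left, _, right = text.partition(arrow)
            if any(a in right for a in _ARROWS_REVERSIBLE + _ARROWS_IRREVERSIBLE):
                raise ReactionParseError("multiple arrows", text, text.index(arrow))
            return left, right, True
    for arrow in _ARROWS_IRREVERSIBLE:
        if arrow in text:
            left, _, right = text.partition(arrow)
            if any(a in right for a in _ARROWS_REVERSIBLE + _ARROWS_IRREVERSIBLE):
                raise ReactionParseError("multiple arrows", text, text.index(arrow))
            return left, right, False
    raise ReactionParseError("no reaction arrow found", text)


def _parse_side(side: str, text: str) -> dict[str, Fraction]:
    coeffs: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return coeffs
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            raise ReactionParseError("empty species term", text, text.find("+"))
        m = _TERM_RE.match(term)
        if m is None:
            raise ReactionParseError(
                f"malformed species term {term!r}", text, text.find(term)
            )
        coef = Fraction(m.group("pcoef") or m.group("coef") or 1)
        token = f"{m.group('name')}[{m.group('cmpt')}]"
        coeffs[token] = coeffs.get(token, Fraction(0)) + coef
    return coeffs


def parse_reaction(text: str, id: str = "", pathway: str = "") -> Reaction:
    """Parse one reaction string into a :class:`Reaction`.

    A species occurring on both sides nets its coefficients; a reaction
    whose net stoichiometry is empty (e.g. ``A[c] -> A[c]``) is rejected.
    """
    raw = text.strip()
    if not raw:
        raise ReactionParseError("empty reaction", text)
    left, right, reversible = _split_arrow(raw)
    subs = _parse_side(left, raw)
    prods = _parse_side(right, raw)
    if not subs and not prods:
        raise ReactionParseError("both sides empty", raw)
    net: dict[str, Fraction] = {}
    for tok, c in subs.items():
        net[tok] = net.get(tok, Fraction(0)) - c
    for tok, c in prods.items():
        net[tok] = net.get(tok, Fraction(0)) + c
    net = {tok: c for tok, c in net.items() if c != 0}
    if not net:
        raise ReactionParseError("net stoichiometry is empty (self-cancelling)", raw)
    return Reaction(
        id=id or "",
        stoichiometry=net,
        reversible=reversible,
        pathway=pathway,
        is_exchange=not subs or not prods,
    )


def _format_coef(c: Fraction) -> str:
    if c.denominator == 1:
        return str(c.numerator)
    f = float(c)
    if Fraction(str(f)) == c:
        return str(f)
    return f"{c.numerator}/{c.denominator}"


def format_reaction(rxn: Reaction) -> str:
    """Serialize a reaction back to the text grammar (canonical form)."""

    def side(coeffs: dict[str, Fraction]) -> str:
        parts = []
        for tok, c in coeffs.items():
            parts.append(tok if c == 1 else f"{_format_coef(c)} {tok}")
        return " + ".join(parts)

    arrow = "<->" if rxn.reversible else "->"
    return f"{side(rxn.substrates)} {arrow} {side(rxn.products)}".strip()


@dataclass
class MetabolicNetwork:
    """Ordered species and reactions; provides the stoichiometric matrix S."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = ""

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_species(self) -> list[Species]:
        return [s for s in self.species if not s.is_boundary]

    @property
    def n_reversible(self) -> int:
        return sum(r.reversible for r in self.reactions)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in network")

    def stoichiometric_matrix_exact(self):
        """Exact rational S over internal species: (rows, row_index, col_index)."""
        tokens = [s.token for s in self.internal_species]
        row_index = {tok: i for i, tok in enumerate(tokens)}
        col_index = {r.id: j for j, r in enumerate(self.reactions)}
        S = [[Fraction(0)] * len(self.reactions) for _ in tokens]
        for j, r in enumerate(self.reactions):
            for tok, c in r.stoichiometry.items():
                if tok in row_index:
                    S[row_index[tok]][j] = c
        return S, row_index, col_index

    def stoichiometric_matrix(self):
        """Float S over internal species: (ndarray, row_index, col_index)."""
        S, row_index, col_index = self.stoichiometric_matrix_exact()
        return (
            np.array([[float(c) for c in row] for row in S]),
            row_index,
            col_index,
        )

    def to_tsv(self) -> str:
        lines = ["id\tequation\treversible\tpathway"]
        for r in self.reactions:
            lines.append(
                f"{r.id}\t{format_reaction(r)}\t{int(r.reversible)}\t{r.pathway}"
            )
        return "\n".join(lines) + "\n"


def stoichiometric_matrix(network: MetabolicNetwork):
    """Module-level convenience wrapper around the network method."""
    return network.stoichiometric_matrix()


_SECTION_RE = re.compile(r"^\[pathway:\s*(?P<name>[^\]]+)\]$")
_ID_RE = re.compile(r"^(?P<id>[A-Za-z_][A-Za-z0-9_\-]*)\s*:\s*(?P<eq>.*)$")


def load_network(source: str | Path, name: str = "") -> MetabolicNetwork:
    """Load a network from model text or a path to a model file.

    Raises :class:`NetworkError` (with the line number) on unparseable
    lines, duplicate ids or duplicate reaction equations; an empty model
    is an error.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
        name = name or Path(source).name
    else:
        text = str(source)

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    seen_eqs: dict[tuple, int] = {}
    pathway = ""
    auto = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sect = _SECTION_RE.match(line)
        if sect:
            pathway = sect.group("name").strip()
            continue
        m = _ID_RE.match(line)
        if m and ("→" in m.group("eq") or "->" in m.group("eq") or "↔" in m.group("eq")
                  or "⟺" in m.group("eq") or "<->" in m.group("eq")):
            rid, eq = m.group("id"), m.group("eq")
            named = True
        else:
            auto += 1
            rid, eq = f"R{auto}", line
            named = False
        try:
            rxn = parse_reaction(eq, id=rid, pathway=pathway)
        except ReactionParseError as exc:
            raise NetworkError(f"line {lineno}: {exc}") from exc
        if rid in seen_ids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        # a repeated equation without a distinguishing id is almost surely an
        # accidental double entry; identical equations under distinct explicit
        # ids are legitimate (isozymes / parallel routes)
        key = (frozenset(rxn.stoichiometry.items()), rxn.reversible)
        if not named and key in seen_eqs:
            raise NetworkError(
                f"line {lineno}: duplicate reaction equation "
                f"(same as line {seen_eqs[key]})"
            )
        seen_ids.add(rid)
        if not named:
            seen_eqs[key] = lineno
        reactions.append(rxn)

    if not reactions:
        raise NetworkError("model contains no reactions")

    # species in order of first appearance
    tokens: list[str] = []
    for r in reactions:
        for tok in r.stoichiometry:
            if tok not in tokens:
                tokens.append(tok)
    # boundary = appears only in exchange reactions
    in_internal = set()
    for r in reactions:
        if not r.is_exchange:
            in_internal.update(r.stoichiometry)
    species = []
    for tok in tokens:
        sid, cmpt = tok[:-3], tok[-2]
        species.append(Species(sid, cmpt, is_boundary=tok not in in_internal))
    return MetabolicNetwork(species=species, reactions=reactions, name=name)


@dataclass
class ValidationReport:
    """Structural diagnostics of a network (informational, never raises)."""

    n_reactions: int
    n_species: int
    n_exchange: int
    n_reversible: int
    expected_reversible: int | None
    dead_end_species: list[str]
    never_produced: list[str]
    never_consumed: list[str]
    carbon_imbalance: dict[str, float]
    lumped_reactions: list[str]
    biomass_carbon: float | None

    @property
    def reversible_count_matches(self) -> bool | None:
        if self.expected_reversible is None:
            return None
        return self.n_reversible == self.expected_reversible


def _reaction_carbon_delta(rxn: Reaction) -> Fraction | None:
    """Net carbon produced minus consumed; None if a species is unknown."""
    total = Fraction(0)
    for tok, c in rxn.stoichiometry.items():
        name = tok[:-3]
        try:
            total += c * species_carbon(name)
        except KeyError:
            return None
    return total


def validate_network(
    network: MetabolicNetwork, expected_reversible: int | None = 18
) -> ValidationReport:
    """Report dead ends, production/consumption gaps and carbon imbalances.

    Reactions involving lumped pseudo-species (biomass, the PHA lump) are
    flagged as intentionally lumped rather than reported as imbalanced.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in network.reactions:
        for tok, c in r.stoichiometry.items():
            if c > 0 or r.reversible:
                produced.add(tok)
            if c < 0 or r.reversible:
                consumed.add(tok)
    internal = {s.token for s in network.internal_species}
    never_produced = sorted(t for t in internal if t not in produced)
    never_consumed = sorted(t for t in internal if t not in consumed)
    dead_ends = sorted(set(never_produced) | set(never_consumed))

    imbalance: dict[str, float] = {}
    lumped: list[str] = []
    biomass_carbon = None
    for r in network.reactions:
        names = {tok[:-3] for tok in r.stoichiometry}
        if names & set(LUMPED_SPECIES_CARBON):
            lumped.append(r.id)
            if "biomass" in names and not r.is_exchange:
                # carbon drained from precursors per unit biomass
                drain = Fraction(0)
                for tok, c in r.stoichiometry.items():
                    name = tok[:-3]
                    if name not in LUMPED_SPECIES_CARBON:
                        drain -= c * species_carbon(name)
                biomass_carbon = float(drain)
            continue
        if r.is_exchange:
            continue
        delta = _reaction_carbon_delta(r)
        if delta is not None and delta != 0:
            imbalance[r.id] = float(delta)

    return ValidationReport(
        n_reactions=len(network.reactions),
        n_species=len(network.species),
        n_exchange=len(network.exchange_reactions),
        n_reversible=network.n_reversible,
        expected_reversible=expected_reversible,
        dead_end_species=dead_ends,
        never_produced=never_produced,
        never_consumed=never_consumed,
        carbon_imbalance=imbalance,
        lumped_reactions=lumped,
        biomass_carbon=biomass_carbon,
    )
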