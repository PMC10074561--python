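"""Plain-text reaction networks for coupled binding equilibria.

A system is described by one reversible reaction per line in its
dissociation direction::

    A + B = AB; Kd
    AB + C = ABC; Kd2/alpha   # constants may be arithmetic in named parameters

Species that never appear as a product are the *components* of the
system: they cannot dissociate further and their free concentrations are
the unknowns of the mass-balance equations.  Everything on a product
side is a *complex*.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import sympy

__all__ = [
    "Reaction",
    "ReactionSystem",
    "ReactionParseError",
    "ReactionValidationError",
    "parse_reactions",
]

logger = logging.getLogger(__name__)

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

# operators allowed inside a dissociation-constant expression
_ALLOWED_EXPR = re.compile(r"^[A-Za-z0-9_+\-*/(). ^]*$")


class ReactionParseError(ValueError):
    """A line of the system description could not be parsed."""


class ReactionValidationError(ValueError):
    """The parsed reactions do not form a valid closed, acyclic network."""


def _parse_constant(text: str, lineno: int) -> sympy.Expr:
    text = text.strip()
    if not text:
        raise ReactionParseError(f"line {lineno}: missing dissociation constant")
    if not _ALLOWED_EXPR.match(text):
        raise ReactionParseError(
            f"line {lineno}: constant expression {text!r} contains "
            "characters outside identifiers, numbers and + - * / ( )"
        )
    # map every identifier to a plain positive symbol so that names like
    # "beta" or "E" are never captured by sympy built-ins
    local_dict = {
        name: sympy.Symbol(name, positive=True)
        for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", text)
    }
    try:
        expr = sympy.parse_expr(text, local_dict=local_dict, evaluate=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ReactionParseError(
            f"line {lineno}: cannot parse constant expression {text!r}"
        ) from exc
    for atom in expr.atoms(sympy.Function):
        raise ReactionParseError(
            f"line {lineno}: function calls are not allowed in constants ({atom})"
        )
    return expr


@dataclass(frozen=True)
class Reaction:
    """One reversible binding reaction, written in its dissociation direction.

    ``reactants`` is the dissociated side (two or more slots; a species
    may repeat, e.g. dimerisation ``A + A = AA``), ``product`` the single
    complex formed, and ``constant`` the dissociation constant
    K = (product of free reactant concentrations) / [complex], given as a
    sympy expression over named parameters (concentration units).
    """

    reactants: tuple[str, ...]
    product: str
    constant: sympy.Expr

    @property
    def parameters(self) -> frozenset[str]:
        return frozenset(str(s) for s in self.constant.free_symbols)

    def to_text(self) -> str:
        return f"{' + '.join(self.reactants)} = {self.product}; {self.constant}"

    def __eq__(self, other):
        if not isinstance(other, Reaction):
            return NotImplemented
        return (
            Counter(self.reactants) == Counter(other.reactants)
            and self.product == other.product
            and self.constant == other.constant
        )

    def __hash__(self):
        return hash((frozenset(Counter(self.reactants).items()), self.product))


@dataclass(frozen=True)
class ReactionSystem:
    """A validated, closed, acyclic network of reversible reactions."""

    reactions: tuple[Reaction, ...]
    components: tuple[str, ...] = field(init=False)
    complexes: tuple[str, ...] = field(init=False)
    parameters: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        products = {r.product for r in self.reactions}
        species: set[str] = set(products)
        for r in self.reactions:
            species.update(r.reactants)
        components = tuple(sorted(species - products))
        params: set[str] = set()
        for r in self.reactions:
            params.update(r.parameters)
        clash = params & species
        if clash:
            raise ReactionValidationError(
                f"names used both as species and as parameters: {sorted(clash)}"
            )
        # keep complexes in first-appearance order of their defining reaction
        complexes = []
        for r in self.reactions:
            if r.product not in complexes:
                complexes.append(r.product)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "complexes", tuple(complexes))
        object.__setattr__(self, "parameters", tuple(sorted(params)))
        self._validate()

    @property
    def species(self) -> tuple[str, ...]:
        return self.components + self.complexes

    def _validate(self) -> None:
        if not self.reactions:
            raise ReactionValidationError("no reactions: empty system description")
        # acyclicity of complex -> reactants, by depth-first search
        producing: dict[str, list[Reaction]] = {}
        for r in self.reactions:
            producing.setdefault(r.product, []).append(r)
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(name: str, stack: tuple[str, ...]) -> None:
            if name not in producing:
                return
            if state.get(name) == 1:
                return
            if state.get(name) == 0:
                cycle = " -> ".join(stack + (name,))
                raise ReactionValidationError(
                    f"cyclic complex definition: {cycle}"
                )
            state[name] = 0
            for r in producing[name]:
                for reac in r.reactants:
                    visit(reac, stack + (name,))
            state[name] = 1

        for c in self.complexes:
            visit(c, ())
        # composition must agree across all defining reactions of a complex
        for c in self.complexes:
            comps = [self._composition_via(r) for r in producing[c]]
            if any(comp != comps[0] for comp in comps[1:]):
                raise ReactionValidationError(
                    f"complex {c} has formation paths with different "
                    f"component stoichiometry: {[dict(x) for x in comps]}"
                )

    def _composition_via(self, reaction: Reaction) -> Counter:
        total: Counter = Counter()
        for reac in reaction.reactants:
            total.update(self.composition(reac))
        return total

    def composition(self, name: str) -> Counter:
        """Component stoichiometry of a species, by recursive expansion
        of its reactant tree (names are free-form: no subscript parsing)."""
        if name in self.components:
            return Counter({name: 1})
        for r in self.reactions:
            if r.product == name:
                return self._composition_via(r)
        raise KeyError(f"unknown species {name!r}")

    def reactions_producing(self, name: str) -> list[Reaction]:
        return [r for r in self.reactions if r.product == name]

    def to_text(self) -> str:
        return "\n".join(r.to_text() for r in self.reactions) + "\n"

    def __eq__(self, other):
        if not isinstance(other, ReactionSystem):
            return NotImplemented
        return frozenset(self.reactions) == frozenset(other.reactions)

    def __hash__(self):
        return hash(frozenset(self.reactions))

    def __repr__(self):
        return (
            f"ReactionSystem({len(self.reactions)} reactions, "
            f"components={list(self.components)}, "
            f"complexes={list(self.complexes)})"
        )


def component_count(system: ReactionSystem) -> int:
    """Number of components n: the system reduces to n mass-balance
    equations with the n free component concentrations as unknowns."""
    return len(system.components)


def _parse_line(line: str, lineno: int) -> Reaction:
    if ";" not in line:
        raise ReactionParseError(
            f"line {lineno}: expected 'A + B = C; constant', got {line!r}"
        )
    head, _, const_text = line.partition(";")
    if "=" not in head:
        raise ReactionParseError(
            f"line {lineno}: missing '=' in {line!r}"
        )
    left, _, right = head.partition("=")
    reactants = tuple(tok.strip() for tok in left.split("+"))
    product = right.strip()
    if "=" in right:
        raise ReactionParseError(f"line {lineno}: multiple '=' in {line!r}")
    for name in (*reactants, product):
        if not _IDENT.match(name):
            raise ReactionParseError(
                f"line {lineno}: {name!r} is not a valid species identifier "
                "(alphanumeric + underscore; '+', '=', ';' are reserved)"
            )
    if len(reactants) < 2:
        raise ReactionParseError(
            f"line {lineno}: a reaction needs at least two reactant slots "
            "(write dimerisation as 'A + A = AA')"
        )
    constant = _parse_constant(const_text, lineno)
    return Reaction(reactants=reactants, product=product, constant=constant)


def parse_reactions(text: str) -> ReactionSystem:
    """Parse a multiline system description into a :class:`ReactionSystem`.

    Blank lines and ``#`` comments are ignored.  Components are identified
    automatically as the species that never appear as a product.  Parameter
    names appearing in constant expressions are auto-declared (and logged).
    """
    reactions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        reactions.append(_parse_line(line, lineno))
    system = ReactionSystem(tuple(reactions))
    logger.info(
        "parsed system: %d reactions, %d components (%s), %d complexes, "
        "parameters auto-declared: %s",
        len(system.reactions),
        len(system.components),
        ", ".join(system.components),
        len(system.complexes),
        ", ".join(system.parameters),
    )
    return system
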