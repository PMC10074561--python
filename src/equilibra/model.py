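"""Symbolic derivation of equilibrium models from a reaction network.

For every reaction ``r1 + r2 + ... = C; K`` at equilibrium the mass-action
ratio fixes the complex concentration::

    [C] = [r1][r2].../K

Substituting recursively until only free *component* concentrations and
parameters remain gives a closed-form expression for every complex.  One
mass balance per component then states that its total equals its free
concentration plus its stoichiometry-weighted occurrence in every complex.
The n balances in the n free component concentrations are the system that
the numerical solver closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy

from .reactions import ReactionSystem

__all__ = [
    "EquilibriumModel",
    "DataFunction",
    "CycleInconsistencyError",
    "build_model",
    "derive_complex_expression",
    "build_mass_balances",
    "compile_data_function",
    "anisotropy_data_function",
    "model_summary",
]


class CycleInconsistencyError(ValueError):
    """Two formation paths of a complex give different expressions,
    i.e. the thermodynamic cycle closed by the constants is inconsistent."""


def total_symbol(component: str) -> sympy.Symbol:
    return sympy.Symbol(f"{component}_tot", positive=True)


def _derive_all(system: ReactionSystem) -> dict[str, sympy.Expr]:
    """Closed-form expression for every complex, with the cycle check."""
    exprs: dict[str, sympy.Expr] = {
        c: sympy.Symbol(c, positive=True) for c in system.components
    }

    def derive(name: str) -> sympy.Expr:
        if name in exprs:
            return exprs[name]
        candidates = []
        for r in system.reactions_producing(name):
            num = sympy.Integer(1)
            for reac in r.reactants:
                num *= derive(reac)
            candidates.append(sympy.together(num / r.constant))
        first = candidates[0]
        for other in candidates[1:]:
            if sympy.simplify(first - other) != 0:
                raise CycleInconsistencyError(
                    f"complex {name} is reachable by paths giving different "
                    f"expressions:\n  {first}\n  {other}\n"
                    "the dissociation constants violate detailed balance"
                )
        exprs[name] = first
        return first

    for c in system.complexes:
        derive(c)
    return {c: exprs[c] for c in system.complexes}


def derive_complex_expression(system: ReactionSystem, complex_name: str) -> sympy.Expr:
    """Equilibrium concentration of ``complex_name`` as an expression in
    free component concentrations and parameters only."""
    if complex_name not in system.complexes:
        raise KeyError(f"{complex_name!r} is not a complex of the system")
    return _derive_all(system)[complex_name]


def build_mass_balances(system: ReactionSystem) -> list[sympy.Eq]:
    """One conservation equation per component:
    total = free + sum over complexes of (stoichiometric count x complex)."""
    exprs = _derive_all(system)
    balances = []
    for comp in system.components:
        rhs = sympy.Symbol(comp, positive=True)
        for cx in system.complexes:
            count = system.composition(cx).get(comp, 0)
            if count:
                rhs = rhs + count * exprs[cx]
        balances.append(sympy.Eq(total_symbol(comp), rhs))
    return balances


@dataclass(frozen=True)
class DataFunction:
    """Maps a solved equilibrium state to one predicted observable.

    ``expression`` is arithmetic over species concentrations and scalar
    parameters (e.g. a luminescence scaling factor in RLU per molar, or an
    anisotropy baseline/amplitude pair).  ``scalars`` lists the non-species
    symbols; they take part in fitting like any other parameter.
    """

    expression: sympy.Expr
    scalars: tuple[str, ...]
    label: str = "signal"

    def __call__(self, species_concentrations: dict, scalar_values: dict) -> float:
        subs = {sympy.Symbol(k, positive=True): v for k, v in species_concentrations.items()}
        subs.update({sympy.Symbol(k, positive=True): v for k, v in scalar_values.items()})
        return float(self.expression.xreplace(subs))


@dataclass(frozen=True)
class EquilibriumModel:
    """A reaction system together with its derived symbolic model."""

    system: ReactionSystem
    complex_exprs: dict[str, sympy.Expr]
    mass_balances: tuple[sympy.Eq, ...]
    data_function: DataFunction | None = None

    @property
    def parameters(self) -> tuple[str, ...]:
        """Equilibrium-constant parameters plus data-function scalars."""
        extra = self.data_function.scalars if self.data_function else ()
        return tuple(self.system.parameters) + tuple(
            s for s in extra if s not in self.system.parameters
        )

    def with_data_function(self, data_function: DataFunction) -> "EquilibriumModel":
        return EquilibriumModel(
            system=self.system,
            complex_exprs=self.complex_exprs,
            mass_balances=self.mass_balances,
            data_function=data_function,
        )


def build_model(
    system: ReactionSystem, data_function: DataFunction | None = None
) -> EquilibriumModel:
    """Derive the full symbolic model (complex expressions + mass balances)."""
    return EquilibriumModel(
        system=system,
        complex_exprs=_derive_all(system),
        mass_balances=tuple(build_mass_balances(system)),
        data_function=data_function,
    )


def compile_data_function(
    model: EquilibriumModel | ReactionSystem,
    expr_text: str,
    scalars: tuple[str, ...] | list[str] = (),
    label: str = "signal",
) -> DataFunction:
    """Compile an observable expression such as ``"ABTa * Scaling"``.

    Every symbol must be a species of the system or a name listed in
    ``scalars``; anything else raises with the list of valid species.
    ``X_tot`` totals of components are also accepted (useful for
    fraction-bound style observables).
    """
    system = model.system if isinstance(model, EquilibriumModel) else model
    expr = sympy.sympify(expr_text, rational=False)
    valid = set(system.species) | set(scalars)
    valid |= {f"{c}_tot" for c in system.components}
    unknown = {str(s) for s in expr.free_symbols} - valid
    if unknown:
        raise ValueError(
            f"unknown species in data function: {sorted(unknown)}; "
            f"valid species are {sorted(system.species)} "
            f"(declare scalar parameters via scalars=...)"
        )
    # rebuild with positive symbols so it cancels cleanly against model exprs
    expr = expr.xreplace(
        {s: sympy.Symbol(str(s), positive=True) for s in expr.free_symbols}
    )
    return DataFunction(expression=expr, scalars=tuple(scalars), label=label)


def anisotropy_data_function(
    model: EquilibriumModel | ReactionSystem,
    labeled: str,
    bound_species: tuple[str, ...] | list[str] | None = None,
    label: str = "anisotropy",
) -> DataFunction:
    """Standard anisotropy/polarisation observable for a titration of a
    labelled component::

        baseline + amplitude * (sum of bound species) / total(labeled)

    ``bound_species`` defaults to every complex containing the labelled
    component, weighted by its stoichiometric count.  ``baseline`` and
    ``amplitude`` are fittable scalars.
    """
    system = model.system if isinstance(model, EquilibriumModel) else model
    if labeled not in system.components:
        raise ValueError(
            f"{labeled!r} is not a component; components: {list(system.components)}"
        )
    if bound_species is None:
        bound = [
            (cx, system.composition(cx)[labeled])
            for cx in system.complexes
            if system.composition(cx).get(labeled, 0)
        ]
    else:
        bound = []
        for cx in bound_species:
            if cx not in system.complexes:
                raise ValueError(
                    f"{cx!r} is not a complex; complexes: {list(system.complexes)}"
                )
            bound.append((cx, system.composition(cx).get(labeled, 1)))
    frac = sum(
        n * sympy.Symbol(cx, positive=True) for cx, n in bound
    ) / total_symbol(labeled)
    baseline = sympy.Symbol("baseline", positive=True)
    amplitude = sympy.Symbol("amplitude", positive=True)
    return DataFunction(
        expression=baseline + amplitude * frac,
        scalars=("baseline", "amplitude"),
        label=label,
    )


def model_summary(model: EquilibriumModel) -> str:
    """Human-readable dump of the derived model, for inspection."""
    sys_ = model.system
    lines = [
        "Equilibrium model",
        f"  components ({len(sys_.components)}): {', '.join(sys_.components)}",
        f"  complexes  ({len(sys_.complexes)}): {', '.join(sys_.complexes)}",
        f"  parameters: {', '.join(model.parameters)}",
        "",
        "Complex expressions:",
    ]
    for cx in sys_.complexes:
        lines.append(f"  [{cx}] = {model.complex_exprs[cx]}")
    lines.append("")
    lines.append("Mass balances:")
    for eq in model.mass_balances:
        lines.append(f"  {eq.lhs} = {eq.rhs}")
    if model.data_function is not None:
        lines.append("")
        lines.append(
            f"Data function ({model.data_function.label}): "
            f"{model.data_function.expression}"
        )
    return "\n".join(lines) + "\n"
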