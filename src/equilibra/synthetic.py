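"""Synthetic titrations with known ground truth.

Every fixture emulates the kind of data the models are fitted to in
practice: a geometric titrate series, an observable that is a data
function of the solved equilibrium species, and additive Gaussian
replicate noise (optionally relative, for luminescence-like signals).
Three ready-made network topologies cover the canonical use cases:

* a 1:1 protein-protein interaction (hub protein R binding partner P),
* a molecular-glue ternary complex with cooperativity ``alpha`` closing
  a thermodynamic cycle,
* a sandwich immunoassay with two bivalent antibodies conjugated to
  split-luciferase halves (statistical factors on the antibody arms, an
  effective molarity EM driving intramolecular complementation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import TitrationDataset
from .model import (
    EquilibriumModel,
    anisotropy_data_function,
    build_model,
    compile_data_function,
)
from .reactions import ReactionSystem, parse_reactions
from .solve import compile_model

__all__ = [
    "SyntheticSpec",
    "make_synthetic",
    "ppi_system",
    "ternary_glue_system",
    "rappid_system",
    "rappid_extended_system",
    "make_paper_topologies",
    "stress_system",
    "ppi_model",
    "ternary_glue_model",
    "rappid_model",
    "ppi_spec",
    "ternary_spec",
    "rappid_spec",
    "PPI_TRUTH",
    "TERNARY_TRUTH",
    "RAPPID_TRUTH",
    "RAPPID_BOUNDS",
    "ANISO_SCALARS",
]

PPI_TEXT = "R + P = RP; Kd1\n"

TERNARY_TEXT = """\
# partner or stabilizer can bind first; alpha closes the cycle
R + P = RP; Kd1
R + S = RS; Kd2
RS + P = RPS; Kd1/alpha
RP + S = RPS; Kd2/alpha
"""

# Sandwich immunoassay: bivalent antibodies A and B bind the analyte T at
# distinct epitopes (statistical factors 1/2 and 2 on the two arms); free
# split-luciferase halves pair with KdN; within the inactive sandwich ABTi
# the effective molarity EM drives complementation to the light-emitting
# ABTa, so at equilibrium [ABTi]/[ABTa] = KdN/EM.  The ABTa-forming
# reaction is written through the AB route to keep every reaction
# bimolecular; its constant KdA*KdB/(4*EM) is fixed by the thermodynamic
# cycle.  10 species, 8 reversible reactions.
RAPPID_TEXT = """\
A + T = AT; KdA/2
AT + T = ATT; 2*KdA
B + T = BT; KdB/2
BT + T = BTT; 2*KdB
AT + B = ABTi; KdB/2
BT + A = ABTi; KdA/2
A + B = AB; KdN
AB + T = ABTa; KdA*KdB/(4*EM)
"""

# Synthetic reconstruction of the extended sandwich model: 8 additional
# equilibria adding the higher-order species in which both antibodies are
# bound to two analyte molecules at once (and a triply loaded sandwich),
# with constants fixed by the statistical factors and thermodynamic
# cycles of the 8-reaction core.
RAPPID_EXTENDED_TEXT = RAPPID_TEXT + """\
ABTi + T = ATTBi; 2*KdA
ATT + B = ATTBi; KdB/2
ABTi + T = ABTTi; 2*KdB
BTT + A = ABTTi; KdA/2
ABTa + T = ATTBa; 2*KdA
ABTa + T = ABTTa; 2*KdB
ATTBi + T = ATTBT; 2*KdB
ABTTi + T = ATTBT; 2*KdA
"""


def ppi_system() -> ReactionSystem:
    """1:1 binding: hub protein R + labelled partner P."""
    return parse_reactions(PPI_TEXT)


def ternary_glue_system() -> ReactionSystem:
    """Ternary complex stabilised by a molecular glue S with
    cooperativity alpha; four reactions, cycle-consistent."""
    return parse_reactions(TERNARY_TEXT)


def rappid_system() -> ReactionSystem:
    """Split-luciferase sandwich immunoassay, 8 reversible reactions
    over the three components A, B (antibodies) and T (analyte)."""
    return parse_reactions(RAPPID_TEXT)


def rappid_extended_system() -> ReactionSystem:
    """Extended sandwich model (16 equilibria) including two-analyte
    antibody complexes; a documented synthetic reconstruction."""
    return parse_reactions(RAPPID_EXTENDED_TEXT)


def make_paper_topologies() -> dict[str, ReactionSystem]:
    """The ready-made topologies, keyed by short name."""
    return {
        "ppi": ppi_system(),
        "ternary": ternary_glue_system(),
        "rappid8": rappid_system(),
        "rappid16": rappid_extended_system(),
    }


def ppi_model() -> EquilibriumModel:
    """PPI system with the standard anisotropy observable of labelled P."""
    sys_ = ppi_system()
    return build_model(sys_, anisotropy_data_function(sys_, labeled="P"))


def ternary_glue_model() -> EquilibriumModel:
    """Ternary system, anisotropy observable of labelled P (both RP and
    RPS count as bound)."""
    sys_ = ternary_glue_system()
    return build_model(sys_, anisotropy_data_function(sys_, labeled="P"))


def rappid_model(extended: bool = False) -> EquilibriumModel:
    """Sandwich model with luminescence observable ``ABTa * Scaling``
    (RLU; Scaling in RLU per molar)."""
    sys_ = rappid_extended_system() if extended else rappid_system()
    df = compile_data_function(sys_, "ABTa * Scaling", scalars=("Scaling",), label="RLU")
    return build_model(sys_, df)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic titration.

    ``noise`` is the Gaussian standard deviation added per replicate, in
    observable units, or as a fraction of each clean value when
    ``noise_relative`` is true.
    """

    model: EquilibriumModel
    true_parameters: dict[str, float]
    titrate: str
    titrate_range: tuple[float, float]
    fixed_totals: dict[str, float]
    n_points: int = 16
    noise: float = 0.0
    noise_relative: bool = False
    replicates: int = 3
    seed: int | None = None
    point_totals: list[dict[str, float] | None] | None = None
    concentrations: np.ndarray | None = None  # overrides the geometric series

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.titrate_range
        if not (0 < lo <= hi):
            raise ValueError("titrate range must be positive")


def make_synthetic(spec: SyntheticSpec) -> tuple[TitrationDataset, dict]:
    """Generate a dataset plus its ground-truth record.

    Observations are the data function of the exact equilibria plus
    noise; with a fixed seed the output is bitwise reproducible.
    """
    cm = compile_model(spec.model)
    if spec.concentrations is not None:
        concs = np.asarray(spec.concentrations, dtype=float)
    else:
        concs = np.geomspace(*spec.titrate_range, spec.n_points)
    df = spec.model.data_function
    if df is None:
        raise ValueError("model needs a data function to generate observables")
    scalars = {s: spec.true_parameters[s] for s in df.scalars}
    pvec = cm.param_vector(spec.true_parameters)
    rng = np.random.default_rng(spec.seed)
    clean = np.empty(len(concs))
    u_prev = None
    for i, conc in enumerate(concs):
        totals = dict(spec.fixed_totals)
        if spec.point_totals is not None and spec.point_totals[i]:
            totals.update(spec.point_totals[i])
        totals[spec.titrate] = float(conc)
        tvec = cm.totals_vector(totals)
        x, c, _res, _ = cm.solve_vectors(tvec, pvec, u0=u_prev)
        act = tvec > 0
        with np.errstate(divide="ignore"):
            u_prev = np.log(np.maximum(x[act], 1e-300))
        clean[i] = cm.predict(x, c, tvec, scalars)
    observations = []
    for i in range(len(concs)):
        sd = spec.noise * (abs(clean[i]) if spec.noise_relative else 1.0)
        observations.append(clean[i] + sd * rng.standard_normal(spec.replicates))
    dataset = TitrationDataset(
        titrate=spec.titrate,
        concentrations=concs,
        observations=observations,
        fixed_totals=dict(spec.fixed_totals),
        point_totals=spec.point_totals,
    )
    truth = {
        "true_parameters": dict(spec.true_parameters),
        "titrate": spec.titrate,
        "fixed_totals": dict(spec.fixed_totals),
        "noise": spec.noise,
        "noise_relative": spec.noise_relative,
        "replicates": spec.replicates,
        "seed": spec.seed,
        "clean_signal": clean.tolist(),
    }
    return dataset, truth


# -- default study conditions for the three topologies ----------------------

#: anisotropy scalars used throughout the fixtures (milli-anisotropy-like)
ANISO_SCALARS = {"baseline": 60.0, "amplitude": 120.0}

PPI_TRUTH = {"Kd1": 4.05e-6, **ANISO_SCALARS}
TERNARY_TRUTH = {"Kd1": 4.05e-6, "Kd2": 3.89e-4, "alpha": 1.34e3, **ANISO_SCALARS}
RAPPID_TRUTH = {
    "KdA": 5.33e-7,
    "KdB": 1.53e-8,
    "KdN": 2.5e-6,
    "EM": 1.0e-4,
    "Scaling": 5.53e17,
}

# With equal antibody totals the sandwich model is exactly symmetric under
# (A, KdA) <-> (B, KdB); both labelings are global optima of any fit.  In a
# real assay the two antibodies are characterised independently, so their
# affinities live on known, separated scales.  These bounds encode that
# prior knowledge and pin the labeling: A is the weaker binder.
RAPPID_BOUNDS = {"KdA": (1e-8, 1e-4), "KdB": (1e-10, 1e-7)}


def ppi_spec(noise=0.0, noise_relative=False, replicates=3, seed=None) -> SyntheticSpec:
    """Anisotropy titration of hub protein R against 10 nM labelled P."""
    return SyntheticSpec(
        model=ppi_model(),
        true_parameters=dict(PPI_TRUTH),
        titrate="R",
        titrate_range=(1e-8, 1e-3),
        fixed_totals={"P": 1e-8},
        n_points=16,
        noise=noise,
        noise_relative=noise_relative,
        replicates=replicates,
        seed=seed,
    )


def ternary_spec(
    noise=0.0, noise_relative=False, replicates=3, seed=None,
    stabilizer_levels=(1e-6, 1e-5, 1e-4, 1e-3),
) -> SyntheticSpec:
    """Family of R-titration curves at several glue concentrations
    (10 nM labelled P), represented as one multi-curve dataset.

    The stabilizer levels bracket the glue's own dissociation constant
    (sub-mM): only with near-saturating glue do the cooperativity and
    the glue affinity separate from their ratio."""
    n_per = 12
    concs, pts = [], []
    for s in stabilizer_levels:
        concs.append(np.geomspace(1e-8, 1e-3, n_per))
        pts.extend([{"S": s}] * n_per)
    concs = np.concatenate(concs)
    order = np.argsort(concs, kind="stable")
    return SyntheticSpec(
        model=ternary_glue_model(),
        true_parameters=dict(TERNARY_TRUTH),
        titrate="R",
        titrate_range=(1e-8, 1e-3),
        fixed_totals={"P": 1e-8, "S": 0.0},
        noise=noise,
        noise_relative=noise_relative,
        replicates=replicates,
        seed=seed,
        concentrations=concs[order],
        point_totals=[pts[i] for i in order],
    )


def rappid_spec(noise=0.0, noise_relative=True, replicates=3, seed=None,
                extended: bool = False) -> SyntheticSpec:
    """Luminescence titration of analyte T against 1 nM of each
    antibody; spans the rising flank and the hook."""
    truth = dict(RAPPID_TRUTH)
    return SyntheticSpec(
        model=rappid_model(extended=extended),
        true_parameters=truth,
        titrate="T",
        titrate_range=(1e-13, 1e-6),
        fixed_totals={"A": 1e-9, "B": 1e-9},
        n_points=16,
        noise=noise,
        noise_relative=noise_relative,
        replicates=replicates,
        seed=seed,
    )


def stress_system(
    n_species: int, seed: int = 0, max_complex_size: int = 6
) -> ReactionSystem:
    """Random acyclic ladder of complexes for solver stress testing.

    Starts from 3-5 components and repeatedly combines two existing
    species into a new complex with a log-uniform constant in
    [1e-9, 1e-3] M, up to ``n_species`` species in total.  Complexes are
    capped at ``max_complex_size`` components — real assemblies are
    wide, not arbitrarily deep, and the cap keeps the monomial
    coefficients within double-precision range.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    # the component chain uses 2*n_comp - 1 species; keep it within budget
    n_comp = int(min(rng.integers(3, 6), max(2, (n_species + 1) // 2)))
    names = [f"C{i}" for i in range(n_comp)]
    sizes = [1] * n_comp  # component count of each species
    lines = []
    k = 0
    # chain through every component first so none is left unused
    prev = 0
    for i in range(1, n_comp):
        if len(names) >= n_species or sizes[prev] >= max_complex_size:
            break
        prod = f"X{k}"
        kd = 10.0 ** rng.uniform(-9, -3)
        lines.append(f"{names[prev]} + {names[i]} = {prod}; {kd:.6e}")
        sizes.append(sizes[prev] + 1)
        names.append(prod)
        prev = len(names) - 1
        k += 1
    while len(names) < n_species:
        a, b = rng.choice(len(names), size=2, replace=True)
        if sizes[int(a)] + sizes[int(b)] > max_complex_size:
            continue
        prod = f"X{k}"
        kd = 10.0 ** rng.uniform(-9, -3)
        lines.append(f"{names[int(a)]} + {names[int(b)]} = {prod}; {kd:.6e}")
        sizes.append(sizes[int(a)] + sizes[int(b)])
        names.append(prod)
        k += 1
    return parse_reactions("\n".join(lines))
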