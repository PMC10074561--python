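# Methods

## Model construction

A system is specified as reversible reactions in their dissociation
direction, one per line: `A + B = AB; K`, where `K` may be an
arithmetic expression over named parameters (`Kd1/alpha`, `2*KdA`).
Species that never appear as a product are the **components**; their
free concentrations are the unknowns. Every constant is a
dissociation constant with the convention

    K = Π [free reactants] / [complex]     (concentration units),

so each complex concentration is obtained by recursive substitution
until only component concentrations and parameters remain. Because
every reaction is a product of species concentrations divided by a
constant, each complex expression is a *monomial* in the components,
`[C] = g(θ) · Π x_i^{n_i}`, with the exponents equal to the recursive
stoichiometry counts. Statistical factors (two equivalent arms of a
bivalent antibody, say) are written by the user into the constant
expressions (`KdA/2`, `2*KdA`), not inferred from symmetry.

When a complex is reachable by more than one reaction path, all paths
must give the identical expression (checked with sympy); a mismatch
means the entered constants violate detailed balance around a
thermodynamic cycle and model construction fails with both expressions
shown. Symbolic work is limited to substitution and cancellation so
the derived expressions are stable across runs.

One mass balance per component — total equals free plus
stoichiometry-weighted occurrence in every complex — closes the system:
*n* equations in *n* unknowns. All concentrations in one model share a
single unit (molar recommended); nothing is ever converted internally.

## Observables

The data function maps a solved state to one predicted value. Two
forms are built in:

* a custom arithmetic expression over species concentrations and scalar
  parameters, e.g. `ABTa * Scaling` for a luminescence assay where the
  signal is proportional to the active-complex concentration (`Scaling`
  in RLU per molar);
* an anisotropy/polarisation form
  `baseline + amplitude · (Σ bound species)/total(labelled component)`,
  the standard shape for titrations of a labelled component. The exact
  default observable forms used with the original datasets are not
  published with the main text, so this documented standard form is the
  package's own choice; `baseline` and `amplitude` are ordinary
  fittable scalars.

## Numerical solution

The unknowns are solved as logarithms `u_i = ln x_i`, which enforces
positivity and handles the fM-mM span the applications need. The
residual of balance *i* is scaled by the component's total, so the
convergence criterion (max relative residual ≤ 1e-8; the solver itself
targets 1e-15) is meaningful across magnitudes. Components with a
total of exactly zero are eliminated from the solve — their free
concentration and every complex containing them are exactly zero —
rather than floored to a tiny value; this is exact and avoids infinite
logarithms.

Stages, in order: (1) damped Newton with analytic Jacobian and
backtracking line search from the fully dissociated state (free =
total), or from a warm start along a titration; (2) Powell hybrid
(`scipy.optimize.root`) from the best iterate; (3) trust-region least
squares on the residuals. A state is only returned if the tolerance is
met; otherwise the failure carries the best residuals. Exponents are
clamped (exp ≤ ~4e260) so far-off iterates stay finite. For whole
titrations the Newton stage runs vectorised across all points (stacked
small linear solves), grouped by zero-total pattern, with a per-group
scalar fallback.

Uniqueness: for detailed-balance networks of this form the positive
equilibrium is unique, so the first root satisfying the physical
constraints is the answer; the solver never reports negative or
complex roots (they cannot occur in log space).

An independent **kinetic oracle** integrates the mass-action ODEs with
kon = 1 and koff = K per reaction to steady state (LSODA over
geometrically growing windows until the projected relative change per
window falls below 1e-10). It exists purely as a cross-check in the
test suite — the algebraic solver never consults it.

## Fitting

The error function is the mean squared error between replicate-averaged
observations and predictions, one term per titrate point. Estimation
uses `scipy.optimize.least_squares` (Trust Region Reflective) over
log10-transformed parameters; the transform enforces positivity and
equalises scales between, e.g., a nanomolar constant and a 1e17 scaling
factor. Families of curves (one titration repeated at several fixed
concentrations of another species) are a single dataset whose rows
carry per-row total overrides; all points weigh equally. If the
equilibrium solver fails at some iterate's parameters, that point's
residual becomes a large finite penalty and the optimisation continues.
Default initial guesses: geometric mean of the titrate range for
constants, 1 for declared dimensionless parameters, the largest
observed value for observable scalars — always overridable.

### Identifiability of the sandwich model

With equal totals of the two antibodies the sandwich model is exactly
symmetric under swapping (A, K_D,A) ↔ (B, K_D,B): both labelings are
global optima. In practice the two antibodies are characterised
independently, so the fits in the fixtures carry bounds
(K_D,A ∈ [10 nM, 100 μM], K_D,B ∈ [0.1 nM, 100 nM]) that encode this
prior knowledge and pin the labeling.

## Analyses

* **Model plot**: per-datum predictions plus a dense log-spaced curve
  (≥100 points per curve group).
* **Concentration profiles**: all species along a titrate range at
  fixed parameters; needs no data. Used, e.g., to exhibit the hook
  effect: with bivalent antibodies the active-sandwich concentration
  has a single interior maximum in analyte, because excess analyte
  saturates each antibody separately.
* **Error landscape**: objective on a log-spaced grid centred on the
  two named estimates (centre cell pinned exactly on the estimates),
  remaining parameters held fixed; failed cells are missing, not zero.
* **Bootstrap CI**: nonparametric, resampling whole titrate points
  (concentration with its replicate set) with replacement, refitting
  each resample from the original estimates, and reporting
  bias-corrected (BC, no acceleration) percentile intervals plus the
  plain bootstrap median. Failed refits are dropped and counted; more
  than 10% triggers a warning. Identical seed and repeat count give
  identical intervals.
* **Sensitivity**: one-at-a-time, every parameter (fitted and fixed)
  multiplied by (1 + perturbation); default M is the change in the sum
  of squared errors, with an alternative M tracking the maximum
  concentration of a named species over the titration. Raw and
  normalised (relative to the unperturbed reference) values are both
  reported; only orderings are asserted in tests, since the
  normalisation convention of the reference analysis is not published.

## Synthetic data

The generator emulates the experiment class the models are fitted to: a
geometric titrate series, observables computed from exactly solved
equilibria, and additive Gaussian replicate noise (optionally relative,
for luminescence-like signals). It does **not** emulate instrument
drift, pipetting error in the nominal concentrations, outliers, or
correlated noise — so passing recovery tests demonstrate correctness of
the estimation machinery under the stated noise model, not robustness
to real-world artefacts.

Study conditions of the three ready-made topologies (molar units):

| topology | truth | conditions |
|---|---|---|
| 1:1 binding | K_D = 4.05 μM | 16-point R-titration 10 nM–1 mM, P fixed 10 nM |
| ternary glue | K_D,I = 4.05 μM (fixed), K_D,II = 0.389 mM, α = 1340 | R-titrations (12 points) at glue levels 1 μM–1 mM, P fixed 10 nM |
| sandwich assay | K_D,A = 533 nM, K_D,B = 15.3 nM, K_D,N = 2.5 μM, EM = 100 μM, Scaling = 5.53e17 RLU/M | 16-point analyte titration 0.1 pM–1 μM, both antibodies 1 nM |

The anisotropy scalars default to baseline 60 and amplitude 120
(milli-anisotropy-like numbers typical of such titrations). The glue
levels deliberately bracket K_D,II: below saturation of the glue site
only the ratio α/K_D,II is identified (the stretched landscape valley),
and a design capped at 0.1 mM leaves the two parameters poorly
separated. The sandwich network is written with statistical factors on
the antibody arms, free luciferase pairing `A + B = AB; KdN`, and the
active sandwich entered through the cycle-consistent bimolecular route
`AB + T = ABTa; KdA*KdB/(4*EM)`, so that `[ABTi]/[ABTa] = KdN/EM`
without needing unimolecular reactions. The extended 16-reaction
variant (adding the two-antibody/two-analyte species and a triply
loaded sandwich) is a reconstruction from the qualitative description
of such models and is flagged as synthetic in its docstring.

`stress_system` builds random acyclic ladders (first chaining all
components so none is orphaned, then combining random species) with
log-uniform constants in [1 nM, 1 mM] for solver stress and oracle
comparisons.

## Sizes and seeds used by the checks

The acceptance-style checks use problem sizes chosen to characterise
the methods well on a single CPU: the closed-form comparison spans a
10^6-fold concentration range (61 points); the oracle comparison uses
100 random networks of up to 8 species; the bootstrap coverage
simulation runs 200 synthetic ternary experiments (two glue levels of
8 points, duplicate replicates, 1% noise) with 120 bootstrap refits per
interval — the repeat count is scaled down from the 2000 used for a
one-off reported interval, which widens per-interval quantile noise
slightly but leaves average coverage interpretable. All stochastic
steps take explicit seeds and are bitwise reproducible.

## Known limitations

* Dissociation constants only; no association constants, rate
  constants, irreversible steps, or time courses (the ODE integrator is
  a test oracle, not a feature).
* No activity coefficients or temperature dependence; one concentration
  unit per model.
* No global multi-dataset fits with shared parameters, no weighted
  least squares, no Bayesian posteriors; CIs are bootstrap-only.
* Sensitivity is local and one-at-a-time; no variance-based global
  analysis.
* The positive-equilibrium uniqueness argument assumes a
  detailed-balance network as parsed; exotic inputs with inconsistent
  cycles are rejected rather than approximated.
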