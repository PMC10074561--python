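# equilibra

Mass-balance equilibrium models of multicomponent biomolecular systems,
built automatically from the reversible reactions that define them.

Coupled binding equilibria — a molecular glue bridging two proteins, a
pair of bivalent antibodies sandwiching an analyte, a scaffold protein
with several partners — rarely admit closed-form solutions, and deriving
a custom numerical model by hand for every new system is slow and
error-prone. `equilibra` takes a plain-text list of reversible
reactions with dissociation constants,

```text
R + P = RP; Kd1
R + S = RS; Kd2
RS + P = RPS; Kd1/alpha
RP + S = RPS; Kd2/alpha
```

and from it derives, symbolically, the equilibrium concentration of
every complex in terms of the free *component* concentrations (species
that cannot dissociate further) and the constants. Each reaction
contributes a mass-action relation `K_D = Π[free reactants]/[complex]`;
recursive substitution gives, e.g., `[RPS] = α·[R][P][S]/(K_D,I·K_D,II)`
by either binding order (the thermodynamic cycle is checked
symbolically). One mass balance per component,

```
total_X = [X] + Σ_complexes count(X in complex) · [complex],
```

yields *n* equations in the *n* free concentrations, solved numerically
in log space (damped Newton with analytic Jacobians, escalating to a
Powell hybrid stage and a trust-region least-squares stage when
needed). On top of the solver sit:

* **fitting** — trust-region-reflective least squares over
  log10-transformed parameters against replicate-averaged titration
  data (constants, cooperativities, effective molarities, signal
  scaling factors);
* **analysis** — prediction curves, species-concentration profiles
  (e.g. the immunoassay hook effect), MSE landscapes over parameter
  pairs, nonparametric bias-corrected bootstrap confidence intervals,
  and local one-at-a-time parameter sensitivity;
* **synthetic data** — seeded generators with known ground truth for
  the canonical topologies (1:1 binding, ternary glue, split-luciferase
  sandwich immunoassay), so every part of the pipeline is testable
  end-to-end.

It is intended for chemical-biology practitioners analysing titration
data (fluorescence anisotropy/polarisation, luminescence) and designing
multicomponent assays, usable from Python or from a thin CLI.

## Worked example

`examples/01_binary_binding.py` fits a 1:1 binding constant from a
synthetic anisotropy titration of a hub protein R against 10 nM of a
labelled partner P, generated at K_D = 4.05 μM with 1% noise:

```text
Data function (anisotropy): baseline + RP*amplitude/P_tot

fitted Kd = 4.191 uM  (generated at 4.05 uM)
rmse = 0.422 anisotropy units over 16 points
```

The fitted constant lands within a few percent of the generating value
and the RMSE matches the injected noise level.
`examples/02_ternary_glue.py` continues with the molecular-glue system
(cooperativity α and glue affinity K_D,II fitted with K_D,I fixed),
showing the positively correlated error-landscape valley and bootstrap
intervals:

```text
alpha = 1291   (truth 1340)
Kd2   = 0.373 mM (truth 0.389 mM)
error-landscape valley slope (log alpha vs log Kd2): +0.85
Kd2 95% CI: (0.350; 0.372; 0.412) mM
```

and `examples/03_sandwich_hook.py` reproduces the immunoassay hook
effect (signal maximum at ~4.7 nM analyte for 1 nM antibodies) and the
sensitivity ordering of the assay parameters.

## Command line

```bash
equilibra build reactions.txt                 # show the derived model
equilibra simulate reactions.txt -p Kd1=1e-6 -t P=1e-8 \
    --titrate R --range 1e-9 1e-4             # species table (CSV)
equilibra make-config reactions.txt           # config template
equilibra fit config.yaml                     # point estimates (JSON)
equilibra analyze config.yaml --mode bootstrap --seed 1
equilibra make-synthetic --topology ternary --seed 0
```

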