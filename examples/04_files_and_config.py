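"""File-based workflow: reactions file, CSV data, YAML config.

The same pipeline the CLI drives, from Python: write a system
description and a synthetic dataset to disk, generate a config template,
fill in the parameter roles, and fit from the files alone.
"""

import tempfile
from pathlib import Path

from equilibra import (
    ExperimentConfig,
    fit,
    load_config,
    parse_reactions,
    write_titration_csv,
)
from equilibra.synthetic import make_synthetic, ppi_spec

workdir = Path(tempfile.mkdtemp())

(workdir / "reactions.txt").write_text("R + P = RP; Kd1\n")
dataset, truth = make_synthetic(ppi_spec(noise=0.01, noise_relative=True, seed=2))
write_titration_csv(workdir / "data.csv", dataset)

cfg = ExperimentConfig(
    reactions_file="reactions.txt",
    data_file="data.csv",
    titrate="R",
    unit="M",
    fixed_totals={"P": 1e-8},
    parameters={
        "Kd1": {"role": "fit", "value": 1e-5},
        "baseline": {"role": "fixed", "value": 60.0},
        "amplitude": {"role": "fixed", "value": 120.0},
    },
    data_function={"type": "anisotropy", "labeled": "P"},
    seed=2,
)
cfg.save(workdir / "config.yaml")

# reload from disk and run the fit purely from the files
loaded = load_config(workdir / "config.yaml")
problem = loaded.build_problem(base_dir=workdir)
result = fit(problem)

system = parse_reactions((workdir / "reactions.txt").read_text())
print(f"system: components {system.components}, complexes {system.complexes}")
print(f"fitted Kd1 = {result.estimates['Kd1'] * 1e6:.3f} uM "
      f"(generated at {truth['true_parameters']['Kd1'] * 1e6:.2f} uM)")
print(f"files in {workdir}: reactions.txt, data.csv, config.yaml")
# Everything on disk is plain text: the reaction list, a CSV titration
# (concentration column + replicate columns) and a YAML config naming
# each parameter's role. The CLI subcommands wrap exactly this flow.
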