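"""Cooperativity of a molecular glue: fit, error landscape, bootstrap CI.

A glue S stabilises the R:P interaction by a cooperativity factor alpha,
closing a thermodynamic cycle: either P or S can bind R first, and the
ternary complex concentration is alpha*R*P*S/(Kd1*Kd2) on both paths.
With the binary constant Kd1 known and fixed, a family of R-titration
curves at several glue concentrations determines alpha and the glue's
own affinity Kd2 — but only jointly well: the error landscape shows the
positively correlated valley, and the bootstrap interval quantifies the
spread.
"""

import numpy as np

from equilibra import FitProblem, bootstrap_ci, error_landscape, fit
from equilibra.synthetic import TERNARY_TRUTH, make_synthetic, ternary_spec

spec = ternary_spec(noise=0.01, noise_relative=True, seed=11)
dataset, _ = make_synthetic(spec)

problem = FitProblem(
    model=spec.model,
    dataset=dataset,
    free_parameters={"alpha": 400.0, "Kd2": 1e-3},
    fixed_parameters={"Kd1": TERNARY_TRUTH["Kd1"],
                      "baseline": 60.0, "amplitude": 120.0},
)
result = fit(problem)
print(f"alpha = {result.estimates['alpha']:.0f}   (truth {TERNARY_TRUTH['alpha']:.0f})")
print(f"Kd2   = {result.estimates['Kd2'] * 1e3:.3f} mM (truth "
      f"{TERNARY_TRUTH['Kd2'] * 1e3:.3f} mM)")

grid = error_landscape(problem, result, "Kd2", "alpha", span=10, resolution=11)
# slope of the valley floor in log-log: positive means weaker glue
# binding can be traded against stronger cooperativity
floor = np.nanargmin(grid.mse, axis=0)
slope = np.polyfit(np.log10(grid.x_values), np.log10(grid.y_values[floor]), 1)[0]
print(f"error-landscape valley slope (log alpha vs log Kd2): {slope:+.2f}")

ci = bootstrap_ci(problem, result, repeats=500, seed=1)
lo, med, hi = ci.intervals["Kd2"]
print(f"Kd2 95% CI: ({lo * 1e3:.3f}; {med * 1e3:.3f}; {hi * 1e3:.3f}) mM")
lo, med, hi = ci.intervals["alpha"]
print(f"alpha 95% CI: ({lo:.0f}; {med:.0f}; {hi:.0f})")
# Wide, order-of-magnitude intervals are expected: they mirror the
# stretched valley of the landscape.
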