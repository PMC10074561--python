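"""Standard analyses over a fitted or fully specified model.

Covers the assessment toolbox used once a model exists: prediction
curves against the data, species-concentration profiles along a
titration (no data needed), mean-squared-error landscapes over parameter
pairs, nonparametric bias-corrected bootstrap confidence intervals, and
local parameter sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fitting import FitProblem, FitResult, TitrationDataset, fit, predict_dataset
from .model import EquilibriumModel
from .solve import CompiledModel, Condition, SolverFailure, compile_model, solve_titration

__all__ = [
    "ModelPlot",
    "LandscapeGrid",
    "BootstrapCI",
    "SensitivityReport",
    "model_plot",
    "concentration_profiles",
    "error_landscape",
    "bootstrap_ci",
    "sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelPlot:
    """Per-datum predictions plus a dense curve for plotting."""

    points: pd.DataFrame  # titrate conc, replicate mean, prediction, curve id
    curve: pd.DataFrame   # dense log-spaced predictions, per curve id


def _curve_groups(dataset: TitrationDataset):
    """Group dataset rows by their fixed-total overrides (one prediction
    curve per group, e.g. per stabilizer concentration)."""
    groups: dict[tuple, list[int]] = {}
    for i in range(len(dataset)):
        if dataset.point_totals is not None and dataset.point_totals[i]:
            key = tuple(sorted(dataset.point_totals[i].items()))
        else:
            key = ()
        groups.setdefault(key, []).append(i)
    return groups


def model_plot(
    problem: FitProblem, result: FitResult, n_curve: int = 120
) -> ModelPlot:
    """Experimental data (replicate means) with the model prediction at
    the point estimates, per datum and as a dense curve (>= 100
    log-spaced points spanning the data range)."""
    values = problem.full_values(result.estimates)
    preds, _ = predict_dataset(problem, values)
    ds = problem.dataset
    cm = problem.compiled
    df = problem.model.data_function
    scalars = {s: values[s] for s in df.scalars}
    pvec = cm.param_vector(values)

    groups = _curve_groups(ds)
    point_rows, curve_rows = [], []
    for gid, (key, idxs) in enumerate(groups.items()):
        overrides = dict(key)
        for i in idxs:
            point_rows.append(
                (gid, ds.concentrations[i], ds.replicate_means[i], preds[i])
            )
        lo = ds.concentrations[idxs].min()
        hi = ds.concentrations[idxs].max()
        dense = np.geomspace(lo, hi, n_curve)
        u_prev = None
        for conc in dense:
            totals = {**ds.fixed_totals, **overrides, ds.titrate: float(conc)}
            tvec = cm.totals_vector(totals)
            x, c, _r, _e = cm.solve_vectors(tvec, pvec, u0=u_prev)
            with np.errstate(divide="ignore"):
                u_prev = np.log(np.maximum(x[tvec > 0], 1e-300))
            curve_rows.append((gid, conc, cm.predict(x, c, tvec, scalars)))
    points = pd.DataFrame(
        point_rows, columns=["curve", ds.titrate, "observed_mean", "predicted"]
    )
    curve = pd.DataFrame(curve_rows, columns=["curve", ds.titrate, "predicted"])
    return ModelPlot(points=points, curve=curve)


def concentration_profiles(
    model: EquilibriumModel | CompiledModel,
    parameter_values: dict[str, float],
    fixed_totals: dict[str, float],
    titrate: str,
    titrate_range: tuple[float, float],
    n_points: int = 100,
) -> pd.DataFrame:
    """Tidy table of every species concentration along a log-spaced
    titration; purely predictive, no experimental data involved."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    concs = np.geomspace(*titrate_range, n_points)
    eq_values = {p: parameter_values[p] for p in cm.param_names}
    conditions = [
        Condition(totals={**fixed_totals, titrate: float(c)}, parameter_values=eq_values)
        for c in concs
    ]
    states = solve_titration(cm, conditions, strict=False)
    rows = []
    for conc, st in zip(concs, states):
        if st is None:
            continue
        for name, value in st.species.items():
            rows.append((conc, name, value))
    return pd.DataFrame(rows, columns=[titrate, "species", "concentration"])


@dataclass(frozen=True)
class LandscapeGrid:
    parameter_x: str
    parameter_y: str
    x_values: np.ndarray  # log-spaced, centred on the estimate
    y_values: np.ndarray
    mse: np.ndarray       # shape (len(y), len(x)); NaN where the solve failed


def error_landscape(
    problem: FitProblem,
    result: FitResult,
    parameter_x: str,
    parameter_y: str,
    span: float = 10.0,
    resolution: int = 21,
) -> LandscapeGrid:
    """Objective surface over a log-spaced grid centred on the point
    estimates; the remaining parameters are held at their estimates.
    ``span`` is the multiplicative half-width of each axis."""
    from .fitting import objective

    for p in (parameter_x, parameter_y):
        if p not in result.estimates:
            raise ValueError(f"{p!r} is not a fitted parameter")
    cx = result.estimates[parameter_x]
    cy = result.estimates[parameter_y]
    if resolution == 1:
        xs = np.array([cx])
        ys = np.array([cy])
    else:
        xs = np.geomspace(cx / span, cx * span, resolution)
        ys = np.geomspace(cy / span, cy * span, resolution)
        # pin the centre cell exactly on the estimates
        xs[resolution // 2] = cx
        ys[resolution // 2] = cy
    mse = np.full((len(ys), len(xs)), np.nan)
    base = dict(result.estimates)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            vals = {**base, parameter_x: float(x), parameter_y: float(y)}
            try:
                mse[iy, ix] = objective(problem, vals)
            except (SolverFailure, ValueError) as exc:
                logger.warning(
                    "landscape cell (%d, %d) failed: %s", iy, ix, exc
                )
    return LandscapeGrid(
        parameter_x=parameter_x, parameter_y=parameter_y,
        x_values=xs, y_values=ys, mse=mse,
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Bias-corrected percentile intervals per fitted parameter."""

    intervals: dict[str, tuple[float, float, float]]  # lower, median, upper
    level: float
    repeats: int
    failures: int
    seed: int | None
    warning: str | None = None


def bootstrap_ci(
    problem: FitProblem,
    result: FitResult,
    repeats: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Nonparametric bootstrap: whole titrate points (a concentration
    with its replicate set) are resampled with replacement, each
    resample is refitted starting from the original point estimates, and
    bias-corrected (BC) percentile intervals are reported together with
    the plain bootstrap median."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if repeats < 100:
        raise ValueError("at least 100 repeats are needed for an interval")
    rng = np.random.default_rng(seed)
    ds = problem.dataset
    names = list(result.estimates)
    samples = {n: [] for n in names}
    failures = 0
    for _ in range(repeats):
        idx = rng.integers(0, len(ds), len(ds))
        try:
            sub = ds.subset(idx)
            sub_problem = FitProblem(
                model=problem.model,
                dataset=sub,
                free_parameters=dict(result.estimates),
                fixed_parameters=dict(problem.fixed_parameters),
                bounds=dict(problem.bounds),
            )
            r = fit(sub_problem, xtol=1e-8, ftol=1e-8)
        except (SolverFailure, ValueError) as exc:
            logger.warning("bootstrap resample failed: %s", exc)
            failures += 1
            continue
        if not np.all(np.isfinite(list(r.estimates.values()))):
            failures += 1
            continue
        for n in names:
            samples[n].append(r.estimates[n])
    n_ok = repeats - failures
    warning = None
    if failures > 0.1 * repeats:
        warning = f"{failures}/{repeats} bootstrap refits failed"
        logger.warning(warning)
    alpha = 1.0 - level
    intervals = {}
    for n in names:
        theta = np.sort(np.asarray(samples[n]))
        that = result.estimates[n]
        # bias correction from the fraction of resamples below the estimate
        prop = (np.sum(theta < that) + 0.5 * np.sum(theta == that)) / len(theta)
        prop = np.clip(prop, 0.5 / len(theta), 1 - 0.5 / len(theta))
        z0 = norm.ppf(prop)
        lo_q = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
        hi_q = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
        lower = float(np.quantile(theta, lo_q))
        upper = float(np.quantile(theta, hi_q))
        median = float(np.quantile(theta, 0.5))
        intervals[n] = (lower, median, upper)
    return BootstrapCI(
        intervals=intervals, level=level, repeats=n_ok,
        failures=failures, seed=seed, warning=warning,
    )


@dataclass(frozen=True)
class SensitivityReport:
    """Change of the M-function per parameter after a fractional
    perturbation; ``raw`` in M units, ``normalized`` relative to the
    unperturbed reference."""

    perturbation: float
    m_function: str
    reference: float
    raw: dict[str, float]
    normalized: dict[str, float]


def sensitivity(
    problem: FitProblem,
    result: FitResult,
    perturbation: float = 0.5,
    m_function: str = "sse",
    species: str | None = None,
) -> SensitivityReport:
    """Local one-at-a-time sensitivity around the point estimates.

    Every parameter — fitted and fixed alike — is multiplied in turn by
    ``1 + perturbation`` while the others stay at their reference
    values.  The default M-function is the change in the sum of squared
    errors against the data; ``m_function="max_species"`` instead tracks
    the change in the maximum concentration of ``species`` (e.g. the
    active sandwich complex) over the dataset's titrate points.
    """
    if perturbation == -1.0:
        raise ValueError("a perturbation of -100% zeroes the parameter")
    values = problem.full_values(result.estimates)
    n = len(problem.dataset)

    if m_function == "sse":
        def m(vals):
            preds, _ = predict_dataset(problem, vals)
            return float(np.sum((preds - problem.dataset.replicate_means) ** 2))
    elif m_function == "max_species":
        if species is None:
            raise ValueError("m_function='max_species' needs a species name")
        cm = problem.compiled
        all_species = list(cm.components) + list(cm.complexes)
        if species not in all_species:
            raise ValueError(f"unknown species {species!r}")

        def m(vals):
            pvec = cm.param_vector(vals)
            best = 0.0
            u_prev = None
            for i in range(n):
                tvec = cm.totals_vector(problem.dataset.row_totals(i))
                x, c, _r, _e = cm.solve_vectors(tvec, pvec, u0=u_prev)
                with np.errstate(divide="ignore"):
                    u_prev = np.log(np.maximum(x[tvec > 0], 1e-300))
                conc = dict(zip(list(cm.components) + list(cm.complexes),
                                list(x) + list(c)))[species]
                best = max(best, conc)
            return best
    else:
        raise ValueError(f"unknown m_function {m_function!r}")

    reference = m(values)
    raw, normalized = {}, {}
    for name in values:
        perturbed = dict(values)
        perturbed[name] = values[name] * (1.0 + perturbation)
        mv = m(perturbed)
        raw[name] = mv - reference
        normalized[name] = (mv - reference) / reference if reference else np.nan
    return SensitivityReport(
        perturbation=perturbation, m_function=m_function,
        reference=reference, raw=raw, normalized=normalized,
    )
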