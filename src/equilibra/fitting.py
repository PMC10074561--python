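"""Least-squares estimation of equilibrium and observable parameters.

The error function is the mean squared error between replicate-averaged
observations and the data-function prediction at each titrate
concentration.  Fitting runs scipy's Trust Region Reflective
``least_squares`` over log10-transformed parameters, which enforces
positivity and copes with order-of-magnitude differences between, say, a
picomolar constant and a luminescence scaling factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import EquilibriumModel

__all__ = [
    "TitrationDataset",
    "FitProblem",
    "FitResult",
    "objective",
    "fit",
    "default_initial_guesses",
]

logger = logging.getLogger(__name__)


@dataclass
class TitrationDataset:
    """A titration: one component varied, all others fixed per curve.

    ``observations[i]`` holds the >= 1 technical repeats measured at
    ``concentrations[i]``.  ``point_totals[i]``, when given, overrides
    entries of ``fixed_totals`` for that row — this is how a family of
    curves at, e.g., several stabilizer concentrations is represented as
    one dataset (every point weighs equally in the fit).
    """

    titrate: str
    concentrations: np.ndarray
    observations: list[np.ndarray]
    fixed_totals: dict[str, float] = field(default_factory=dict)
    point_totals: list[dict[str, float] | None] | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1 or len(self.concentrations) == 0:
            raise ValueError("concentrations must be a nonempty 1-D array")
        if np.any(self.concentrations <= 0):
            raise ValueError("titrate concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("titrate concentrations must be sorted ascending")
        self.observations = [
            np.asarray(o, dtype=float).ravel() for o in self.observations
        ]
        if len(self.observations) != len(self.concentrations):
            raise ValueError("one observation row per concentration required")
        for i, o in enumerate(self.observations):
            if o.size == 0 or not np.any(np.isfinite(o)):
                raise ValueError(f"row {i}: needs at least one finite observation")
        if self.point_totals is not None and len(self.point_totals) != len(
            self.concentrations
        ):
            raise ValueError("point_totals must have one entry per row")
        self._means = np.array([np.nanmean(o) for o in self.observations])

    def __len__(self) -> int:
        return len(self.concentrations)

    @property
    def replicate_means(self) -> np.ndarray:
        """Technical repeats averaged per titrate concentration."""
        return self._means

    def row_totals(self, i: int) -> dict[str, float]:
        totals = dict(self.fixed_totals)
        if self.point_totals is not None and self.point_totals[i]:
            totals.update(self.point_totals[i])
        totals[self.titrate] = float(self.concentrations[i])
        return totals

    def subset(self, indices) -> "TitrationDataset":
        """Row subset (used by bootstrap resampling); re-sorted by
        concentration so the dataset invariant holds."""
        idx = np.asarray(indices, dtype=int)
        order = idx[np.argsort(self.concentrations[idx], kind="stable")]
        return TitrationDataset(
            titrate=self.titrate,
            concentrations=self.concentrations[order],
            observations=[self.observations[i] for i in order],
            fixed_totals=dict(self.fixed_totals),
            point_totals=(
                [self.point_totals[i] for i in order]
                if self.point_totals is not None
                else None
            ),
        )


@dataclass
class FitProblem:
    """Which parameters are estimated and which are held fixed."""

    model: EquilibriumModel
    dataset: TitrationDataset
    free_parameters: dict[str, float]  # name -> initial guess
    fixed_parameters: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        from .solve import compile_model

        self._compiled = compile_model(self.model)
        declared = set(self.free_parameters) | set(self.fixed_parameters)
        needed = set(self.model.parameters)
        overlap = set(self.free_parameters) & set(self.fixed_parameters)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if declared != needed:
            raise ValueError(
                f"free+fixed must cover every model parameter exactly once; "
                f"missing {sorted(needed - declared)}, "
                f"unknown {sorted(declared - needed)}"
            )
        if any(v <= 0 for v in self.free_parameters.values()):
            raise ValueError("initial guesses must be positive")
        # per-row total vectors and curve-group keys never change across
        # objective calls: precompute them once
        ds = self.dataset
        self._tmatrix = np.array(
            [self._compiled.totals_vector(ds.row_totals(i)) for i in range(len(ds))]
        )
        self._plan = self._compiled.batch_plan(self._tmatrix)
        self._warm_cache: dict = {}

    @property
    def compiled(self) -> CompiledModel:
        return self._compiled

    def full_values(self, free_values: dict[str, float]) -> dict[str, float]:
        return {**self.fixed_parameters, **free_values}


def _scalar_values(problem: FitProblem, values: dict[str, float]) -> dict[str, float]:
    df = problem.model.data_function
    if df is None:
        raise ValueError("model has no data function; cannot predict observables")
    return {s: values[s] for s in df.scalars}


def predict_dataset(
    problem: FitProblem, values: dict[str, float], warm: bool = False
) -> tuple[np.ndarray, int]:
    """Prediction at every dataset row; returns (predictions, n_failures).

    Rows where the equilibrium solver fails get a large finite penalty
    prediction so the optimiser survives a bad parameter region.
    ``warm=True`` reuses the previous call's solution as the starting
    point (used inside the fit loop, where the call sequence is fixed);
    the default cold start makes a single call bitwise reproducible.
    """
    cm = problem.compiled
    ds = problem.dataset
    pvec = cm.param_vector(values)
    scalars = _scalar_values(problem, values)
    means = ds.replicate_means
    penalty = 1e3 * (1.0 + np.max(np.abs(means)))
    T = problem._tmatrix
    X, C, failed = cm.solve_batch(
        T, pvec, warm_cache=problem._warm_cache if warm else None,
        plan=problem._plan,
    )
    failures = int(failed.sum())
    if failures:
        logger.warning(
            "objective: solver failed at rows %s", np.flatnonzero(failed).tolist()
        )
        X = np.where(np.isnan(X), 0.0, X)
        C = np.where(np.isnan(C), 0.0, C)
    preds = cm.predict_batch(X, C, T, scalars)
    preds[failed] = penalty
    return preds, failures


def objective(problem: FitProblem, parameter_values: dict[str, float]) -> float:
    """Mean squared error between replicate means and predictions."""
    values = problem.full_values(parameter_values)
    preds, _ = predict_dataset(problem, values)
    resid = preds - problem.dataset.replicate_means
    return float(np.mean(resid**2))


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    mse: float
    rmse: float
    per_point: pd.DataFrame
    convergence: dict
    success: bool

    def __repr__(self):
        est = ", ".join(f"{k}={v:.4g}" for k, v in self.estimates.items())
        return f"FitResult({est}, rmse={self.rmse:.4g}, success={self.success})"


def default_initial_guesses(
    model: EquilibriumModel,
    dataset: TitrationDataset,
    free_names,
    dimensionless: tuple[str, ...] = (),
) -> dict[str, float]:
    """Heuristic starting values: geometric mean of the titrate range for
    constants, 1 for declared dimensionless parameters, the largest
    replicate mean for data-function scalars.  Always overridable."""
    geo = math.sqrt(
        float(dataset.concentrations[0]) * float(dataset.concentrations[-1])
    )
    top = float(np.max(np.abs(dataset.replicate_means))) or 1.0
    scalars = set(model.data_function.scalars) if model.data_function else set()
    guesses = {}
    for name in free_names:
        if name in dimensionless:
            guesses[name] = 1.0
        elif name in scalars:
            guesses[name] = top
        else:
            guesses[name] = geo
    return guesses


def fit(
    problem: FitProblem,
    log_transform: bool = True,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    max_nfev: int | None = None,
) -> FitResult:
    """Trust-region-reflective least squares on the replicate-averaged
    residuals; parameters are optimised as log10 values by default.

    Deterministic given data, guesses and tolerances.  On
    non-convergence the best iterate is still returned, flagged via
    ``success``/``convergence``.
    """
    names = list(problem.free_parameters)
    x0 = np.array([problem.free_parameters[n] for n in names])
    means = problem.dataset.replicate_means

    def to_internal(v):
        return np.log10(v) if log_transform else v

    def from_internal(z):
        return 10.0**z if log_transform else z

    lo = np.full(len(names), -np.inf if log_transform else 0.0)
    hi = np.full(len(names), np.inf)
    for k, n in enumerate(names):
        if n in problem.bounds:
            bl, bh = problem.bounds[n]
            lo[k] = to_internal(bl) if bl > 0 or log_transform is False else -np.inf
            hi[k] = to_internal(bh) if np.isfinite(bh) else np.inf

    problem._warm_cache.clear()  # fixed starting state: deterministic fit

    def residuals(z):
        vals = dict(zip(names, from_internal(z)))
        preds, _ = predict_dataset(problem, problem.full_values(vals), warm=True)
        # clip so a wild iterate cannot overflow the cost
        return np.clip(preds - means, -1e30, 1e30)

    res = least_squares(
        residuals,
        to_internal(x0),
        bounds=(lo, hi),
        method="trf",
        xtol=xtol,
        ftol=ftol,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    estimates = dict(zip(names, from_internal(res.x)))
    values = problem.full_values(estimates)
    preds, failures = predict_dataset(problem, values)
    mse = float(np.mean((preds - means) ** 2))
    ds = problem.dataset
    per_point = pd.DataFrame(
        {
            ds.titrate: ds.concentrations,
            "observed_mean": means,
            "predicted": preds,
            "n_replicates": [int(np.sum(np.isfinite(o))) for o in ds.observations],
        }
    )
    success = bool(res.success) and failures == 0
    if not success:
        logger.warning(
            "fit did not fully converge (status=%s, solver failures=%d)",
            res.status, failures,
        )
    return FitResult(
        estimates=estimates,
        mse=mse,
        rmse=math.sqrt(mse),
        per_point=per_point,
        convergence={
            "nfev": int(res.nfev),
            "status": int(res.status),
            "message": res.message,
            "cost": float(res.cost),
            "solver_failures": failures,
            "log_transform": log_transform,
        },
        success=success,
    )
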