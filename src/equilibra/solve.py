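"""Numerical solution of the mass-balance equations.

The unknowns are the free component concentrations.  Because every
complex expression is a monomial ``g(parameters) * prod(x_i ** n_i)`` in
the free concentrations ``x_i`` (a direct consequence of mass action),
the model compiles to a stoichiometry matrix plus one coefficient
function per complex, and the balances are solved for ``u_i = ln x_i``:
log-space enforces positivity and spans the fM-mM range the models need.

A fast root stage (Powell hybrid with analytic Jacobian) runs first and
is polished by plain Newton steps; a trust-region least-squares stage is
the robust fallback when no physical equilibrium is found directly.  A
mass-action ODE relaxation (`kinetic_oracle`) is provided purely as an
independent cross-check for testing, never as the production path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, root

from .model import EquilibriumModel
from .reactions import ReactionSystem

__all__ = [
    "Condition",
    "SystemState",
    "SolverFailure",
    "CompiledModel",
    "compile_model",
    "solve_equilibrium",
    "solve_titration",
    "kinetic_oracle",
]

logger = logging.getLogger(__name__)

#: default relative tolerance on each mass balance for an accepted state
BALANCE_RTOL = 1e-8
#: target of the root stage before escalation (relative residual)
ROOT_STAGE_RTOL = 1e-12

_FLOOR = 1e-30  # absolute concentration floor used only in convergence tests


class SolverFailure(RuntimeError):
    """Both solver stages failed to reach the balance tolerance."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class Condition:
    """Total concentrations of every component plus parameter values,
    all in one consistent concentration unit (molar recommended)."""

    totals: dict[str, float]
    parameter_values: dict[str, float]


@dataclass(frozen=True)
class SystemState:
    """All species concentrations at one solved equilibrium."""

    free: dict[str, float]
    complexes: dict[str, float]
    totals: dict[str, float]
    residuals: dict[str, float]
    escalated: bool = False

    @property
    def species(self) -> dict[str, float]:
        return {**self.free, **self.complexes}


def _monomial_parts(expr: sympy.Expr, comp_syms):
    """Split a complex expression into (coefficient over parameters,
    integer exponent per component)."""
    coeff, mono = expr.as_independent(*comp_syms, as_Add=False)
    powers = sympy.Pow(mono, 1).as_powers_dict()
    exps = []
    for s in comp_syms:
        e = powers.get(s, 0)
        e = int(e)
        exps.append(e)
    residue = mono / sympy.Mul(*[s**e for s, e in zip(comp_syms, exps)])
    if sympy.simplify(residue - 1) != 0:
        raise ValueError(
            f"complex expression is not a monomial in components: {expr}"
        )
    return coeff, exps


class CompiledModel:
    """An :class:`EquilibriumModel` compiled to numpy-evaluable form."""

    def __init__(self, model: EquilibriumModel):
        self.model = model
        sys_ = model.system
        self.components: tuple[str, ...] = sys_.components
        self.complexes: tuple[str, ...] = sys_.complexes
        self.param_names: tuple[str, ...] = tuple(sys_.parameters)
        comp_syms = [sympy.Symbol(c, positive=True) for c in self.components]
        par_syms = [sympy.Symbol(p, positive=True) for p in self.param_names]

        coeffs, rows = [], []
        for cx in self.complexes:
            coeff, exps = _monomial_parts(model.complex_exprs[cx], comp_syms)
            coeffs.append(coeff)
            rows.append(exps)
        # N[j, i]: count of component i in complex j (monomial exponents
        # coincide with the recursive stoichiometry)
        self.N = np.asarray(rows, dtype=float).reshape(len(self.complexes), len(self.components))
        self._coeff_fn = sympy.lambdify(par_syms, coeffs, modules="numpy")
        self._const_fn = sympy.lambdify(
            par_syms, [r.constant for r in sys_.reactions], modules="numpy"
        )

        df = model.data_function
        if df is not None:
            self._df_args = (
                list(self.components)
                + list(self.complexes)
                + [f"{c}_tot" for c in self.components]
                + list(df.scalars)
            )
            self._df_fn = sympy.lambdify(
                [sympy.Symbol(a, positive=True) for a in self._df_args],
                df.expression,
                modules="numpy",
            )
        else:
            self._df_fn = None

    # -- parameter plumbing -------------------------------------------------
    def param_vector(self, values: dict[str, float]) -> np.ndarray:
        try:
            return np.array([float(values[p]) for p in self.param_names])
        except KeyError as exc:
            raise ValueError(f"missing parameter value for {exc.args[0]!r}") from exc

    def coefficients(self, pvec: np.ndarray) -> np.ndarray:
        g = np.asarray(self._coeff_fn(*pvec), dtype=float)
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise ValueError(
                "non-positive or non-finite complex coefficient; check that "
                "all dissociation-constant expressions are positive at the "
                f"given parameter values ({dict(zip(self.param_names, pvec))})"
            )
        return g

    def constants(self, values: dict[str, float]) -> np.ndarray:
        """Numeric dissociation constant of each reaction, in input order."""
        return np.asarray(self._const_fn(*self.param_vector(values)), dtype=float)

    def totals_vector(self, totals: dict[str, float]) -> np.ndarray:
        try:
            t = np.array([float(totals[c]) for c in self.components])
        except KeyError as exc:
            raise ValueError(f"missing total for component {exc.args[0]!r}") from exc
        if np.any(t < 0):
            raise ValueError("total concentrations must be >= 0")
        return t

    # -- core solve ---------------------------------------------------------
    def solve_vectors(
        self,
        totals: np.ndarray,
        pvec: np.ndarray,
        u0: np.ndarray | None = None,
        rtol: float = BALANCE_RTOL,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
        """Solve one condition; returns (free, complex concs, relative
        residuals, escalated flag).  ``u0`` warm-starts the active
        log-unknowns."""
        g = self.coefficients(pvec)
        act = np.flatnonzero(totals > 0)
        # a complex dies with any of its zero-total components
        alive = np.flatnonzero((self.N[:, totals == 0] == 0).all(axis=1))
        x_full = np.zeros(len(self.components))
        c_full = np.zeros(len(self.complexes))
        if act.size == 0:
            res = np.zeros(len(self.components))
            return x_full, c_full, res, False

        Nr = self.N[np.ix_(alive, act)]
        lg = np.log(g[alive])
        tot = totals[act]

        # the exponent clamp keeps far-off iterates finite (exp <= ~4e260),
        # so no overflow can occur anywhere downstream
        NrT = Nr.T.copy()

        def F(u):
            x = np.exp(np.minimum(u, 600.0))
            c = np.exp(np.minimum(lg + Nr @ u, 600.0))
            return (tot - x - NrT @ c) / tot

        def J(u):
            x = np.exp(np.minimum(u, 600.0))
            c = np.exp(np.minimum(lg + Nr @ u, 600.0))
            M = np.diag(x) + NrT @ (c[:, None] * Nr)
            return -M / tot[:, None]

        def newton_solve(u, max_iter=80):
            """Damped Newton with backtracking; the workhorse stage."""
            f = F(u)
            r = abs(f).max()
            best_u, best_r = u, r
            for _ in range(max_iter):
                if r < 1e-15:
                    return u
                try:
                    du = np.linalg.solve(J(u), f)
                except np.linalg.LinAlgError:
                    break
                du = np.clip(du, -50.0, 50.0)
                step = 1.0
                for _bt in range(12):
                    u_new = u - step * du
                    f_new = F(u_new)
                    r_new = abs(f_new).max()
                    if r_new < r:
                        break
                    step *= 0.5
                else:
                    break
                u, f, r = u_new, f_new, r_new
                if r < best_r:
                    best_u, best_r = u, r
            return best_u

        u_cold = np.log(tot)  # fully dissociated start: always feasible
        warm = (
            u0 is not None and u0.shape == tot.shape and np.all(np.isfinite(u0))
        )
        escalated = False

        u = newton_solve(u0 if warm else u_cold)
        if warm and np.max(np.abs(F(u))) > ROOT_STAGE_RTOL:
            u_retry = newton_solve(u_cold)  # warm start led astray: cold retry
            if np.max(np.abs(F(u_retry))) < np.max(np.abs(F(u))):
                u = u_retry
        if np.max(np.abs(F(u))) > ROOT_STAGE_RTOL:
            # second stage: Powell hybrid from the best point so far
            sol = root(F, u, jac=J, method="hybr", options={"xtol": 1e-14})
            u_h = newton_solve(sol.x, max_iter=10)
            if np.max(np.abs(F(u_h))) < np.max(np.abs(F(u))):
                u = u_h
        if np.max(np.abs(F(u))) > ROOT_STAGE_RTOL:
            # escalation: robust trust-region least squares from scratch
            escalated = True
            best = u if np.max(np.abs(F(u))) < np.max(np.abs(F(u_cold))) else u_cold
            ls = least_squares(
                F, best, jac=J, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=None, max_nfev=2000,
            )
            u = newton_solve(ls.x, max_iter=10)
        resid = np.abs(F(u))
        if np.max(resid) > rtol:
            res_full = np.zeros(len(self.components))
            res_full[act] = resid
            raise SolverFailure(
                "no physical equilibrium found: max relative balance residual "
                f"{np.max(resid):.3e} > {rtol:.1e}",
                residuals=dict(zip(self.components, res_full)),
            )
        x_full[act] = np.exp(u)
        if alive.size:
            c_full[alive] = np.exp(lg + Nr @ u)
        res_full = np.zeros(len(self.components))
        res_full[act] = resid
        return x_full, c_full, res_full, escalated

    def batch_plan(self, totals_matrix: np.ndarray) -> list[dict]:
        """Group condition rows by their zero-total pattern and
        precompute the per-group arrays ``solve_batch`` needs; reuse the
        plan across repeated solves of the same conditions (fitting)."""
        T = np.asarray(totals_matrix, dtype=float)
        patterns: dict[tuple, list[int]] = {}
        for i in range(T.shape[0]):
            patterns.setdefault(tuple(T[i] > 0), []).append(i)
        plan = []
        for pattern, rows in patterns.items():
            act = np.flatnonzero(np.array(pattern))
            if act.size == 0:
                continue
            alive = np.flatnonzero(
                (self.N[:, ~np.array(pattern)] == 0).all(axis=1)
            )
            rows = np.array(rows)
            Nr = self.N[np.ix_(alive, act)]
            plan.append({
                "pattern": pattern,
                "rows": rows,
                "act": act,
                "alive": alive,
                "Nr": Nr,
                "NrT": Nr.T.copy(),
                "tot": T[np.ix_(rows, act)],
                "eye": np.eye(act.size),
            })
        return plan

    def solve_batch(
        self,
        totals_matrix: np.ndarray,
        pvec: np.ndarray,
        rtol: float = BALANCE_RTOL,
        max_iter: int = 120,
        warm_cache: dict | None = None,
        plan: list[dict] | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Solve many conditions at once with a vectorised damped Newton.

        ``totals_matrix`` has one row per condition.  Rows are grouped by
        their zero-total pattern; rows the batched iteration cannot close
        fall back to the scalar two-stage path.  Returns free and complex
        concentration matrices plus a boolean failure mask (a failed row
        is all-NaN rather than raising, so a fit objective can penalise
        it and continue).
        """
        T = np.asarray(totals_matrix, dtype=float)
        n_pts = T.shape[0]
        g = self.coefficients(pvec)
        X = np.zeros((n_pts, len(self.components)))
        C = np.zeros((n_pts, len(self.complexes)))
        failed = np.zeros(n_pts, dtype=bool)
        if plan is None:
            plan = self.batch_plan(T)
        for entry in plan:
            pattern = entry["pattern"]
            rows, act, alive = entry["rows"], entry["act"], entry["alive"]
            Nr, NrT, tot, eye = (
                entry["Nr"], entry["NrT"], entry["tot"], entry["eye"]
            )
            lg = np.log(g[alive])
            U = np.log(tot)  # fully dissociated start per row
            cached = warm_cache.get(pattern) if warm_cache is not None else None
            if cached is not None and cached.shape == U.shape and np.all(
                np.isfinite(cached)
            ):
                U = cached.copy()

            def FB(U):
                Xm = np.exp(np.minimum(U, 600.0))
                Cm = np.exp(np.minimum(lg + U @ NrT, 600.0))
                return (tot - Xm - Cm @ Nr) / tot, Xm, Cm
            Fm, Xm, Cm = FB(U)
            res = np.abs(Fm).max(axis=1)
            for _ in range(max_iter):
                live = res > 1e-15
                if not live.any():
                    break
                # batched Jacobian wrt u for the still-unconverged rows
                Ul, totl, Fl = U[live], tot[live], Fm[live]
                Xl, Cl = Xm[live], Cm[live]
                M = Xl[:, None, :] * eye + np.einsum(
                    "ji,nj,jl->nil", Nr, Cl, Nr
                )
                Jb = -M / totl[:, :, None]
                try:
                    du = np.linalg.solve(Jb, Fl[:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    break
                du = np.clip(du, -50.0, 50.0)
                step = np.ones(len(du))
                improved = np.zeros(len(du), dtype=bool)
                U_new = Ul.copy()
                r_old = res[live]
                r_new = r_old.copy()
                for _bt in range(12):
                    trial = Ul - step[:, None] * du
                    Xl2 = np.exp(np.minimum(trial, 600.0))
                    Cl2 = np.exp(np.minimum(lg + trial @ NrT, 600.0))
                    Ft = (totl - Xl2 - Cl2 @ Nr) / totl
                    rt = np.abs(Ft).max(axis=1)
                    better = (~improved) & (rt < r_old)
                    U_new[better] = trial[better]
                    r_new[better] = rt[better]
                    improved |= better
                    if improved.all():
                        break
                    step[~improved] *= 0.5
                if not improved.any():
                    break
                live_idx = np.flatnonzero(live)
                U[live_idx[improved]] = U_new[improved]
                Fm, Xm, Cm = FB(U)
                res = np.abs(Fm).max(axis=1)
            if warm_cache is not None:
                warm_cache[pattern] = U.copy()
            # scalar fallback for any row still above tolerance, warm from
            # the batched iterate first
            for k, row in enumerate(rows):
                if res[k] <= rtol:
                    X[row, act] = np.exp(U[k])
                    C[row, alive] = np.exp(lg + Nr @ U[k])
                else:
                    try:
                        x, c, _r, _e = self.solve_vectors(
                            T[row], pvec, u0=U[k], rtol=rtol
                        )
                        X[row], C[row] = x, c
                    except SolverFailure:
                        failed[row] = True
                        X[row], C[row] = np.nan, np.nan
        return X, C, failed

    def solve(
        self,
        condition: Condition,
        u0: np.ndarray | None = None,
        rtol: float = BALANCE_RTOL,
    ) -> SystemState:
        totals = self.totals_vector(condition.totals)
        pvec = self.param_vector(condition.parameter_values)
        if np.any(pvec <= 0) or not np.all(np.isfinite(pvec)):
            raise ValueError("equilibrium constants/parameters must be positive")
        x, c, res, esc = self.solve_vectors(totals, pvec, u0=u0, rtol=rtol)
        if esc:
            logger.info("solver escalated to least-squares stage")
        return SystemState(
            free=dict(zip(self.components, x)),
            complexes=dict(zip(self.complexes, c)),
            totals=dict(zip(self.components, totals)),
            residuals=dict(zip(self.components, res)),
            escalated=esc,
        )

    # -- observable ---------------------------------------------------------
    def predict(
        self,
        x: np.ndarray,
        c: np.ndarray,
        totals: np.ndarray,
        scalar_values: dict[str, float],
    ) -> float:
        if self._df_fn is None:
            raise ValueError("model has no data function")
        df = self.model.data_function
        args = list(x) + list(c) + list(totals) + [
            float(scalar_values[s]) for s in df.scalars
        ]
        return float(self._df_fn(*args))

    def predict_batch(
        self,
        X: np.ndarray,
        C: np.ndarray,
        T: np.ndarray,
        scalar_values: dict[str, float],
    ) -> np.ndarray:
        """Vectorised data-function evaluation, one value per row."""
        if self._df_fn is None:
            raise ValueError("model has no data function")
        df = self.model.data_function
        args = (
            [X[:, i] for i in range(X.shape[1])]
            + [C[:, j] for j in range(C.shape[1])]
            + [T[:, i] for i in range(T.shape[1])]
            + [float(scalar_values[s]) for s in df.scalars]
        )
        out = self._df_fn(*args)
        return np.broadcast_to(np.asarray(out, dtype=float), (X.shape[0],)).copy()

    def predict_state(self, state: SystemState, scalar_values: dict[str, float]) -> float:
        x = np.array([state.free[cp] for cp in self.components])
        c = np.array([state.complexes[cx] for cx in self.complexes])
        t = np.array([state.totals[cp] for cp in self.components])
        return self.predict(x, c, t, scalar_values)


_COMPILE_CACHE: dict[int, tuple[EquilibriumModel, CompiledModel]] = {}


def compile_model(model: EquilibriumModel) -> CompiledModel:
    """Compile ``model``, reusing a previous compilation of the same
    model object (lambdification is by far the dominant setup cost)."""
    hit = _COMPILE_CACHE.get(id(model))
    if hit is not None and hit[0] is model:
        return hit[1]
    cm = CompiledModel(model)
    if len(_COMPILE_CACHE) > 256:
        _COMPILE_CACHE.clear()
    _COMPILE_CACHE[id(model)] = (model, cm)
    return cm


def solve_equilibrium(
    model: EquilibriumModel | CompiledModel,
    condition: Condition,
    rtol: float = BALANCE_RTOL,
) -> SystemState:
    """Solve the n mass balances for the free component concentrations.

    Deterministic: fixed fully-dissociated initial point, no randomness.
    Raises :class:`SolverFailure` with the best residuals when both the
    root and least-squares stages miss the tolerance.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    return cm.solve(condition, rtol=rtol)


def solve_titration(
    model: EquilibriumModel | CompiledModel,
    conditions: list[Condition],
    warm_start: bool = True,
    rtol: float = BALANCE_RTOL,
    strict: bool = True,
) -> list[SystemState | None]:
    """Solve an ordered series of conditions, warm-starting each solve
    from the previous solution.  With ``strict=False`` a per-point
    failure is logged (with its index) and returned as ``None`` while the
    remaining points are still attempted."""
    if not conditions:
        raise ValueError("empty condition list")
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    states: list[SystemState | None] = []
    u_prev = None
    act_prev = None
    for i, cond in enumerate(conditions):
        totals = cm.totals_vector(cond.totals)
        act = tuple(np.flatnonzero(totals > 0))
        u0 = u_prev if (warm_start and act_prev == act) else None
        try:
            st = cm.solve(cond, u0=u0, rtol=rtol)
        except (SolverFailure, ValueError) as exc:
            if strict:
                raise SolverFailure(f"titration point {i}: {exc}") from exc
            logger.warning("titration point %d failed: %s", i, exc)
            states.append(None)
            u_prev, act_prev = None, None
            continue
        states.append(st)
        xs = np.array([st.free[c] for c in cm.components])[list(act)]
        with np.errstate(divide="ignore"):
            u_prev = np.log(np.maximum(xs, _FLOOR))
        act_prev = act
    return states


class OracleNonConvergence(RuntimeError):
    pass


def kinetic_oracle(
    model: EquilibriumModel | CompiledModel,
    condition: Condition,
    horizon: float = 1e18,
) -> SystemState:
    """Steady state of the mass-action kinetics, as an independent test
    oracle: kon = 1 and koff = K for each reaction (detailed balance), so
    the ODE relaxes to the same equilibrium the algebraic solver finds.

    Integration proceeds over geometrically growing windows until the
    projected relative concentration change over the elapsed time falls
    below 1e-10 for every species; exceeding ``horizon`` raises
    :class:`OracleNonConvergence`.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    sys_ = cm.model.system
    names = list(cm.components) + list(cm.complexes)
    idx = {n: i for i, n in enumerate(names)}
    K = cm.constants(condition.parameter_values)
    rxns = [
        ([idx[r] for r in rxn.reactants], idx[rxn.product], K[k])
        for k, rxn in enumerate(sys_.reactions)
    ]
    totals = cm.totals_vector(condition.totals)
    y0 = np.concatenate([totals, np.zeros(len(cm.complexes))])
    scale = max(totals.max(), _FLOOR)

    def rhs(t, y):
        dy = np.zeros_like(y)
        for reac, prod, kd in rxns:
            fwd = 1.0
            for i in reac:
                fwd *= y[i]
            rate = fwd - kd * y[prod]
            for i in reac:
                dy[i] -= rate
            dy[prod] += rate
        return dy

    t0, t1 = 0.0, 1.0 / max(K.max(), 1.0)
    y = y0
    while t1 <= horizon:
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA",
            rtol=1e-12, atol=scale * 1e-16, dense_output=False,
        )
        if not sol.success:
            raise OracleNonConvergence(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        dy = rhs(t1, y)
        rel_rate = np.max(np.abs(dy) / np.maximum(np.abs(y), scale * 1e-12))
        if rel_rate * t1 < 1e-10:
            break
        t0, t1 = t1, t1 * 10.0
    else:
        raise OracleNonConvergence(
            f"no steady state within horizon {horizon:g} time units"
        )
    y = np.maximum(y, 0.0)
    free = dict(zip(cm.components, y[: len(cm.components)]))
    cx = dict(zip(cm.complexes, y[len(cm.components):]))
    res = {}
    for i, comp in enumerate(cm.components):
        bound = sum(
            cm.N[j, i] * y[len(cm.components) + j] for j in range(len(cm.complexes))
        )
        tot = totals[i]
        res[comp] = abs(tot - free[comp] - bound) / max(tot, _FLOOR)
    return SystemState(
        free=free, complexes=cx,
        totals=dict(zip(cm.components, totals)), residuals=res,
    )
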