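import numpy as np
import pytest

from equilibra.analysis import (
    bootstrap_ci,
    concentration_profiles,
    error_landscape,
    model_plot,
    sensitivity,
)
from equilibra.fitting import FitProblem, fit, objective
from equilibra.synthetic import (
    RAPPID_BOUNDS,
    make_synthetic,
    ppi_spec,
    rappid_model,
    rappid_spec,
    ternary_spec,
)

ANISO_FIXED = {"baseline": 60.0, "amplitude": 120.0}
HOOK_PARAMS = {
    "KdN": 2.5e-6, "KdA": 10e-9, "KdB": 15e-9, "EM": 100e-6, "Scaling": 1.0,
}


@pytest.fixture(scope="module")
def ppi_fit():
    spec = ppi_spec(noise=0.01, noise_relative=True, seed=21)
    dataset, _ = make_synthetic(spec)
    problem = FitProblem(
        model=spec.model, dataset=dataset,
        free_parameters={"Kd1": 1e-5}, fixed_parameters=dict(ANISO_FIXED),
    )
    return problem, fit(problem)


@pytest.fixture(scope="module")
def ternary_fit():
    spec = ternary_spec(noise=0.01, noise_relative=True, seed=22)
    dataset, _ = make_synthetic(spec)
    problem = FitProblem(
        model=spec.model, dataset=dataset,
        free_parameters={"alpha": 500.0, "Kd2": 1e-3},
        fixed_parameters={"Kd1": 4.05e-6, **ANISO_FIXED},
    )
    return problem, fit(problem)


class TestModelPlot:
    def test_noiseless_predictions_equal_observations(self):
        spec = ppi_spec(noise=0.0)
        dataset, _ = make_synthetic(spec)
        problem = FitProblem(
            model=spec.model, dataset=dataset,
            free_parameters={"Kd1": 1e-5}, fixed_parameters=dict(ANISO_FIXED),
        )
        result = fit(problem)
        mp = model_plot(problem, result)
        assert np.allclose(mp.points.observed_mean, mp.points.predicted, rtol=1e-6)

    def test_per_point_prediction_matches_objective_path(self, ppi_fit):
        problem, result = ppi_fit
        mp = model_plot(problem, result)
        merged = mp.points.sort_values("R")
        assert np.allclose(
            merged.predicted.to_numpy(),
            result.per_point.predicted.to_numpy(),
        )

    def test_dense_curve_spans_data(self, ppi_fit):
        problem, result = ppi_fit
        mp = model_plot(problem, result, n_curve=150)
        assert len(mp.curve) >= 100
        ds = problem.dataset
        assert mp.curve.R.min() == pytest.approx(ds.concentrations.min())
        assert mp.curve.R.max() == pytest.approx(ds.concentrations.max())


class TestConcentrationProfiles:
    def test_hook_effect_single_interior_maximum(self):
        """Sandwich assay: the active-complex profile rises then falls as
        excess analyte saturates each antibody separately."""
        prof = concentration_profiles(
            rappid_model(), HOOK_PARAMS, {"A": 1e-9, "B": 1e-9},
            "T", (1e-14, 1e-6), n_points=60,
        )
        y = prof[prof.species == "ABTa"].concentration.to_numpy()
        i = int(np.argmax(y))
        assert 0 < i < len(y) - 1
        d = np.diff(y)
        assert np.all(d[:i] > 0) and np.all(d[i:] < 0)

    def test_conservation_along_titration(self, ppi_fit):
        problem, result = ppi_fit
        values = problem.full_values(result.estimates)
        prof = concentration_profiles(
            problem.model, values, {"P": 1e-8}, "R", (1e-8, 1e-3), n_points=25,
        )
        for conc, grp in prof.groupby("R"):
            by = dict(zip(grp.species, grp.concentration))
            assert by["R"] + by["RP"] == pytest.approx(conc, rel=1e-7)
            assert by["P"] + by["RP"] == pytest.approx(1e-8, rel=1e-7)


class TestErrorLandscape:
    def test_centre_cell_equals_fit_mse(self, ternary_fit):
        problem, result = ternary_fit
        grid = error_landscape(problem, result, "Kd2", "alpha",
                               span=3.0, resolution=5)
        centre = grid.mse[2, 2]
        assert centre == pytest.approx(result.mse, rel=1e-10)

    def test_single_cell_grid(self, ternary_fit):
        problem, result = ternary_fit
        grid = error_landscape(problem, result, "Kd2", "alpha", resolution=1)
        assert grid.mse.shape == (1, 1)
        assert grid.mse[0, 0] == pytest.approx(result.mse, rel=1e-10)

    def test_landscape_evaluation_matches_direct_objective(self, ternary_fit):
        problem, result = ternary_fit
        grid = error_landscape(problem, result, "Kd2", "alpha",
                               span=2.0, resolution=3)
        direct = objective(problem, {
            "Kd2": float(grid.x_values[0]), "alpha": float(grid.y_values[0]),
        })
        assert grid.mse[0, 0] == direct

    def test_minimum_near_centre_and_valley_restarts(self, ternary_fit):
        """The fitted point is the grid minimum, and refits started from
        valley cells return the same estimates."""
        problem, result = ternary_fit
        grid = error_landscape(problem, result, "Kd2", "alpha",
                               span=10.0, resolution=7)
        assert np.nanmin(grid.mse) >= result.mse * (1 - 1e-9)
        flat = np.argsort(grid.mse, axis=None)[:5]
        for pos in flat:
            iy, ix = np.unravel_index(pos, grid.mse.shape)
            restart = FitProblem(
                model=problem.model, dataset=problem.dataset,
                free_parameters={"Kd2": float(grid.x_values[ix]),
                                 "alpha": float(grid.y_values[iy])},
                fixed_parameters=dict(problem.fixed_parameters),
            )
            r2 = fit(restart)
            assert r2.estimates["Kd2"] == pytest.approx(
                result.estimates["Kd2"], rel=0.01)
            assert r2.estimates["alpha"] == pytest.approx(
                result.estimates["alpha"], rel=0.01)

    def test_positive_correlation_of_cooperativity_and_affinity(self, ternary_fit):
        """Along the valley, weaker glue binding (larger Kd2) pairs with
        stronger cooperativity (larger alpha)."""
        problem, result = ternary_fit
        grid = error_landscape(problem, result, "Kd2", "alpha",
                               span=5.0, resolution=11)
        best_alpha_idx = np.nanargmin(grid.mse, axis=0)  # per Kd2 column
        slope = np.polyfit(np.log10(grid.x_values),
                           np.log10(grid.y_values[best_alpha_idx]), 1)[0]
        assert slope > 0


class TestBootstrap:
    def test_reproducible_given_seed(self, ppi_fit):
        problem, result = ppi_fit
        a = bootstrap_ci(problem, result, repeats=100, seed=5)
        b = bootstrap_ci(problem, result, repeats=100, seed=5)
        assert a.intervals == b.intervals

    def test_interval_ordering_and_level(self, ppi_fit):
        problem, result = ppi_fit
        ci = bootstrap_ci(problem, result, repeats=100, seed=6)
        lo, med, hi = ci.intervals["Kd1"]
        assert lo <= med <= hi
        assert ci.level == 0.95

    def test_zero_noise_degenerate_interval(self):
        spec = ppi_spec(noise=0.0)
        dataset, _ = make_synthetic(spec)
        problem = FitProblem(
            model=spec.model, dataset=dataset,
            free_parameters={"Kd1": 1e-5}, fixed_parameters=dict(ANISO_FIXED),
        )
        result = fit(problem)
        ci = bootstrap_ci(problem, result, repeats=100, seed=7)
        lo, med, hi = ci.intervals["Kd1"]
        assert hi - lo <= 1e-3 * med

    def test_too_few_repeats_rejected(self, ppi_fit):
        problem, result = ppi_fit
        with pytest.raises(ValueError, match="100"):
            bootstrap_ci(problem, result, repeats=10, seed=1)


@pytest.fixture(scope="module")
def rappid_fit():
    spec = rappid_spec(noise=0.01, seed=23)
    dataset, _ = make_synthetic(spec)
    problem = FitProblem(
        model=spec.model, dataset=dataset,
        free_parameters={"KdA": 2e-6, "KdB": 5e-9, "Scaling": 1e17},
        fixed_parameters={"KdN": 2.5e-6, "EM": 1e-4},
        bounds=dict(RAPPID_BOUNDS),
    )
    return problem, fit(problem)


class TestSensitivity:
    def test_zero_perturbation_gives_zero(self, rappid_fit):
        problem, result = rappid_fit
        rep = sensitivity(problem, result, perturbation=0.0)
        assert all(v == 0 for v in rep.raw.values())

    def test_ordering_weak_antibody_dominates(self, rappid_fit):
        """The weak-binding antibody arm limits sandwich formation, and
        the fixed complementation parameters dominate the fitted ones."""
        problem, result = rappid_fit
        rep = sensitivity(problem, result, perturbation=0.5)
        assert rep.raw["KdA"] > rep.raw["KdB"]
        fitted_max = max(rep.raw["KdA"], rep.raw["KdB"])
        assert rep.raw["KdN"] > fitted_max
        assert rep.raw["EM"] > fitted_max

    def test_nonnegative_at_optimum(self, rappid_fit):
        problem, result = rappid_fit
        rep = sensitivity(problem, result, perturbation=0.5)
        assert all(v >= -1e-6 * abs(rep.reference) for v in rep.raw.values())

    def test_inert_parameter_has_zero_sensitivity(self):
        spec = ppi_spec(noise=0.0)
        dataset, _ = make_synthetic(spec)
        problem = FitProblem(
            model=spec.model, dataset=dataset,
            free_parameters={"Kd1": 1e-5}, fixed_parameters=dict(ANISO_FIXED),
        )
        result = fit(problem)
        rep = sensitivity(problem, result, perturbation=0.5)
        # baseline shifts every prediction, Kd1 moves the curve: both != 0;
        # nothing here is inert, so use a disjoint-system spectator instead
        from equilibra.model import build_model, anisotropy_data_function
        from equilibra.reactions import parse_reactions

        sys_ = parse_reactions("R + P = RP; Kd1\nC + D = CD; Kspec")
        model = build_model(sys_, anisotropy_data_function(sys_, labeled="P"))
        ds2, _ = make_synthetic(ppi_spec(noise=0.0))
        from equilibra.fitting import TitrationDataset

        ds2 = TitrationDataset(
            titrate="R", concentrations=ds2.concentrations,
            observations=ds2.observations,
            fixed_totals={"P": 1e-8, "C": 0.0, "D": 0.0},
        )
        prob2 = FitProblem(
            model=model, dataset=ds2,
            free_parameters={"Kd1": 1e-5},
            fixed_parameters={"Kspec": 1e-6, **ANISO_FIXED},
        )
        r2 = fit(prob2)
        rep2 = sensitivity(prob2, r2, perturbation=0.5)
        assert rep2.raw["Kspec"] == 0.0

    def test_max_species_m_function(self, rappid_fit):
        problem, result = rappid_fit
        rep = sensitivity(problem, result, perturbation=0.5,
                          m_function="max_species", species="ABTa")
        # weakening the weak antibody reduces the peak active complex
        assert rep.raw["KdA"] < 0
        assert rep.raw["Scaling"] == 0  # scaling does not move concentrations

    def test_full_perturbation_rejected(self, rappid_fit):
        problem, result = rappid_fit
        with pytest.raises(ValueError, match="100"):
            sensitivity(problem, result, perturbation=-1.0)
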