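"""Grid + fine search, GLM gains, variance explained, cross-validation."""

import numpy as np
import pytest

import stprf
from stprf import models, solver, synth
from stprf.exceptions import ParameterError, ShapeError
from stprf.solver import (
    FineSearchSpec,
    GridSpec,
    estimate_betas,
    threefold_runs,
    variance_explained,
)


class TestVarianceExplained:
    def test_hand_computed_cases(self):
        assert variance_explained([1.0, 2.0], [1.0, 2.0]) == 1.0
        assert variance_explained([0.0, 0.0], [1.0, 2.0]) == 0.0
        # residual 1, raw sum of squares 5
        assert variance_explained([1.0, 1.0], [1.0, 2.0]) == pytest.approx(0.8)

    def test_zero_data_flagged(self):
        assert np.isnan(variance_explained([1.0], [0.0]))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            variance_explained([1.0, 2.0], [1.0])

    def test_not_mean_centered(self):
        # a constant prediction of the data mean does NOT give R^2 = 0
        data = np.array([1.0, 3.0])
        assert variance_explained([2.0, 2.0], data) == pytest.approx(0.8)


class TestEstimateBetas:
    def test_single_channel_scaling(self):
        rng = np.random.default_rng(0)
        sus = rng.random(100)
        tran = rng.random(100)
        X = np.stack([sus, tran])
        b = estimate_betas(X, 2.0 * sus)
        assert b[0] == pytest.approx(2.0, abs=1e-9)
        assert b[1] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_sum_recovers_unit_weights(self):
        X = np.zeros((2, 10))
        X[0, :5] = 1.0
        X[1, 5:] = 1.0
        b = estimate_betas(X, X.sum(axis=0))
        assert np.allclose(b, [1.0, 1.0])

    def test_zero_data_zero_betas(self):
        X = np.stack([np.ones(10), np.arange(10.0)])
        assert np.allclose(estimate_betas(X, np.zeros(10)), 0.0)

    def test_collinear_falls_back_with_warning(self):
        x = np.arange(10.0)
        X = np.stack([x, 2 * x])
        with pytest.warns(UserWarning, match="collinear"):
            b = estimate_betas(X, x)
        assert np.isfinite(b).all()

    def test_negative_betas_allowed(self):
        x = np.arange(10.0)
        b = estimate_betas(x[None], -3.0 * x)
        assert b[0] == pytest.approx(-3.0)


class TestGridSpec:
    def test_published_grid_materializes_exactly(self):
        g = GridSpec()
        s = g.sigma_values()
        assert len(s) == 96
        assert s[0] == pytest.approx(0.1) and s[-1] == pytest.approx(12.0)
        ratios = s[1:] / s[:-1]
        assert np.allclose(ratios, ratios[0])          # log-linear
        x = g.x_values()
        assert len(x) == 61 and x[0] == -12.0 and x[-1] == 12.0
        assert np.allclose(np.diff(x), 0.4)
        assert g.n_grid == (0.25, 0.5, 0.75, 1.0)
        assert g.cst_tau == 4.93
        assert g.dnst_defaults == (0.05, 0.1, 2.0, 0.1)

    def test_coarse_keeps_ranges(self):
        g = GridSpec.coarse()
        s = g.sigma_values()
        assert s[0] == pytest.approx(0.1) and s[-1] == pytest.approx(12.0)
        x = g.x_values()
        assert x[0] == -12.0 and x[-1] == 12.0


@pytest.fixture(scope="module")
def seq3():
    """Three spatiotemporal runs: enough for grid/fine/cv tests."""
    return stprf.spatiotemporal_sequence(n_runs=3, seed=13)


@pytest.fixture(scope="module")
def tiny_grid():
    return GridSpec(xy_step_deg=4.0, sigma_steps=5)


class TestGridSearch:
    def test_on_node_voxel_wins_its_node(self, seq3, tiny_grid):
        """A noiseless voxel generated exactly at a grid node is scored
        best at that node."""
        x = tiny_grid.x_values()[4]
        sigma = tiny_grid.sigma_values()[3]
        gt = synth.GroundTruthSet(
            "spatial", [models.SpatialParams(x, 0.0, sigma)], None, 1
        )
        bold = synth.synthesize_bold(gt, seq3)[:, 0]
        theta, r2 = solver.grid_search(bold, seq3, "spatial", grid=tiny_grid)
        assert theta[0] == pytest.approx(x)
        assert theta[1] == pytest.approx(0.0)
        assert theta[2] == pytest.approx(sigma)
        assert r2 == pytest.approx(1.0, abs=1e-4)

    def test_cst_grid_enumerates_exponents(self, seq3, tiny_grid):
        eng = solver.build_engine(seq3, "cst", None)
        bank = eng.grid_bank(tiny_grid)
        n_col = bank["theta"][:, 4]
        assert set(np.round(np.unique(n_col), 2)) == {0.25, 0.5, 0.75, 1.0}
        assert np.allclose(bank["theta"][:, 3], 4.93)

    def test_degenerate_voxel_flagged(self, seq3, tiny_grid):
        theta, flags = solver.grid_search(np.zeros(540), seq3, "spatial",
                                          grid=tiny_grid)
        assert theta is None and flags["degenerate_voxel"]


class TestFineSearch:
    def test_off_grid_spatial_voxel_recovered(self, seq3, tiny_grid):
        truth = models.SpatialParams(2.3, -1.7, 0.9)
        gt = synth.GroundTruthSet("spatial", [truth], None, 1)
        bold = synth.synthesize_bold(gt, seq3)[:, 0]
        coarse, r2_grid = solver.grid_search(bold, seq3, "spatial",
                                             grid=tiny_grid)
        res = solver.fine_search(bold, seq3, "spatial", coarse,
                                 spec=FineSearchSpec(seed=0))
        # fine search never degrades the grid solution
        assert res.r2_train >= r2_grid - 1e-9
        assert res.params.x == pytest.approx(2.3, abs=0.02)
        assert res.params.y == pytest.approx(-1.7, abs=0.02)
        assert res.params.sigma == pytest.approx(0.9, abs=0.02)
        assert res.r2_train == pytest.approx(1.0, abs=1e-6)

    def test_solution_respects_bounds(self, seq3, tiny_grid):
        rng = np.random.default_rng(8)
        bold = rng.standard_normal(540)          # pure noise voxel
        coarse, _ = solver.grid_search(bold, seq3, "cst", grid=tiny_grid)
        spec = FineSearchSpec(maxfev=60, polish_maxfev=40, seed=1)
        res = solver.fine_search(bold, seq3, "cst", coarse, spec=spec)
        bounds = spec.bounds("cst", np.asarray(coarse))
        d = models.params_to_dict(res.params)
        for (lo, hi), name in zip(bounds, models.free_param_names("cst")):
            assert lo - 1e-9 <= d[name] <= hi + 1e-9

    def test_tau_at_upper_bound_is_flagged(self, seq3, tiny_grid):
        truth = models.CSTParams(models.SpatialParams(1.0, 1.0, 1.2),
                                 tau=100.0, n_exp=0.6)
        gt = synth.GroundTruthSet("cst", [truth], None, 1)
        bold = synth.synthesize_bold(gt, seq3)[:, 0]
        coarse = np.array([1.0, 1.0, 1.2, 4.93, 0.5])
        res = solver.fine_search(bold, seq3, "cst", coarse,
                                 spec=FineSearchSpec(maxfev=300,
                                                     polish_maxfev=300,
                                                     seed=2))
        d = models.params_to_dict(res.params)
        assert d["tau"] >= 99.0
        assert res.flags.get("tau_at_bound", False)

    def test_low_r2_flagged(self, seq3, tiny_grid):
        rng = np.random.default_rng(9)
        bold = rng.standard_normal(540)
        res = solver.solve_voxels(bold, seq3, "spatial", grid=tiny_grid,
                                  fine=FineSearchSpec(maxfev=60,
                                                      polish_maxfev=40),
                                  seed=0)[0]
        assert res.flags.get("low_r2", False)


class TestCrossValidation:
    def test_threefold_partition_disjoint_and_complete(self):
        folds = threefold_runs(9)
        assert len(folds) == 3
        all_test = sorted(r for _, test in folds for r in test)
        assert all_test == list(range(9))
        for train, test in folds:
            assert not set(train) & set(test)
            assert len(train) == 6 and len(test) == 3

    def test_run_count_must_split(self):
        with pytest.raises(ParameterError):
            threefold_runs(8)

    def test_noiseless_voxel_cv_r2_near_one(self, seq3, tiny_grid):
        gt = synth.GroundTruthSet(
            "spatial", [models.SpatialParams(-3.0, 1.0, 1.1)], None, 1
        )
        bold = synth.synthesize_bold(gt, seq3)
        cv = solver.crossvalidate(bold, seq3, "spatial", grid=tiny_grid,
                                  fine=FineSearchSpec(seed=0), seed=0)
        assert cv[0] == pytest.approx(1.0, abs=1e-3)

    def test_shuffled_prediction_scores_worse(self, seq3):
        gt = synth.GroundTruthSet(
            "spatial", [models.SpatialParams(-3.0, 1.0, 1.1)], None, 1
        )
        bold = synth.synthesize_bold(gt, seq3)[:, 0]
        rng = np.random.default_rng(10)
        shuffled = rng.permutation(bold)
        assert variance_explained(shuffled, bold) < variance_explained(
            bold, bold
        )
        assert variance_explained(shuffled, bold) < 0.5
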