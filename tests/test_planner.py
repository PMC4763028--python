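"""Objective arithmetic, gradients, aperture init and optimizer convergence."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import nnls

import emxplan as ex
from emxplan.dose import DoseDepositionMatrix
from emxplan.phantom import VoxelPhantom
from emxplan.planner import ConfigurationError, structure_rows, _dv_flags


def _toy_problem(n_vox=20, n_blt=5, seed=0, with_oar=False):
    """Small dense instance with a 1D phantom layout for objective tests."""
    rng = np.random.default_rng(seed)
    M = rng.uniform(0, 1, (n_vox, n_blt))
    A = DoseDepositionMatrix(
        matrix=sp.csr_matrix(M),
        voxel_indices=np.arange(n_vox),
        grid_shape=(n_vox, 1, 1),
    )
    body = np.ones((n_vox, 1, 1), dtype=bool)
    ptv = np.zeros_like(body)
    ptv[: n_vox // 2] = True
    structures = {"BODY": body, "PTV": ptv}
    if with_oar:
        oar = np.zeros_like(body)
        oar[n_vox // 2 :] = True
        structures["OAR"] = oar
    ph = VoxelPhantom(
        spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0),
        density=np.ones((n_vox, 1, 1)), structures=structures,
    )
    return A, ph


class TestObjective:
    def test_exact_prescription_is_zero(self):
        """Three target voxels exactly at the prescription: objective 0."""
        A = DoseDepositionMatrix(
            matrix=sp.csr_matrix(np.eye(3)), voxel_indices=np.arange(3),
            grid_shape=(3, 1, 1),
        )
        body = np.ones((3, 1, 1), dtype=bool)
        ph = VoxelPhantom(
            spacing=(1, 1, 1), origin=(0, 0, 0), density=np.ones((3, 1, 1)),
            structures={"BODY": body, "PTV": body.copy()},
        )
        obj = ex.PlanObjective(prescription=50.0)
        val, _ = ex.evaluate_objective(np.array([50.0, 50.0, 50.0]), A, obj, ph)
        assert val == 0.0

    def test_hand_arithmetic(self):
        """Doses (48, 50, 52) against prescription 50 give 4 + 0 + 4 = 8."""
        A = DoseDepositionMatrix(
            matrix=sp.csr_matrix(np.eye(3)), voxel_indices=np.arange(3),
            grid_shape=(3, 1, 1),
        )
        body = np.ones((3, 1, 1), dtype=bool)
        ph = VoxelPhantom(
            spacing=(1, 1, 1), origin=(0, 0, 0), density=np.ones((3, 1, 1)),
            structures={"BODY": body, "PTV": body.copy()},
        )
        obj = ex.PlanObjective(prescription=50.0)
        val, _ = ex.evaluate_objective(np.array([48.0, 50.0, 52.0]), A, obj, ph)
        assert val == pytest.approx(8.0, abs=1e-12)

    def test_r_scales_only_penalty_terms(self):
        A, ph = _toy_problem(with_oar=True)
        obj = ex.PlanObjective(
            prescription=10.0,
            oar_constraints={"OAR": (ex.DVConstraint("OAR", 0.5, 10.0, "upper"),)},
        )
        x = np.full(A.n_beamlets, 3.0)
        f1, fl = ex.evaluate_objective(x, A, obj, ph, r=1.0)
        f2, _ = ex.evaluate_objective(x, A, obj, ph, r=2.0)
        d = A.matrix @ x
        rows = structure_rows(A, ph, "PTV")
        base = float(np.sum((d[rows] - 10.0) ** 2))
        assert f2 - base == pytest.approx(2.0 * (f1 - base), rel=1e-12)

    def test_missing_structure_rejected(self):
        A, ph = _toy_problem()
        obj = ex.PlanObjective(
            prescription=10.0,
            oar_constraints={"CORD": (ex.DVConstraint("CORD", 1.0, 10.0),)},
        )
        with pytest.raises(ConfigurationError):
            ex.evaluate_objective(np.ones(A.n_beamlets), A, obj, ph)

    def test_dv_flags_respect_volume_allowance(self):
        """Upper constraint: the hottest v% may exceed the threshold unflagged."""
        doses = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        c = ex.DVConstraint("S", 5.5, 20.0, "upper")  # 2 voxels allowed above
        flags = _dv_flags(doses, c)
        assert flags.sum() == 3  # doses 6,7,8 flagged; 9,10 permitted
        assert not flags[doses >= 9.0].any()
        c_low = ex.DVConstraint("S", 4.5, 20.0, "lower")
        flags_low = _dv_flags(doses, c_low)
        assert flags_low.sum() == 2  # doses 3,4 flagged; 1,2 permitted as coldest
        assert not flags_low[doses <= 2.0].any()


class TestGradient:
    def test_zero_at_zero_objective(self):
        A = DoseDepositionMatrix(
            matrix=sp.csr_matrix(np.eye(3)), voxel_indices=np.arange(3),
            grid_shape=(3, 1, 1),
        )
        body = np.ones((3, 1, 1), dtype=bool)
        ph = VoxelPhantom(
            spacing=(1, 1, 1), origin=(0, 0, 0), density=np.ones((3, 1, 1)),
            structures={"BODY": body, "PTV": body.copy()},
        )
        obj = ex.PlanObjective(prescription=50.0)
        g = ex.objective_gradient(np.full(3, 50.0), A, obj, ph)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_matches_finite_differences(self):
        A, ph = _toy_problem(with_oar=True, seed=4)
        obj = ex.PlanObjective(
            prescription=10.0,
            target_constraints=(
                ex.DVConstraint("PTV", 9.5, 2.0, "lower"),
                ex.DVConstraint("PTV", 10.8, 2.0, "upper"),
            ),
            oar_constraints={"OAR": (ex.DVConstraint("OAR", 2.0, 15.0, "upper"),)},
        )
        x = np.random.default_rng(1).uniform(1.0, 3.0, A.n_beamlets)
        val, flags = ex.evaluate_objective(x, A, obj, ph)
        g = ex.objective_gradient(x, A, obj, ph, flags=flags)
        from emxplan.planner import _objective_fixed_flags

        eps = 1e-6
        for j in range(A.n_beamlets):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            fd = (
                _objective_fixed_flags(xp, A, obj, ph, obj.r_initial, flags)
                - _objective_fixed_flags(xm, A, obj, ph, obj.r_initial, flags)
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_weight_scaling_scales_penalty_gradient(self):
        A, ph = _toy_problem(with_oar=True, seed=2)
        x = np.full(A.n_beamlets, 2.0)
        c1 = ex.DVConstraint("OAR", 0.5, 10.0, "upper", weight=1.0)
        c3 = ex.DVConstraint("OAR", 0.5, 10.0, "upper", weight=3.0)
        obj1 = ex.PlanObjective(prescription=10.0, oar_constraints={"OAR": (c1,)})
        obj3 = ex.PlanObjective(prescription=10.0, oar_constraints={"OAR": (c3,)})
        g0 = ex.objective_gradient(x, A, ex.PlanObjective(prescription=10.0), ph)
        g1 = ex.objective_gradient(x, A, obj1, ph)
        g3 = ex.objective_gradient(x, A, obj3, ph)
        assert np.allclose(g3 - g0, 3.0 * (g1 - g0), rtol=1e-12)


class TestCiaoInit:
    def test_aperture_is_target_disc(self, slab_phantom, slab_iso, slab_plan):
        _, grids, _ = slab_plan
        x = ex.ciao_init(grids[0], slab_phantom)
        # 4 cm target -> ~pi * 2^2 = 12.6 unit beamlets, discretization slop
        assert abs(x.sum() - np.pi * 4.0) <= 4.0
        assert set(np.unique(x)) <= {0.0, 1.0}

    def test_miss_gives_zero_init(self, slab_phantom, curves):
        ray = ex.Ray(
            source=(50.0, 100.0, 0.0), direction=(0.0, -1.0, 0.0),
            isocenter=(50.0, 0.0, 0.0),
        )
        grid = ex.BeamletGrid(
            beam=ray, energy_MV=6,
            centers_uv=np.array([[0.0, 0.0]]),
            u_axis=np.array([1.0, 0.0, 0.0]), v_axis=np.array([0.0, 0.0, 1.0]),
        )
        with pytest.warns(UserWarning):
            x = ex.ciao_init(grid, slab_phantom)
        assert not x.any()


class TestOptimize:
    def test_monotone_descent_at_fixed_r(self, slab_phantom, slab_plan):
        A, _, init = slab_plan
        obj = ex.PlanObjective.with_default_target_bounds(prescription=50.0)
        _, state = ex.optimize(A, obj, slab_phantom, init,
                               ex.OptimizerControls(max_iterations=120))
        h = np.asarray(state.objective_history)
        rr = np.asarray(state.r_history)
        same_r = rr[:-1] == rr[1:]
        diffs = np.diff(h)[same_r]
        assert np.all(diffs <= 1e-6 * np.abs(h[:-1][same_r]) + 1e-9)
        assert state.stop_reason in ("converged", "max_iter", "time_limit")

    def test_nonnegativity_preserved(self, slab_phantom, slab_plan):
        A, _, init = slab_plan
        obj = ex.PlanObjective.with_default_target_bounds(prescription=50.0)
        x, _ = ex.optimize(A, obj, slab_phantom, init,
                           ex.OptimizerControls(max_iterations=60))
        assert (x >= 0).all()

    def test_matches_qp_oracle_without_dv_constraints(self, slab_phantom, slab_plan):
        """Target-only least squares: optimizer reaches the NNLS optimum."""
        A, _, init = slab_plan
        obj = ex.PlanObjective(prescription=50.0)
        x, state = ex.optimize(A, obj, slab_phantom, init,
                               ex.OptimizerControls(max_iterations=200))
        rows = structure_rows(A, slab_phantom, "PTV")
        _, resid = nnls(A.matrix[rows].toarray(), np.full(len(rows), 50.0))
        assert state.objective_history[-1] <= (resid**2) * 1.01

    def test_already_optimal_init_stays_put(self):
        A = DoseDepositionMatrix(
            matrix=sp.csr_matrix(np.eye(4)), voxel_indices=np.arange(4),
            grid_shape=(4, 1, 1),
        )
        body = np.ones((4, 1, 1), dtype=bool)
        ph = VoxelPhantom(
            spacing=(1, 1, 1), origin=(0, 0, 0), density=np.ones((4, 1, 1)),
            structures={"BODY": body, "PTV": body.copy()},
        )
        obj = ex.PlanObjective(prescription=10.0)
        init = np.full(4, 10.0)
        x, state = ex.optimize(A, obj, ph, init)
        assert np.allclose(x, init)
        assert state.stop_reason == "converged"
        assert state.iterations <= ex.OptimizerControls().tolerance_window + 1

    def test_oar_constraint_reduces_oar_dose(self, slab_phantom, slab_plan):
        """Adding an upper DV constraint on a shell structure lowers its mean
        dose relative to the unconstrained plan."""
        A, _, init = slab_plan
        ph = slab_phantom
        # carve a shell OAR just outside the target
        from emxplan.phantom import VoxelPhantom as VP

        X, Y, Z = ph.voxel_centers()
        r2 = X**2 + (Y + 8.0) ** 2 + Z**2
        shell = (r2 > 2.5**2) & (r2 <= 4.0**2)
        structures = dict(ph.structures)
        structures["SHELL"] = shell & ph.structures["BODY"]
        ph2 = VP(spacing=ph.spacing, origin=ph.origin, density=ph.density,
                 structures=structures)
        free = ex.PlanObjective.with_default_target_bounds(prescription=50.0)
        tight = ex.PlanObjective.with_default_target_bounds(
            prescription=50.0,
            oar_constraints={"SHELL": (ex.DVConstraint("SHELL", 20.0, 5.0, "upper", 5.0),)},
            oar_weights={"SHELL": 5.0},
        )
        ctrl = ex.OptimizerControls(max_iterations=120)
        x_free, _ = ex.optimize(A, free, ph2, init, ctrl)
        x_tight, _ = ex.optimize(A, tight, ph2, init, ctrl)
        d_free = ex.accumulate_dose(A, x_free)[structures["SHELL"]].mean()
        d_tight = ex.accumulate_dose(A, x_tight)[structures["SHELL"]].mean()
        assert d_tight < d_free

    def test_target_coverage_on_five_beam_slab(self, slab_phantom, slab_plan):
        """After D95-normalization, >=95% of target voxels lie within 2% of
        the prescription."""
        A, _, init = slab_plan
        obj = ex.PlanObjective.with_default_target_bounds(prescription=50.0)
        x, _ = ex.optimize(A, obj, slab_phantom, init,
                           ex.OptimizerControls(max_iterations=200))
        dose = ex.accumulate_dose(A, x)
        dose = ex.normalize_plan(dose, slab_phantom.structures["PTV"], 50.0)
        pt = dose[slab_phantom.structures["PTV"]]
        assert np.mean(np.abs(pt - 50.0) <= 1.0) >= 0.95
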