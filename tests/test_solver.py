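"""Solver-level checks that do not require full multistart optimization."""

import numpy as np
import pytest

from quadrugait.morphology import GaitTask
from quadrugait.solver import (
    HomotopyStage,
    SolverConfig,
    _interp_guess,
    _simulate_guess,
    _solve_stage_nlp,
    estimate_mesh_error,
    random_initial_guess,
    validate,
)
from quadrugait.transcription import Transcription


@pytest.fixture
def task(dalmatian):
    return GaitTask.from_speed(dalmatian, U_H_prime=0.39, D_prime=1.21)


class TestConfigValidation:
    def test_positive_tolerances_required(self):
        with pytest.raises(ValueError):
            SolverConfig(mesh_tolerance=0.0)

    def test_at_least_one_start(self):
        with pytest.raises(ValueError):
            SolverConfig(n_starts=0)

    def test_infeasible_task_rejected(self, dalmatian):
        with pytest.raises(ValueError):
            GaitTask(U=1.0, D=-1.0, lB=0.6)


class TestValidation:
    def _sol(self, mesh_error, max_violation):
        class S:  # minimal stand-in carrying the two diagnostics
            pass

        s = S()
        s.mesh_error = mesh_error
        s.max_violation = max_violation
        return s

    def test_within_tolerance_is_valid(self):
        cfg = SolverConfig()
        assert validate(self._sol(5e-5, 1e-6), cfg)

    def test_boundary_is_valid(self):
        cfg = SolverConfig()
        assert validate(self._sol(cfg.mesh_tolerance, cfg.violation_tolerance), cfg)

    def test_complementarity_violation_invalidates(self):
        cfg = SolverConfig()
        assert not validate(self._sol(5e-5, 0.05), cfg)

    def test_mesh_error_invalidates(self):
        cfg = SolverConfig()
        assert not validate(self._sol(2e-4, 1e-6), cfg)


class TestSimulatedGuess:
    def test_interior_defects_vanish_where_unclipped(self, dalmatian, task):
        cfg = SolverConfig()
        tr = Transcription(dalmatian, task, 8)
        g = random_initial_guess(cfg.bounds, task, seed=3)
        X, U = _interp_guess(g, tr.t)
        w0 = tr.pack(X, U, g.feet4)
        lb, ub = tr.variable_bounds(cfg.bounds)
        w = _simulate_guess(tr, w0, lb, ub, cfg.bounds)
        X2, _, _ = tr.unpack(w)
        # force states follow the Euler integration of the force rates
        # wherever the state box did not clip
        dt = tr.t[1] - tr.t[0]
        Uc = tr.unpack(w)[1]
        for P in range(tr.M - 1):
            pred = X2[P, 6:13] + Uc[P, :7] * dt
            flo = np.array([lb[tr.xcol(P + 1, 6 + c)] for c in range(7)])
            fhi = np.array([ub[tr.xcol(P + 1, 6 + c)] for c in range(7)])
            interior = (pred > flo + 1e-12) & (pred < fhi - 1e-12)
            assert X2[P + 1, 6:13][interior] == pytest.approx(pred[interior])


class TestStageSolver:
    def test_stage_reaches_feasibility_from_fixture_like_start(self, dalmatian, task):
        # a cheap, deterministic end-to-end check of the Gauss-Newton /
        # multiplier machinery: coarse mesh, loose stage targets
        cfg = SolverConfig(max_nfev_first=250, max_nfev=80, lsmr_maxiter=80)
        tr = Transcription(dalmatian, task, 8)
        g = random_initial_guess(cfg.bounds, task, seed=5)
        X, U = _interp_guess(g, tr.t)
        lb, ub = tr.variable_bounds(cfg.bounds)
        w0 = _simulate_guess(tr, tr.pack(X, U, g.feet4), lb, ub, cfg.bounds)
        stage = HomotopyStage(eps_work=3e-2, mu0=1e2, tol_feas=5e-3,
                              mesh_iterations=1, max_outer=5)
        res = _solve_stage_nlp(tr, w0, stage, cfg, first_solve=True)
        assert res.constr_violation < 5e-2  # far below the random-guess scale
        assert np.isfinite(res.fun)

    def test_mesh_error_estimator_flags_coarse_meshes(self, dalmatian, task):
        # an unconverged random iterate must never report a tiny mesh error
        cfg = SolverConfig()
        tr = Transcription(dalmatian, task, 8)
        g = random_initial_guess(cfg.bounds, task, seed=1)
        X, U = _interp_guess(g, tr.t)
        w = tr.pack(X, U, g.feet4)
        assert estimate_mesh_error(tr, w) > 1e-2


class TestMultistartContracts:
    def test_duplicate_seeds_give_identical_guesses(self, task):
        cfg = SolverConfig()
        a = random_initial_guess(cfg.bounds, task, seed=cfg.seed + 4)
        b = random_initial_guess(cfg.bounds, task, seed=cfg.seed + 4)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.U, b.U)

    def test_empty_result_status(self, dalmatian, task, monkeypatch):
        # force every solve to come back invalid: multistart must say so
        import quadrugait.solver as S

        def fake_build(tr, w, config, records, **kw):
            sol = S.Solution(
                trajectory=tr.trajectory(w), costs=None, mesh_error=np.inf,
                violations={}, max_violation=np.inf, valid=False,
                converged=False, status=[], **kw)
            return sol

        monkeypatch.setattr(S, "_build_solution", fake_build)
        monkeypatch.setattr(
            S, "_run_stages",
            lambda g, m, t, c, stages, records, cold=True: (
                np.zeros(Transcription(m, t, c.n_segments_initial).n_vars),
                Transcription(m, t, c.n_segments_initial), g))
        cfg = SolverConfig(n_starts=2, polish_top=None)
        out = S.multistart(dalmatian, task, cfg)
        assert out.status == "no-valid-solution"
        assert out.best is None
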