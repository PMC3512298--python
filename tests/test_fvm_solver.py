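import numpy as np
import pytest

from micromyo.cell_models import CellStateArray, get_model
from micromyo.fvm_solver import (Discretization, SimulationState,
                                 assemble_diffusion_system, godunov_step,
                                 pde_step, problem_size, run_simulation,
                                 volumes_for_size_cm)
from micromyo.microstructure import (FaceField, assign_face_conductances,
                                     tile_units)
from micromyo.protocols import StimulusPulse, StimulusSchedule

from oracles import dense_diffusion_matrix, dense_split_step


def uniform_faces(nx, ny, sigma=0.4):
    return FaceField(sigma_x=np.full((nx - 1, ny), sigma),
                     sigma_y=np.full((nx, ny - 1), sigma))


class TestDiscretization:
    def test_substep_count_and_alpha(self):
        d = Discretization()
        assert d.N_o == 100
        assert d.alpha == pytest.approx(d.beta * d.Cm * 1e-5 * 64 / 0.01)

    def test_mismatched_steps_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            Discretization(dt_p=0.01, dt_o=0.0003)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            Discretization(beta=0.0)


class TestAssembly:
    def test_three_volume_chain_is_the_expected_tridiagonal(self, geoms):
        sigma = 0.4
        disc = Discretization()
        a = disc.alpha
        sys_ = assemble_diffusion_system(
            geoms["chain3"], uniform_faces(3, 1, sigma), disc)
        expected = np.array([
            [a + sigma, -sigma, 0.0],
            [-sigma, a + 2 * sigma, -sigma],
            [0.0, -sigma, a + sigma],
        ])
        assert np.allclose(sys_.A.toarray(), expected, rtol=0, atol=1e-15)

    def test_row_sums_equal_alpha_everywhere(self, unit):
        geom = tile_units(unit, 1, 1)
        disc = Discretization()
        sys_ = assemble_diffusion_system(
            geom, assign_face_conductances(geom), disc)
        ones = np.ones(sys_.A.shape[0])
        assert np.allclose(sys_.A @ ones, disc.alpha, rtol=0, atol=1e-12)

    def test_operator_is_symmetric(self, geoms):
        disc = Discretization()
        sys_ = assemble_diffusion_system(
            geoms["oracle20"], assign_face_conductances(geoms["oracle20"]),
            disc)
        assert (sys_.A - sys_.A.T).nnz == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_flux_balance_assembly(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 21, size=2)
        sx = rng.uniform(0, 0.5, size=(nx - 1, ny))
        sy = rng.uniform(0, 0.5, size=(nx, ny - 1))
        sx[rng.random(sx.shape) < 0.3] = 0.0     # sprinkle membrane faces
        sy[rng.random(sy.shape) < 0.3] = 0.0
        from micromyo.microstructure import TissueGeometry
        geom = TissueGeometry(
            cell_label_grid=np.zeros((nx, ny), np.int32),
            x_face_labels=np.zeros((nx - 1, ny), np.int8),
            y_face_labels=np.zeros((nx, ny - 1), np.int8),
        )
        disc = Discretization()
        sys_ = assemble_diffusion_system(geom, FaceField(sx, sy), disc)
        oracle = dense_diffusion_matrix(sx, sy, disc.alpha)
        assert np.allclose(sys_.A.toarray(), oracle, rtol=0, atol=1e-14)

    def test_negative_face_rejected(self, geoms):
        sx = np.full((2, 1), -0.1)
        with pytest.raises(ValueError, match="nonnegative"):
            assemble_diffusion_system(
                geoms["chain3"], FaceField(sx, np.empty((3, 0))),
                Discretization())

    def test_shape_mismatch_rejected(self, geoms):
        with pytest.raises(ValueError, match="shape"):
            assemble_diffusion_system(
                geoms["chain3"], uniform_faces(4, 1), Discretization())


class TestPdeStep:
    def test_constant_field_is_invariant(self, geoms):
        sys_ = assemble_diffusion_system(
            geoms["oracle20"], assign_face_conductances(geoms["oracle20"]),
            Discretization())
        V = np.full((20, 20), -82.42)
        assert np.allclose(pde_step(sys_, V), V, rtol=0, atol=1e-9)

    def test_heterogeneous_patch_matches_dense_direct_solve(self, geoms, rng):
        geom = geoms["het4x4"]
        faces = assign_face_conductances(geom)
        disc = Discretization()
        sys_ = assemble_diffusion_system(geom, faces, disc)
        V = rng.normal(-60, 25, size=(4, 4))
        expected = np.linalg.solve(
            dense_diffusion_matrix(faces.sigma_x, faces.sigma_y, disc.alpha),
            disc.alpha * V.ravel(),
        ).reshape(4, 4)
        assert np.allclose(pde_step(sys_, V, tol=1e-12), expected,
                           rtol=1e-10, atol=1e-10)

    def test_mean_potential_is_conserved(self, unit, rng):
        geom = tile_units(unit, 1, 1)
        sys_ = assemble_diffusion_system(
            geom, assign_face_conductances(geom), Discretization())
        V = rng.normal(-60, 25, size=(geom.nx, geom.ny))
        Vs = pde_step(sys_, V, tol=1e-12)
        assert Vs.mean() == pytest.approx(V.mean(), abs=1e-8)

    def test_direct_factorization_agrees_with_cg(self, geoms, rng):
        geom = geoms["oracle20"]
        faces = assign_face_conductances(geom)
        disc = Discretization()
        V = rng.normal(-60, 25, size=(20, 20))
        cg = pde_step(assemble_diffusion_system(geom, faces, disc), V,
                      tol=1e-12)
        direct = pde_step(
            assemble_diffusion_system(geom, faces, disc,
                                      preconditioner="direct"), V)
        assert np.allclose(direct, cg, rtol=1e-9, atol=1e-9)

    def test_vanishing_dt_p_freezes_the_field(self, geoms, rng):
        geom = geoms["oracle20"]
        faces = assign_face_conductances(geom)
        V = rng.normal(-60, 25, size=(20, 20))
        prev = None
        for dt_p in (1e-2, 1e-4, 1e-6):
            sys_ = assemble_diffusion_system(
                geom, faces, Discretization(dt_p=dt_p, dt_o=dt_p))
            change = np.linalg.norm(pde_step(sys_, V, tol=1e-12) - V) \
                / np.linalg.norm(V)
            if prev is not None:
                assert change < prev
            prev = change
        assert prev < 2e-3


class TestGodunovStep:
    def _setup(self, geom, model, dt_p=0.01, dt_o=0.001):
        faces = assign_face_conductances(geom)
        disc = Discretization(dt_p=dt_p, dt_o=dt_o)
        sys_ = assemble_diffusion_system(geom, faces, disc)
        sim = SimulationState(time=0.0,
                              states=CellStateArray(model, geom.n_volumes))
        return faces, disc, sys_, sim

    def test_resting_tissue_stays_at_rest(self, geoms, twovar):
        geom = geoms["het4x4"]
        _, disc, sys_, sim = self._setup(geom, twovar)
        before = sim.states.arr.copy()
        godunov_step(sim, sys_, twovar, disc, None)
        assert np.allclose(sim.states.arr, before, rtol=0, atol=1e-12)

    def test_step_bookkeeping(self, geoms, twovar):
        geom = geoms["het4x4"]
        _, disc, sys_, sim = self._setup(geom, twovar)
        for _ in range(10):
            godunov_step(sim, sys_, twovar, disc, None)
        assert sim.time == pytest.approx(0.1)
        assert sim.macro_steps == 10
        assert sim.ode_substeps == 100

    def test_macro_step_equals_manual_composition(self, geoms, twovar, rng):
        geom = geoms["het4x4"]
        _, disc, sys_, sim = self._setup(geom, twovar)
        sim.states.arr[0] += rng.uniform(0, 30, size=16)
        sched = StimulusSchedule(
            [StimulusPulse(0, 2, 0, 2, 40.0, 0.0, 1.0)], (4, 4))
        manual = sim.states.arr.copy()
        godunov_step(sim, sys_, twovar, disc, sched)
        # compose by hand: PDE solve then N_o explicit substeps
        manual[0] = pde_step(sys_, manual[0].reshape(4, 4)).ravel()
        for k in range(disc.N_o):
            istim = sched.current_array(k * disc.dt_o, 16)
            twovar.step(manual, disc.dt_o, istim)
        assert np.array_equal(sim.states.arr, manual)

    @pytest.mark.parametrize("model_name", ["test", "bdk"])
    def test_split_step_matches_dense_oracle(self, model_name, rng):
        model = get_model(model_name)
        nx, ny = 6, 5
        from micromyo.microstructure import TissueGeometry
        geom = TissueGeometry(
            cell_label_grid=np.zeros((nx, ny), np.int32),
            x_face_labels=np.zeros((nx - 1, ny), np.int8),
            y_face_labels=np.zeros((nx, ny - 1), np.int8),
        )
        sx = rng.uniform(0, 0.4, size=(nx - 1, ny))
        sy = rng.uniform(0, 0.4, size=(nx, ny - 1))
        faces = FaceField(sx, sy)
        dt_o = 1e-4 if model_name == "bdk" else 1e-3
        disc = Discretization(dt_p=100 * dt_o, dt_o=dt_o)
        sys_ = assemble_diffusion_system(geom, faces, disc, tol=1e-12)
        sim = SimulationState(time=0.0,
                              states=CellStateArray(model, nx * ny))
        sim.states.arr[0] += rng.uniform(0, 25, size=nx * ny)
        start = sim.states.arr.copy()
        sched = StimulusSchedule(
            [StimulusPulse(0, 3, 0, 3, 30.0, 0.0, disc.dt_p)], (nx, ny))
        godunov_step(sim, sys_, model, disc, sched)
        oracle = dense_split_step(
            start[0].reshape(nx, ny), start, sx, sy, disc.alpha, model,
            dt_o, disc.N_o,
            lambda t: sched.current_array(t, nx * ny), 0.0)
        assert np.allclose(sim.states.arr, oracle, rtol=1e-8, atol=1e-8)

    def test_membrane_isolated_tissue_equals_single_cells(self, twovar, rng):
        # sigma = 0 everywhere: tissue must evolve exactly like independent
        # cells (the PDE stage becomes the identity)
        nx, ny = 3, 2
        from micromyo.microstructure import TissueGeometry
        geom = TissueGeometry(
            cell_label_grid=np.arange(6, dtype=np.int32).reshape(3, 2),
            x_face_labels=np.zeros((2, 2), np.int8),
            y_face_labels=np.zeros((3, 1), np.int8),
        )
        faces = FaceField(np.zeros((2, 2)), np.zeros((3, 1)))
        disc = Discretization(dt_p=0.01, dt_o=0.001)
        sys_ = assemble_diffusion_system(geom, faces, disc)
        sim = SimulationState(time=0.0, states=CellStateArray(twovar, 6))
        sim.states.arr[0] += rng.uniform(0, 30, size=6)
        start = sim.states.arr.copy()
        istim = rng.uniform(0, 20, size=6)
        sched = StimulusSchedule(
            [StimulusPulse(i, i + 1, j, j + 1, float(istim[i * 2 + j]),
                           0.0, 1.0)
             for i in range(3) for j in range(2)], (3, 2))
        for _ in range(5):
            godunov_step(sim, sys_, twovar, disc, sched)
        # independent single-cell integration (the decoupled PDE stage is
        # the identity up to one round-off of the warm-started solve)
        for m in range(6):
            S = np.ascontiguousarray(start[:, m:m + 1])
            for k in range(5 * disc.N_o):
                twovar.step(S, disc.dt_o, istim[m:m + 1])
            assert np.allclose(sim.states.arr[:, m], S[:, 0],
                               rtol=0, atol=1e-12)


class TestRunSimulation:
    def test_two_runs_are_bit_identical(self, unit, twovar):
        from micromyo.protocols import make_central_stimulus
        geom = tile_units(unit, 1, 1)
        faces = assign_face_conductances(geom)
        disc = Discretization(dt_p=0.05, dt_o=0.05)
        stim = make_central_stimulus(geom)
        runs = [
            run_simulation(geom, faces, disc, twovar, stim, duration=3.0,
                           probes=[(10, 9), (70, 9)])
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].probe_traces, runs[1].probe_traces)
        assert np.array_equal(runs[0].times, runs[1].times)

    def test_duration_to_macro_step_count(self, geoms, twovar):
        geom = geoms["het4x4"]
        res = run_simulation(geom, uniform_faces(4, 4),
                             Discretization(dt_p=0.01, dt_o=0.01), twovar,
                             None, duration=1.0)
        assert res.state.macro_steps == 100

    def test_splitting_error_decreases_with_dt_p(self, twovar):
        # halving dt_p must monotonically reduce the relative L2 error
        # against a matched-step reference on a fixed excitation
        from micromyo.analysis import l2_relative_error
        from micromyo.microstructure import TissueGeometry
        nx = ny = 20
        geom = TissueGeometry(
            cell_label_grid=np.zeros((nx, ny), np.int32),
            x_face_labels=np.ones((nx - 1, ny), np.int8),
            y_face_labels=np.ones((nx, ny - 1), np.int8),
        )
        faces = uniform_faces(nx, ny, 0.1)
        sched = StimulusSchedule(
            [StimulusPulse(8, 12, 8, 12, 200.0, 0.0, 1.0)], (nx, ny))

        def record(dt_p, dt_o):
            res = run_simulation(geom, faces,
                                 Discretization(dt_p=dt_p, dt_o=dt_o),
                                 twovar, sched, duration=4.0,
                                 record_full_every=0.08)
            return res.recordings[1:]

        ref = record(0.0025, 0.0025)
        errs = [l2_relative_error(record(dt_p, 0.0025), ref)
                for dt_p in (0.08, 0.04, 0.02)]
        assert errs[0] > errs[1] > errs[2] > 0

    def test_central_stimulus_field_has_180_degree_symmetry(self, twovar):
        from micromyo.microstructure import TissueGeometry
        nx = ny = 21
        geom = TissueGeometry(
            cell_label_grid=np.zeros((nx, ny), np.int32),
            x_face_labels=np.ones((nx - 1, ny), np.int8),
            y_face_labels=np.ones((nx, ny - 1), np.int8),
        )
        sched = StimulusSchedule(
            [StimulusPulse(9, 12, 9, 12, 600.0, 0.0, 1.0)], (nx, ny))
        res = run_simulation(geom, uniform_faces(nx, ny, 0.2),
                             Discretization(dt_p=0.02, dt_o=0.02), twovar,
                             sched, duration=2.0, record_full_every=2.0,
                             tol=1e-11)
        V = res.recordings[-1]
        assert np.allclose(V, V[::-1, ::-1], rtol=0, atol=1e-6)
        assert V.max() > -70.0   # the stimulus actually did something

    def test_planner_counts_unknowns(self):
        assert volumes_for_size_cm(1.0) == 1250
        ps = problem_size(1250, 1250, 41)
        assert ps["ode_unknowns"] == 64_062_500
        assert ps["pde_unknowns"] == 1_562_500


class TestFluxDiagnostics:
    def test_pair_current_and_conservation(self, geoms):
        from micromyo.fvm_solver import face_currents, volumetric_current
        faces = assign_face_conductances(geoms["pair-gap"])
        V = np.array([[0.0], [10.0]])
        Ix, _ = face_currents(faces, V, d=10.0)
        # plicate face: G = 0.5 uS, current = -G * dV = -5 nA
        assert Ix[0, 0] == pytest.approx(-5.0)
        iv = volumetric_current(faces, V)
        assert iv.sum() == pytest.approx(0.0, abs=1e-15)
        assert iv[0, 0] > 0 > iv[1, 0]       # charge flows into the low-V cell

    def test_uniform_field_has_no_fluxes(self, geoms, rng):
        from micromyo.fvm_solver import face_currents, volumetric_current
        geom = geoms["oracle20"]
        faces = assign_face_conductances(geom)
        V = np.full((20, 20), -77.7)
        Ix, Iy = face_currents(faces, V)
        assert not Ix.any() and not Iy.any()
        assert not volumetric_current(faces, V).any()
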