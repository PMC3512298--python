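"""Heterogeneous monodomain solver: five-point FVM assembly + Godunov splitting.

Space is discretized on the microstructure grid (h = 8 um volumes, depth d);
each interior face carries an effective conductivity sigma_face (uS/um).
Time stepping splits each macro step dt_p into

  1. an implicit-Euler diffusion step: solve
         (sum of face sigmas + alpha) V*_ij - sum sigma_face V*_neighbour
             = alpha V^n_ij,
     with alpha = beta Cm h^2 / dt_p (same units as sigma_face), via
     conjugate gradients preconditioned with ILU(0) (Jacobi fallback);
  2. N_o explicit-Euler reaction substeps of length dt_o (N_o dt_o = dt_p)
     of the ionic model, with the applied stimulus current injected in this
     stage.

No-flux boundaries come out of the assembly for free: boundary faces simply
contribute nothing, so every row of the operator sums exactly to alpha and
the mean of V is conserved by the diffusion step.

Internal unit system: um, ms, mV, uS; capacitance in nF (uS*ms).  The
surface-to-volume ratio beta is given in 1/um and the specific membrane
capacitance in uF/cm^2 (converted internally to nF/um^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cell_models.base import CellStateArray, IonicModelSpec
from .microstructure import FaceField, TissueGeometry
from .protocols import StimulusSchedule

log = logging.getLogger(__name__)

__all__ = [
    "Discretization",
    "SymmetricSparseSystem",
    "SimulationState",
    "SimulationResult",
    "assemble_diffusion_system",
    "pde_step",
    "godunov_step",
    "run_simulation",
    "face_currents",
    "volumetric_current",
    "problem_size",
    "volumes_for_size_cm",
]

UF_PER_CM2_TO_NF_PER_UM2 = 1e-5   # 1 uF/cm^2 = 1e-5 nF/um^2


@dataclass(frozen=True)
class Discretization:
    """Space/time discretization and membrane scaling parameters.

    The default surface-to-volume ratio beta = 0.28 1/um (2800 cm^-1) was
    calibrated once, together with the template's junction placement, so the
    default microstructure reproduces the reference conduction velocities
    (410 um/ms along, 130 um/ms across the fibers); it sits inside the
    physiological range implied by the shipped cell model's own geometry
    (Acap / cell volume ~ 0.3-0.6 1/um).  See docs/methods.md.
    """

    h: float = 8.0          # um
    d: float = 10.0         # um
    beta: float = 0.28      # surface-to-volume ratio, 1/um
    Cm: float = 1.0         # specific capacitance, uF/cm^2
    dt_p: float = 0.01      # diffusion (PDE) step, ms
    dt_o: float = 0.0001    # reaction (ODE) substep, ms

    def __post_init__(self) -> None:
        if min(self.h, self.d, self.beta, self.Cm, self.dt_p, self.dt_o) <= 0:
            raise ValueError("all discretization parameters must be positive")
        n = self.dt_p / self.dt_o
        if abs(n - round(n)) > 1e-9 * n:
            raise ValueError(
                f"dt_p must be an integer multiple of dt_o "
                f"(dt_p={self.dt_p}, dt_o={self.dt_o})"
            )

    @property
    def N_o(self) -> int:
        """Reaction substeps per macro step (N_o * dt_o = dt_p)."""
        return int(round(self.dt_p / self.dt_o))

    @property
    def Cm_internal(self) -> float:
        """Membrane capacitance per area in nF/um^2."""
        return self.Cm * UF_PER_CM2_TO_NF_PER_UM2

    @property
    def alpha(self) -> float:
        """beta * Cm * h^2 / dt_p, in face-conductivity units (uS/um)."""
        return self.beta * self.Cm_internal * self.h ** 2 / self.dt_p


@dataclass
class SymmetricSparseSystem:
    """The implicit-Euler five-point diffusion operator of one macro step.

    The "ilu" preconditioner is the zero-fill incomplete factorization of
    the SPD five-point operator (ILU(0) keeps A's sparsity pattern; for this
    symmetric M-matrix it coincides with DIC/IC(0)), applied by structured
    forward/backward sweeps.  Jacobi (diagonal scaling) is the fallback.
    """

    A: sp.csr_matrix
    alpha: float
    shape: tuple[int, int]            # (nx, ny)
    diag_grid: np.ndarray | None = None   # (nx, ny)
    sx: np.ndarray | None = None          # (nx-1, ny)
    sy: np.ndarray | None = None          # (nx, ny-1)
    preconditioner: str = "ilu"       # "ilu" | "jacobi" | "none" | "direct"
    tol: float = 1e-6                 # relative residual
    maxiter: int = 10_000
    _M: spla.LinearOperator | None = field(default=None, repr=False)
    _lu: object = field(default=None, repr=False)
    cg_iterations: list[int] = field(default_factory=list, repr=False)

    def _build_preconditioner(self) -> spla.LinearOperator | None:
        from ._ic0 import ic0_apply, ic0_factor

        n = self.A.shape[0]
        if self.preconditioner == "none":
            return None
        if self.preconditioner == "ilu" and self.diag_grid is not None:
            d = ic0_factor(self.diag_grid, self.sx, self.sy)
            if (d > 0).all():
                nx, ny = self.shape
                sx, sy = self.sx, self.sy
                buf = np.empty((nx, ny))

                def apply(r):
                    return ic0_apply(
                        r.reshape(nx, ny), d, sx, sy, buf
                    ).ravel().copy()

                return spla.LinearOperator((n, n), matvec=apply)
            log.warning("IC(0) pivot breakdown; falling back to Jacobi")
        dinv = 1.0 / self.A.diagonal()
        return spla.LinearOperator((n, n), matvec=lambda x: dinv * x)

    @property
    def M(self) -> spla.LinearOperator | None:
        if self._M is None and self.preconditioner != "none":
            self._M = self._build_preconditioner()
        return self._M


def assemble_diffusion_system(
    geom: TissueGeometry,
    faces: FaceField,
    disc: Discretization,
    preconditioner: str = "ilu",
    tol: float = 1e-6,
) -> SymmetricSparseSystem:
    """Assemble the symmetric five-point operator of the implicit PDE step.

    Row (i, j): diagonal alpha + sum of the four face conductivities,
    off-diagonal -sigma_face per interior neighbour.  Volumes are flattened
    in C order over the (nx, ny) grid.
    """
    nx, ny = geom.nx, geom.ny
    sx, sy = np.asarray(faces.sigma_x, float), np.asarray(faces.sigma_y, float)
    if sx.shape != (nx - 1, ny) or sy.shape != (nx, ny - 1):
        raise ValueError("face field shape does not match geometry")
    if (sx < 0).any() or (sy < 0).any():
        raise ValueError("face conductivities must be nonnegative")

    def p(i, j):
        return i * ny + j

    n = nx * ny
    diag = np.full((nx, ny), disc.alpha)
    ii, jj = np.meshgrid(np.arange(nx - 1), np.arange(ny), indexing="ij")
    rows_x, cols_x = p(ii, jj).ravel(), p(ii + 1, jj).ravel()
    diag[:-1, :] += sx
    diag[1:, :] += sx
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny - 1), indexing="ij")
    rows_y, cols_y = p(ii, jj).ravel(), p(ii, jj + 1).ravel()
    diag[:, :-1] += sy
    diag[:, 1:] += sy

    rows = np.concatenate([np.arange(n), rows_x, cols_x, rows_y, cols_y])
    cols = np.concatenate([np.arange(n), cols_x, rows_x, cols_y, rows_y])
    vals = np.concatenate(
        [diag.ravel(), -sx.ravel(), -sx.ravel(), -sy.ravel(), -sy.ravel()]
    )
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return SymmetricSparseSystem(
        A=A, alpha=disc.alpha, shape=(nx, ny),
        diag_grid=diag, sx=sx.copy(), sy=sy.copy(),
        preconditioner=preconditioner, tol=tol,
    )


def pde_step(
    system: SymmetricSparseSystem, V_n: np.ndarray, tol: float | None = None
) -> np.ndarray:
    """Implicit-Euler diffusion step: solve A V* = alpha V^n by CG.

    Returns V* with the shape of ``V_n``.  Raises ``RuntimeError`` if CG does
    not reach the relative-residual tolerance within ``system.maxiter``.
    """
    b = system.alpha * np.asarray(V_n, float).ravel()
    if not np.isfinite(b).all():
        raise FloatingPointError("non-finite V passed to pde_step")
    if system.preconditioner == "direct":
        # exact sparse LU, factorized once per assembled system; used where
        # the diffusion solve plays the role of a reference/oracle
        if system._lu is None:
            system._lu = spla.splu(system.A.tocsc())
        system.cg_iterations.append(0)
        return system._lu.solve(b).reshape(np.asarray(V_n).shape)
    rtol = system.tol if tol is None else tol
    it = [0]

    def cb(_):
        it[0] += 1

    x, info = spla.cg(
        system.A, b, x0=b / system.alpha, rtol=rtol, atol=0.0,
        maxiter=system.maxiter, M=system.M, callback=cb,
    )
    if info != 0:
        res = np.linalg.norm(system.A @ x - b) / np.linalg.norm(b)
        raise RuntimeError(
            f"CG failed to converge (info={info}, rel residual {res:.3e})"
        )
    system.cg_iterations.append(it[0])
    return x.reshape(np.asarray(V_n).shape)


@dataclass
class SimulationState:
    """Running state of a tissue simulation."""

    time: float
    states: CellStateArray
    macro_steps: int = 0
    ode_substeps: int = 0

    @property
    def V(self) -> np.ndarray:
        return self.states.V


def godunov_step(
    sim: SimulationState,
    system: SymmetricSparseSystem,
    model: IonicModelSpec,
    disc: Discretization,
    stim: StimulusSchedule | None = None,
) -> SimulationState:
    """One macro step: implicit diffusion, then N_o explicit reaction substeps.

    The stimulus current is injected during the reaction substeps (it is part
    of the reaction operator), evaluated at each substep time.  Advances
    ``sim`` in place and returns it.
    """
    n_vol = sim.states.n_volumes
    if system.shape[0] * system.shape[1] != n_vol:
        raise ValueError("system size does not match state array")
    arr = sim.states.arr
    arr[0, :] = pde_step(system, arr[0, :])
    dt_o, N_o = disc.dt_o, disc.N_o
    zero = np.zeros(n_vol)
    for k in range(N_o):
        t_sub = sim.time + k * dt_o
        istim = stim.current_array(t_sub, n_vol) if stim is not None else zero
        model.step(arr, dt_o, istim)
    sim.ode_substeps += N_o
    sim.macro_steps += 1
    sim.time = sim.macro_steps * disc.dt_p
    if not np.isfinite(arr[0, :]).all():
        bad = int(np.argwhere(~np.isfinite(arr[0, :]))[0])
        raise FloatingPointError(
            f"non-finite V at volume {bad}, t = {sim.time:.4f} ms"
        )
    return sim


@dataclass
class SimulationResult:
    times: np.ndarray                       # probe sample times, ms
    probe_traces: np.ndarray                # (nt, n_probes) V in mV
    probes: list[tuple[int, int]]
    state: SimulationState
    record_times: np.ndarray | None = None  # full-field sample times
    recordings: np.ndarray | None = None    # (nrec, nx, ny) V fields
    cg_iterations: np.ndarray | None = None


def run_simulation(
    geom: TissueGeometry,
    faces: FaceField,
    disc: Discretization,
    model: IonicModelSpec,
    schedule: StimulusSchedule | None,
    duration: float,
    probes: list[tuple[int, int]] | None = None,
    record_full_every: float | None = None,
    snapshot_every: float | None = None,
    snapshot_writer: Callable[[np.ndarray, float], None] | None = None,
    monitor: Callable[[SimulationState], bool] | None = None,
    initial_states: CellStateArray | None = None,
    preconditioner: str = "ilu",
    tol: float = 1e-6,
    log_every_ms: float = 10.0,
) -> SimulationResult:
    """Run the split monodomain model for ``duration`` ms.

    Fully deterministic: identical inputs give bit-identical outputs.  Probe
    traces are sampled every macro step (t = 0 included).  ``monitor`` may
    return True to stop early (used e.g. once a wave has passed all probes).
    """
    nx, ny = geom.nx, geom.ny
    system = assemble_diffusion_system(
        geom, faces, disc, preconditioner=preconditioner, tol=tol
    )
    states = initial_states or CellStateArray(model, nx * ny)
    sim = SimulationState(time=0.0, states=states)
    n_steps = math.ceil(duration / disc.dt_p - 1e-9)

    probes = probes or []
    probe_idx = []
    for (i, j) in probes:
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValueError(f"probe {(i, j)} outside mesh")
        probe_idx.append(i * ny + j)
    probe_idx = np.array(probe_idx, dtype=int)

    rec_stride = None
    if record_full_every is not None:
        rec_stride = int(round(record_full_every / disc.dt_p))
        if abs(rec_stride * disc.dt_p - record_full_every) > 1e-9:
            raise ValueError("record_full_every must be a multiple of dt_p")
    snap_stride = None
    if snapshot_every is not None:
        snap_stride = int(round(snapshot_every / disc.dt_p))

    times, traces = [], []
    rec_times, recs = [], []
    # sample t=0
    times.append(0.0)
    if len(probe_idx):
        traces.append(states.arr[0, probe_idx].copy())
    if rec_stride is not None:
        rec_times.append(0.0)
        recs.append(states.arr[0, :].reshape(nx, ny).copy())
    if snap_stride is not None and snapshot_writer is not None:
        snapshot_writer(states.arr[0, :].reshape(nx, ny), 0.0)

    next_log = log_every_ms
    for step in range(1, n_steps + 1):
        godunov_step(sim, system, model, disc, schedule)
        times.append(sim.time)
        if len(probe_idx):
            traces.append(states.arr[0, probe_idx].copy())
        if rec_stride is not None and step % rec_stride == 0:
            rec_times.append(sim.time)
            recs.append(states.arr[0, :].reshape(nx, ny).copy())
        if snap_stride is not None and snapshot_writer is not None \
                and step % snap_stride == 0:
            snapshot_writer(states.arr[0, :].reshape(nx, ny), sim.time)
        if sim.time >= next_log - 1e-9:
            log.info("t = %.2f ms (V range %.1f .. %.1f mV)",
                     sim.time, states.arr[0].min(), states.arr[0].max())
            next_log += log_every_ms
        if monitor is not None and monitor(sim):
            log.info("monitor requested stop at t = %.3f ms", sim.time)
            break

    return SimulationResult(
        times=np.array(times),
        probe_traces=(np.array(traces) if traces
                      else np.empty((len(times), 0))),
        probes=list(probes),
        state=sim,
        record_times=np.array(rec_times) if rec_stride is not None else None,
        recordings=np.array(recs) if rec_stride is not None else None,
        cg_iterations=np.array(system.cg_iterations),
    )


def face_currents(faces: FaceField, V: np.ndarray, d: float = 10.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Intracellular currents through interior faces, in nA.

    For a face with effective conductivity sigma (uS/um) the current from
    the lower-index to the higher-index volume is ``-sigma * d * dV``
    (for gap-junction faces sigma = G/d, so this reduces to ``-G * dV``).
    Returns (Ix, Iy) with the shapes of the face fields.
    """
    V = np.asarray(V, float)
    Ix = -faces.sigma_x * d * (V[1:, :] - V[:-1, :])
    Iy = -faces.sigma_y * d * (V[:, 1:] - V[:, :-1])
    return Ix, Iy


def volumetric_current(faces: FaceField, V: np.ndarray, h: float = 8.0,
                       d: float = 10.0) -> np.ndarray:
    """Net volumetric current density I_v per volume (nA/um^3).

    The discrete divergence of the face currents divided by the volume
    h^2 d; sums to zero over the tissue (no-flux boundaries).
    """
    Ix, Iy = face_currents(faces, V, d)
    net = np.zeros_like(np.asarray(V, float))
    net[:-1, :] -= Ix          # current leaving through the east face
    net[1:, :] += Ix           # current entering from the west face
    net[:, :-1] -= Iy
    net[:, 1:] += Iy
    return net / (h * h * d)


def volumes_for_size_cm(size_cm: float, h: float = 8.0) -> int:
    """Number of h-um volumes spanning a physical length given in cm."""
    return int(round(size_cm * 1e4 / h))


def problem_size(nx: int, ny: int, n_vars: int) -> dict[str, int]:
    """Bookkeeping for a planned run: ODE and PDE unknown counts."""
    return {
        "volumes": nx * ny,
        "pde_unknowns": nx * ny,
        "ode_unknowns": nx * ny * n_vars,
    }
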