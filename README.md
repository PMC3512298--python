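# micromyo

Microscopic cardiac tissue electrophysiology: a heterogeneous monodomain
simulator that resolves the myocyte-level microstructure of ventricular
tissue at 8 μm, for studying how discrete gap-junction coupling shapes
action-potential propagation — slow and discontinuous conduction,
anisotropy, and reentrant (spiral-wave) activity.

## Who this is for

Computational cardiac electrophysiologists who want tissue simulations in
which individual myocytes, their cytoplasm, and their gap-junction
connections are explicit, rather than homogenized into a smooth conductivity
tensor — e.g. to compare microscopic against discrete/homogenized models, or
to study micro-scale conduction phenomena with a modern Markov-chain ionic
model.

## The model

Transmembrane potential `V(x, y, t)` obeys the monodomain reaction–diffusion
equation

    β Cm ∂V/∂t + β I_ion(V, η) = ∇·(σ(x, y) ∇V) + I_stim,
    ∂η/∂t = f(V, η),

with no-flux boundaries, surface-to-volume ratio β and membrane capacitance
Cm.  Space is discretized by finite volumes on a uniform 8 μm grid whose
**faces** carry the microstructure: each face between neighbouring volumes
is membrane (σ = 0), cytoplasm (σ_c = 0.4 μS/μm), or one of three
gap-junction classes — plicate (G_p = 0.5 μS) at longitudinal cell ends,
interplicate (G_i = 0.33 μS) and combined plicate (G_c = 0.062 μS) on
lateral borders — with junction conductances converted to face
conductivities as G/d for tissue depth d = 10 μm.  Geometry comes from a
32-myocyte template unit (648 × 144 μm, mean cell 120.9 ± 27.8 μm by
18.3 ± 3.5 μm, six gap-junction neighbours per cell under periodic tiling)
that tiles into arbitrarily large sheets.

Time stepping uses Godunov operator splitting: an unconditionally stable
implicit-Euler diffusion step (Δt_p = 0.01 ms; conjugate gradients with a
zero-fill incomplete factorization) followed by N_o = 100 explicit-Euler
reaction substeps (Δt_o = 0.0001 ms) of the ionic model.  Two ionic models
ship: a 41-variable Markov-chain mouse left-ventricular myocyte model
(15 transmembrane currents, full Ca²⁺ handling) and a cheap two-variable
excitable model for solver tests and demonstrations.

## Worked example

```python
from micromyo import benchmarks

st = benchmarks.mesh_statistics()
print(f"length: {st.mean_length:.1f} +/- {st.sd_length:.1f} um")
print(f"width:  {st.mean_width:.1f} +/- {st.sd_width:.1f} um")
print(f"gap-junction neighbours per cell: {st.mean_neighbors:.1f}")

plan = benchmarks.planned_unknowns(1.0, 1.0)   # a 1 cm x 1 cm sheet
print(f"{plan['nx']} x {plan['ny']} volumes, "
      f"{plan['ode_unknowns']:,} ODE unknowns")
```

prints

```
length: 120.9 +/- 27.8 um
width:  18.3 +/- 3.5 um
gap-junction neighbours per cell: 6.0
1250 x 1250 volumes, 64,062,500 ODE unknowns
```

— the shipped microstructure reproduces the reference myocyte morphometry,
and the planner shows why a full square centimetre (64 million ODE unknowns
advanced 100 times per PDE step) is a cluster-scale job: this package runs
the same physics on strips and patches of a few millimetres.

A single stimulated myocyte (41-variable model, explicit Euler at
Δt = 0.0001 ms):

```python
import numpy as np
from micromyo.cell_models import get_model

m = get_model("bdk")
S = m.make_states(1)
stim = np.zeros(1)
for k in range(600_000):                       # 60 ms
    t = k * 1e-4
    stim[0] = 80.0 if 1.0 <= t < 1.5 else 0.0  # pA/pF
    m.step(S, 1e-4, stim)
```

gives a mouse ventricular action potential: rest −82.4 mV, peak +33.0 mV,
maximum upstroke velocity 156 mV/ms, repolarized within ~25 ms.

Tissue runs are driven from YAML configs (`micromyo run --config run.yaml`)
or directly through `micromyo.fvm_solver.run_simulation`; see
`micromyo --help` for the mesh-building, single-cell, conduction-velocity,
threshold-finding and S1–S2 sweep commands.

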