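# Methods

## Model

The package solves the monodomain equation on a two-dimensional tissue
sheet,

    β Cm ∂V/∂t + β I_ion(V, η) = ∇·(σ ∇V) + I_stim,      n·σ∇V = 0 on ∂Ω,

with a heterogeneous, face-based conductivity field σ that encodes cardiac
microstructure at subcellular resolution.  The extracellular space is not
modelled (no bidomain); applied currents are transmembrane.  All internal
arithmetic uses μm, ms, mV and μS (capacitance in nF = μS·ms); user-facing
parameters keep their conventional units (Cm in μF/cm², converted on use).

### Microstructure

The tissue is a uniform grid of h × h × d volumes (h = 8 μm, depth
d = 10 μm).  Every interior face carries one of five connection labels:

| label            | face conductivity (μS/μm) | where                     |
|------------------|---------------------------|---------------------------|
| membrane         | 0                         | uncoupled cell borders    |
| cytoplasm        | σ_c = 0.4                 | interior of a myocyte     |
| plicate          | G_p/d = 0.05              | longitudinal cell ends    |
| interplicate     | G_i/d = 0.033             | lateral borders           |
| combined plicate | G_c/d = 0.0062            | lateral borders           |

Geometry comes from a checked-in 32-myocyte template on an 81 × 18 grid
(648 × 144 μm) in a running-bond (staggered brick) layout of eight
longitudinal strands.  The template is defined on the periodic closure of
the unit (four cells wrap the east seam): this is what makes a mean
gap-junction degree of exactly 6 attainable — an Euler-characteristic
argument shows any unwrapped rectangular partition loses one adjacency pair
per four-cell corner on the seam and cannot exceed 6 − S/16 for S strand
interfaces.  Under periodic tiling every one of the 32 cells has exactly
2 end neighbours (via plicate faces) and 2 lateral neighbours on each side
(via interplicate/combined-plicate faces).  Tiled sheets repeat the
template; faces between copies carry the template's designed seam labels,
and each copy contributes 32 distinct cell ids.  Domain-boundary faces are
membrane (no flux).

Cell-dimension statistics are carried by designed continuous (pre-raster)
length/width pairs stored with the template — mean ± sample SD (n−1)
120.9 ± 27.8 μm by 18.3 ± 3.5 μm — because an 8 μm raster of a 648 × 144 μm
area cannot express those statistics exactly (the raster's mean cell area is
fixed at 2916 μm² by the partition).  The raster provides topology and face
labels; the continuous dims provide morphometry.

Junction placement density is the template's free design parameter (the
historical microstructure it stylizes was itself hand-tuned): one plicate
face per cell-end interface, and four interplicate plus two combined-plicate
faces per lateral border arc.  These fractions, together with
β = 0.28 μm⁻¹, were fixed once so the default tissue conducts at
≈ 400 μm/ms along and ≈ 132 μm/ms across the fiber direction (reference
values 410 and 130, ratio 0.32), and were not revisited afterwards.

**On β.**  Published values of the surface-to-volume ratio for this model
family print as 0.14 cm⁻¹, which is dimensionally untenable (physiological
myocyte values are 2000–6000 cm⁻¹; a literal reading makes conduction three
orders of magnitude too fast).  Reading the figure as 0.14 μm⁻¹
(1400 cm⁻¹) gives plausible physics but, with the printed conductance
values, longitudinal conduction cannot be brought below ≈ 495 μm/ms by any
junction placement that keeps plicate junctions at cell ends — the 0.5 μS
plicate conductance is too large a share of the axial path, and the lateral
junctions required for transverse conduction provide a bypass.  The default
is therefore β = 0.28 μm⁻¹, inside the physiological range implied by the
shipped ionic model's own geometry (capacitive area / cell volume
≈ 0.3–0.6 μm⁻¹), calibrated once against both reference velocities.  β is
an ordinary parameter of `Discretization` and can be set to any value.

### Ionic models

`cell_models/bondarenko.py` holds a complete transcription of the
41-variable mouse left-ventricular (apex) myocyte model: Markov chains for
the fast Na⁺ channel (9 states), L-type Ca²⁺ channel (8), rapid delayed
rectifier (5) and ryanodine receptor (4); Hodgkin–Huxley gates for the
transient-outward, ultrarapid, noninactivating and slow K⁺ currents; and
full Ca²⁺ handling (subspace, junctional/network SR, troponin, calmodulin,
calsequestrin).  I_ion is the sum of its 15 transmembrane currents in pA/pF.
One Markov state per chain is carried implicitly as one minus the explicit
occupancies, keeping 41 differential variables.  The whole definition lives
in that single file so it can be audited in one diff.  The shipped rest
state is the published quiescent state relaxed for 2000 ms by the module's
own integrator and frozen into the source
(`scripts/freeze_rest_state.py` regenerates it).  Apex parameters are used
throughout (the slow transient-outward conductance is zero at the apex; its
gates are still integrated).  Single-cell behaviour: rest −82.4 mV, peak
+33 mV, maximum upstroke 156 mV/ms, APD90 ≈ 23 ms.

The two-variable test model is a Mitchell–Schaeffer-type excitable system
rescaled to mV (parameters in `cell_models/twovar.py`): exact resting fixed
point, ~50-fold cheaper right-hand side, non-stiff (usable at
Δt_o = Δt_p).  It exists so every solver property can be exercised cheaply;
its time scales are adjustable for demonstrations.

### Time integration

Godunov splitting per macro step Δt_p:

1. **Diffusion** (implicit Euler): solve
   `(Σ σ_face + α) V*_ij − Σ σ_face V*_nb = α V^n_ij` with
   α = β Cm h²/Δt_p.  The operator is symmetric positive definite with row
   sums exactly α, so the spatial mean of V is conserved.  Solver:
   conjugate gradients, relative residual 10⁻⁶ (configurable), warm-started
   at V^n, preconditioned by the zero-fill incomplete factorization of the
   five-point operator (ILU(0) on this symmetric M-matrix ≡ IC(0)/DIC),
   applied with structured forward/backward sweeps; Jacobi fallback if the
   factorization breaks down; an exact sparse-LU path exists for runs where
   the diffusion solve serves as a reference.
2. **Reaction** (explicit Euler): N_o = Δt_p/Δt_o substeps of
   `V ← V + Δt_o (−I_ion + I_stim)`, `η ← η + Δt_o f(V, η)`, volumes
   independent.  The applied stimulus belongs to this stage and is evaluated
   at each substep time.

Defaults Δt_p = 0.01 ms, Δt_o = 0.0001 ms (N_o = 100); Δt_o is a stability
requirement of the stiff Markov-chain kinetics and explicit Euler (a
Rush–Larsen variant was deliberately not implemented: for Markov-chain
models it buys no step-size headroom and costs more per step).  No adaptive
stepping.  States use a structure-of-arrays layout (one contiguous block per
variable, V first) so the diffusion stage reads V without copies; reaction
kernels are numba-compiled.  The pipeline contains no randomness: reruns are
bit-identical.

Non-finite values abort the run with the offending volume/variable and time
stamp.  Degenerate inputs are rejected at construction (negative
conductances, non-integer Δt_p/Δt_o, empty or out-of-mesh stimulus regions,
probes outside the mesh).

### Stimulation

Schedules are pure data: rectangular pulses with amplitude in pA/pF
(current already normalized by Cm), start and duration.  Defaults: 2 ms
pulses at 500 pA/pF — roughly twice the measured diastolic threshold for
small-region stimuli on the default tissue.  The large number is a
consequence of well-coupled tissue (liminal length ~1 mm): a thin stimulated
strip drains into a large downstream sink.  `find_threshold` measures
thresholds by bisection; `make_s1s2` builds the cross-field pair (S1 strip
on the left edge at t = 0, S2 over the lower-left quadrant at the coupling
interval).

### Measurements

Activation time is the first upward crossing of −30 mV, linearly
interpolated between samples (a crossing landing on a sample takes that
sample's time); the threshold sits mid-upstroke and the convention is
insensitive to ±20 mV changes at these sampling rates.  Conduction velocity
is probe distance over activation-time difference, with probes ≥ 0.4 mm
from stimulus and boundaries.  The anisotropy ratio is min/max of the two
velocities.  The splitting-error metric is the literal ratio
`Σ (V − V_ref)² / Σ V_ref²` over all recorded samples and volumes (no
square root; reported as a percentage; a square-root variant is exposed as
an option).

## Reference experiments and problem sizes

The package's benchmark drivers use workstation-scale configurations:

- **Longitudinal CV**: 3 × 1 template units (243 × 18 volumes, ≈ 1.94 mm ×
  144 μm), left-edge stimulus, probes at x = 0.6 and 1.44 mm on the
  mid-row, 41-variable model, default steps.  Result ≈ 400 μm/ms.
- **Transverse CV**: 1 × 7 units (81 × 126 volumes, 648 μm × ≈ 1 mm),
  bottom-edge stimulus, probes at y = 0.2 and 0.8 mm mid-width.  Result
  ≈ 132 μm/ms; ratio ≈ 0.33.
- **Splitting error**: 0.05 × 0.05 cm patch (62 × 62 volumes cropped from a
  1 × 4 tiling), central stimulus, 20 ms, V recorded on every volume each
  0.01 ms; split run (Δt_p = 0.01) against matched-step reference
  (Δt_p = Δt_o = 0.0001, direct solves).  Only space is reduced relative to
  the reference configuration (0.5 × 0.5 cm); the 20 ms window is kept
  because the metric's denominator needs a full action-potential cycle —
  the mouse AP passes through ≈ 0 mV at ~4–6 ms, and a window truncated
  there makes Σ V_ref² collapse and the ratio meaningless.  Result
  ≈ 0.02 %.
- **Reentry demo**: the full-scale spiral wave (1 cm², 41-variable model)
  is far beyond one workstation, so the demo shrinks the rotor wavelength
  instead: 3 × 13 units (≈ 1.9 × 1.9 mm), test model with shortened
  recovery (τ_close = 12 ms, τ_open = 50 ms), and β scaled ×150, which
  slows conduction uniformly while preserving every junction-to-cytoplasm
  current ratio.  (Scaling the conductances themselves instead causes
  source–sink block at the weakened sparse lateral junctions, and at native
  velocities the broken S2 end merges with the conditioning wave before it
  can curl.)  Cross-field S1–S2 at a coupling interval of 85 ms (vulnerable
  window ≈ 80–90 ms) produces a rotor that outlives the stimulus by
  hundreds of milliseconds.

## What the reduced conditions do and do not show

The strips and patches above demonstrate that the discretized physics —
microstructured conduction, anisotropy, splitting accuracy, vulnerability
to reentry — behaves correctly at reduced scale.  They do not reproduce
full-scale emergent phenomena (boundary effects are proportionally larger;
the demo rotor lives in a rescaled, not native, parameter regime), and the
two-variable model's action potential is phenomenological: only the
41-variable runs speak to mouse electrophysiology.  Wall-clock performance
of the original parallel implementations (MPI/GPU) is out of scope; this
package is serial by design, with numba-compiled kernels.

## Known limitations

- Two-dimensional sheets only; no extracellular domain, bath, or fibrosis.
- The template's exact junction positions are a stylized reconstruction
  constrained by summary statistics (cell counts, dimensions, degree,
  conduction velocities); the historical template's cell outlines are not
  recoverable.
- One ventricular parameter set (mouse apex); no septum variant, no other
  species.
- Explicit Euler for the reaction stage requires Δt_o = 0.0001 ms with the
  41-variable model; there is no stiff/exponential integrator option.
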