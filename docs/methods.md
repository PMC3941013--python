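# Methods

This note documents the models behind each `permion` stage, the defaults
and units, the synthetic-data generators that stand in for
molecular-dynamics output, and the numerical and design choices that were
genuinely open.

## Units and constants

All in-memory quantities use nm, ns, K, kJ/mol, kJ mol⁻¹ nm⁻¹ (force),
kJ mol⁻¹ nm⁻² (spring constants) and pS (conductance).  Conversions live
in one table in `permion.constants` (1 e·mV = 0.0964853 kJ/mol,
1 m²/s = 10⁹ nm²/ns, Å ↔ nm at the PDB boundary) and are round-trip
tested.  kB·T at 300 K is 2.494 kJ/mol.

## PMF from steered pulling

A tagged ion is towed along the pore axis by a harmonic spring (stiffness
k, typically 2000 kJ mol⁻¹ nm⁻²) whose free end moves at constant
velocity v.  When the spring is stiff and the pull slow, the time-averaged
spring force balances the mean force the channel exerts on the ion, so
its line integral along z is the free-energy profile (potential of mean
force).  The pipeline is:

1. `window_average_force` — block means of the recorded force over fixed
   time windows (default 0.04 ns).  The z coordinate of a window is the
   mean **trap** position, because the trap is the controlled variable;
   ion-position binning is available by flag.  Incomplete trailing
   windows are dropped.
2. `integrate_pmf` — cumulative trapezoid of (z, F̄), anchored W = 0 at
   the first grid point (cytoplasmic entry).  The anchor is pure gauge:
   conductance depends only on free-energy differences.
3. `reflect_pmf` — mirror about the extracellular end to build the
   full-channel profile of two docked hemichannels.  The mirror may sit
   up to one grid spacing past the last window centre, since window-centre
   grids stop up to half a window short of the nominal span.

No stiff-spring or friction correction is applied by default; an optional
Stokes-drag subtraction γ_f·v with γ_f = kBT/D is provided
(`pmf_from_log(friction_correction=True)`).  At the recovery settings
used in the tests (v = 0.1 nm/ns, D = 1.957 nm²/ns) the drag bias is
0.13 kJ mol⁻¹ nm⁻¹, well below thermal noise.

## Conductance from the PMF

Permeation is modelled as 1-D overdamped diffusion in the full-channel
profile W_GJ(z) with the bulk diffusion coefficient D = 1.957·10⁻⁹ m²/s
(experimental value for K⁺ in water).  The mean first passage time from
one entrance to an absorbing boundary at the other (reflecting behind the
start) is the double integral

τ = (1/D) ∫ dy e^{βU(y)} ∫ dz e^{−βU(z)},

evaluated by trapezoid with prefix sums (O(n)); the maximum of βU is
factored out of the exponentials so barriers beyond 100 kJ/mol do not
overflow (profiles with βU range > 700 are rejected as unphysical).  A
membrane potential ΔV adds the linear term qΔV(L−z)/L, normalised over
the actual grid span so U is exactly qΔV at the entrance and 0 at the
exit.  Rates are κ = 1/τ, the net current I = q(κ_f − κ_r), and γ₀ is
the ordinary-least-squares slope of I vs ΔV with a free intercept; an
intercept above 1% of max|I| triggers a warning, since any consistent
quadrature must give I(0) = 0.

Default voltage sweep: ±10, ±20, ±30, ±40, ±50 mV.  At ±50 mV
βqΔV ≈ 1.9, and the cubic term of the I–V curve shaves ~1.4% off the
fitted slope relative to the analytic small-voltage limit
γ₀ = 4q²D/(3kBT·L²) (54.66 pS for a flat profile at defaults, 53.90 pS
from the default sweep).  Validation against the closed form is therefore
done on a ±2…±10 mV sweep, inside the formula's domain of validity; the
production default keeps the wider, experimentally realistic range.

Multi-ion correction: the Debye length
λ_D = √(ε₀ε_r kB T / (2e² N_A c)) is 0.79 nm at 300 K, 0.15 M, ε_r 78.4
(ε_r is not part of the source data; 78.4 is bulk water near 300 K and is
an exposed parameter).  Ions a Debye diameter apart are screened, so
N_I = L/2λ_D ions occupy the channel near-independently and γ = N_I γ₀.
`ion_count(rounding="printed")` reproduces the hand-calculation
convention of rounding λ_D to two decimals before doubling
(2·0.79 = 1.58 nm, N_I = 10.89); exact division gives 10.92.  The
correction cancels in any conductance ratio between two channels.

## Hexamer symmetry

Six structurally equivalent alpha carbons define a hexagon; its
"diameters" are the three opposite-vertex (main-diagonal) distances —
edges and short diagonals are not diameters.  The eccentricity
coefficient is E = D_max/d_min ≥ 1; interior angles come from the edge
vectors at each vertex, computed after projecting onto the least-squares
plane of the six vertices (planar input passes through unchanged), with
convex hexagons assumed (no reflex handling; noiseless convex rings sum
to 720°).  E and the angles are invariant to rigid motion and uniform
scaling.

For a ring stretched by a factor a along one axis the noiseless map is
E = a/√(a²/4 + 3/4), inverted by `anisotropy_from_eccentricity`.  i.i.d.
vertex noise biases E upward (the max/min of noisy diagonals), so noisy
estimates are validated by a recovery harness — many short trajectories
against one long reference under identical noise — rather than against
the noiseless value.

Aggregation of E over residues 2–14 and ~100 frames: the default averages
residues within each frame and reports mean ± s.e.m. over frame means
(n = frames); pooling all (residue, frame) values (n = residues×frames)
is available by flag.  Both are reported because the appropriate n for a
published mean ± s.e.m. of this kind is ambiguous.  Distributions are
compared with the two-sided Mann–Whitney U test (`scipy.stats`), exact
when n₁+n₂ ≤ 12 and tie-free, tie-corrected normal approximation
otherwise; the angle comparison pools all six vertex-angle series of a
ring into one distribution per condition.

## Detachment forces

Force ramps of nominal slope k·v (100 kJ mol⁻¹ nm⁻² × 1 nm/ns for helix
pulls) are analysed two ways:

- `detachment_force` (per trace): the running peak at the onset of the
  first drop below (1 − drop_fraction)·peak sustained for ≥ dwell
  (defaults 30%, 0.1 ns).  A ramp with no qualifying drop returns an
  explicit "not detected" result, not an exception — a helix may simply
  hold for the whole ramp.
- `divergence_force` (two conditions): the first time the mean traces
  differ by more than n_sd pooled pointwise standard deviations for
  ≥ dwell (defaults 2, 0.1 ns).  The force is read on the **larger** of
  the two traces at that onset — the condition still on the shared
  loading ramp — which is symmetric under swapping the conditions.
  Reading the mean of both instead under-reports by ~20 kJ mol⁻¹ nm⁻¹,
  because the detached condition has already relaxed by the time the
  threshold is crossed.

Mean traces are built on a common grid at the coarsest native spacing
(linear interpolation), with pointwise sd retained.  The running average
is a centred box with shrinking edges; a window below one sample spacing
is the identity (the printed 200 fs smoothing window is shorter than
typical ns-scale trace strides, so it only bites on finely sampled data).

## Synthetic generators

`synthgen` emulates the statistical structure of the MD outputs with
prescribed ground truth; all three generators are bit-reproducible under
a fixed seed.

- **Steered logs**: Euler–Maruyama integration of overdamped Langevin
  motion, dz = (D/kBT)F dt + √(2D dt)·η, friction from the Einstein
  relation.  Step size defaults to half the stability bound
  k·dt·D/kBT < 0.1 and violating steps are rejected.  Steering is 1-D
  along z (the published analysis uses only F_z; lateral confinement is
  not emulated).  In a stationary trap the ion obeys equipartition,
  sd(z_ion − z_trap) = √(kBT/k) = 0.0353 nm at k = 2000; with thermal
  noise disabled the spring force settles to the Stokes drag γ_f·v
  exactly.  The thermal noise amplitude on the recorded force is exposed
  (via T) rather than guessed, since how production runs filtered it
  beyond the 40 ps averaging is unknown.
- **Hexamer rings**: vertices at 0°, 60°, …, 300° on per-residue circles
  (default radius 1 nm, rings offset 0.15 nm along z), x-axis stretched
  by a ≥ 1, i.i.d. Gaussian noise per coordinate per frame; frames
  independent.  Default 100 frames at 0.18 ns spacing, matching a
  ~100-configuration / 18 ns analysis window.
- **Rupture ramps**: force = k·v·t to a per-trace rupture drawn from
  N(mean, sd), then exponential relaxation (τ = 0.05 ns — "abrupt" is
  not otherwise quantified; configurable) to the residual level, plus
  additive Gaussian noise.  The spec-level reachability check is against
  the mean; individual draws are clipped to 98% of the maximum ramp force
  so every trace has exactly one rupture.  Six traces per condition by
  default, one per helix of a hexamer.

What the generators do **not** emulate: lateral ion motion, per-frame
correlation in ring shapes (frames are i.i.d.), force-dependent rupture
kinetics (ruptures are drawn, not Bell–Evans), or solvent/membrane
effects.  Passing tests therefore demonstrate estimator correctness under
the stated statistical model, not fidelity to any particular simulated
system.

## Problem sizes

Test and validation runs are scaled for quick iteration: PMF recovery
uses a 4 nm span at v = 0.1 nm/ns (40 ns of Langevin dynamics, ~6·10⁵
steps), conductance grids use 512–1024 points (grid-doubling changes γ₀
by < 0.5%), eccentricity recovery uses 20 seeds × 100 frames against a
2000-frame reference, and detachment recovery 20 seeds × 6 traces.

## Known limitations

- Absolute conductances of a real channel require its measured PMF
  curves as input; the package validates the transform, not the inputs.
- The MFPT model is single-ion; multi-ion physics enters only through
  the Debye occupancy count, not through ion–ion dynamics.
- Interior angles assume convex hexagons; heavily distorted rings with
  reflex vertices would need a signed-angle treatment.
- The I–V relation is near-linear only for |βqΔV| ≲ 1; fitted slopes
  over wider sweeps are systematically a few percent below the
  small-signal conductance.
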