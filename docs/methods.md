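# Methods

`porodisc` models the intervertebral disk as a fluid-saturated porous
solid and asks two questions: what pair of material parameters —
nucleus elastic modulus `E_NP` and hydraulic permeability `k` — makes a
simulated cyclic-compression test match a measured one, and how does the
disk's fluid–solid interaction change with loading frequency and with
enzyme-induced degeneration.

## Forward model

**Geometry.** An axisymmetric cylinder of radius `R` and height `h`
split into an inner nucleus pulposus (NP) core (radial fraction 0.55 by
default; the split is not measurable from the outside and published disk
models put the NP at roughly a third to a half of the cross-section) and
an outer anulus fibrosus (AF) ring. Each region carries its own porosity
and material parameters.

**Constitutive model.** Quasi-static linear Biot poroelasticity with
incompressible constituents (Biot coefficient 1, infinite Biot modulus):
a linear-elastic drained skeleton (`E`, `ν` per region) plus Darcy flow
with a constant isotropic permeability per region,

    div(σ′ − p I) = 0,   σ′ = C(E, ν) : ε(u),
    ∂(div u)/∂t + div q = 0,   q = −k ∇p.

The two regions are tied (no slip, continuous pressure). The material
pair is constrained the way the inverse analysis uses it:
`E_AF = 1.67 E_NP` and `k_AF = k_NP`, so the identifiable parameters are
exactly (`E_NP`, `k`). Poisson's ratio is not identifiable from a
pressure-controlled axial test and is fixed at ν = 0.3 for both regions
(configurable), mid-range of published disk poroelastic models.

Strains at the 0.8 MPa load peak reach tens of percent on a 3–4 mm
disk; the model is nevertheless small-strain (linear kinematics).  This
is a deliberate trade: the outputs of interest are cycle-level scalars
and trends, and linearity is what makes the inverse analysis cheap and
deterministic.  Its consequences are visible and documented below
(frequency trend of fluid loss).

**Discretisation.** 8-node serendipity quadrilaterals on the meridional
rectangle: quadratic displacement, bilinear pressure on the corners (a
Taylor–Hood-type stable u–p pair), 3×3 Gauss quadrature, backward Euler
in time. Each step solves the symmetric saddle-point system exactly via
static condensation: the displacement block is factored once per
material, and the step reduces to a dense SPD Schur complement on the
free pressure nodes (~160 unknowns at the default mesh), whose inverse
is cached per time-step size. A per-step interior continuity residual is
tracked independently; it stays at machine precision (~1e-16 relative to
the disk fluid volume), which both verifies the linear algebra and
enforces the discrete fluid-mass balance.

**Boundary conditions.** Bottom surface fixed axially, symmetry on the
axis, top surface tied to one master unknown (rigid frictionless platen)
loaded with `F(t) = −P(t)·πR²`. Drainage only on the outer radial
surface, where the pore pressure is clamped at the imposed boundary
pressure (0.3 MPa by default, representing the swelling state); top and
bottom are impermeable, since vertebral bone is orders of magnitude less
permeable than the disk. The solver works in excess pressure
`p̃ = p − p_boundary`, so the pre-swollen equilibrium (u = 0,
p = 0.3 MPa) is the zero state and no artificial initial transient
occurs; absolute pressure is restored on output. A `column` mode (radial
displacement fixed, drainage at the top only) exists for verification
against Terzaghi's 1-D consolidation closed form, which the solver
matches to 0.02% L2 at time factors 0.1–1.0.

**Loading.** The standard test: linear ramp 0 → 0.1 MPa over 60 s, 10
min hold, then sinusoidal cycling 0.1–0.8 MPa. The identification sweep
runs 300 s segments at 0.01, 0.063, 0.1, 0.63, 1 and 6.3 Hz
consecutively in ascending order, carrying the consolidation state
between segments as a sweep test does; an option adds the 10 Hz segment
the experimental rig also ran. The default time resolution is 20 steps
per cycle, i.e. increments of 5, 0.5, 0.05 and 0.005 s at 0.01, 0.1, 1
and 10 Hz (a period must be resolved by at least 10 steps).

**Mesh.** 24 × 6 elements with the radial widths in geometric
progression (ratio 0.8, finer outward). The grading matters: the
pore-pressure boundary layer at the draining surface is ~0.7 mm thick at
the sweep timescale, and a uniform 16 × 6 mesh misestimates cumulative
fluid loss by ~24% while getting displacements right to ~1%. At the
graded default, all four reported scalars (peak-to-peak deformation,
intradiscal pressure, total fluid loss, peak axial effective stress) are
within 0.2% of a 64 × 16 / double-time-resolution reference, and the
suite checks that a 2× refinement in `nr`, `nz` and time moves each
scalar by < 2%.

**Outputs.** Per sinusoid segment, the peak-to-peak platen displacement
over the final full cycle; intradiscal pressure (IDP) as the peak pore
pressure at the nucleus centre over the final cycle; total fluid loss as
the accumulated boundary outflow; maximum axial stress as the largest
compressive effective σ′_zz at any Gauss point over the final cycle.

## Inverse identification (DOE + quadratic response surface)

Given observed peak-to-peak deformations across the sweep, one round:

1. 5 × 5 full factorial over the search window — default
   `E_NP ∈ [1.2, 1.8]` MPa for both groups, `k ∈ [1.56, 2.34]·10⁻¹⁶`
   m⁴/(N·s) for intact and `[1.18, 1.76]·10⁻¹⁶` for degenerated disks —
   i.e. 25 forward sweeps;
2. normalized RMS error per point:
   `100·sqrt(mean_f (sim_f − obs_f)²) / mean_f obs_f` (normalisation by
   the mean observed deformation keeps the measure scale-free);
3. ordinary least squares fit of the six-term quadratic
   `β0 + βE Ẽ + βk k̃ + βEE Ẽ² + βkk k̃² + βEk Ẽ k̃` on factors scaled
   to [−1, 1] (k is of magnitude 10⁻¹⁶; scaling is what keeps the normal
   equations conditioned);
4. exact minimization of the quadratic over the closed box (interior
   stationary point if convex and inside, otherwise the best of the edge
   and corner minimizers; deterministic tie-break);
5. re-simulation at the surrogate optimum. The reported RMS is always
   re-simulated, never read off the surrogate.

The fit is accepted when the re-simulated RMS is below 5%. Otherwise
the window is recentred on the incumbent optimum, widened by 50% per
factor (lower bounds clipped to stay positive), and the round repeats
(5 rounds maximum by default). The incumbent each round is the best of
the surrogate optimum and all DOE points, which guarantees the final RMS
never exceeds the best sampled point. The loop is exposed both as
`backward_identify()` and as the scikit-learn estimator
`DiskParameterIdentifier` (`fit(frequencies, observed)` →
`e_np_`, `k_`, `rms_pct_final_`, `converged_`).

### What is and is not identifiable

A quantitative caveat that shapes every downstream result: with
permeabilities of order 2·10⁻¹⁶ m⁴/(N·s), the disk's consolidation time
constant (`cv = k(λ+2μ)` ≈ 5·10⁻⁴ mm²/s over a 13 mm drainage path) is
tens of hours. Every sweep frequency from 0.01 to 10 Hz is therefore
essentially undrained, and the peak-to-peak deformation varies by only
~0.006% RMS across the entire k window — versus a ~6% RMS change for a
6% change in `E_NP`. Consequently:

- `E_NP` is identified sharply (median recovery error ~2% at 2%
  measurement noise in the shipped recovery study);
- `k` is identified only weakly: noise-free it is pinned by the clean
  residual pattern, but at 2% multiplicative noise the recovered `k`
  scatters across a good part of the window (median recovery error ~11%
  in the same study);
- the re-simulated RMS floor of a converged fit sits at 2–5%, because a
  quadratic fitted to the cone-shaped RMS surface (which is ~|E − E*|
  near its minimum) lands its argmin slightly off the apex.

This is a property of the experiment design (frequency range vs tissue
time constant), not of the optimizer; sharable k information would
require loading slow enough to drain (mHz and below) or a direct flow
measurement.

## Synthetic cohorts

The generator emulates the porcine study's structure: two groups of nine
specimens. Geometry (radius, height, two porosities) and material
(`E_NP`, `k`) are drawn independently per specimen from truncated
Gaussians with the measured group means and SDs (intact: radius
13.18 (0.32) mm, height 4.21 (0.34) mm, porosities 0.80 (0.03) /
0.92 (0.04), E_NP 1.41 (0.17) MPa, k 2.17 (0.36)·10⁻¹⁶; degenerated:
13.29 (0.27), 2.95 (0.28), 0.78 (0.04) / 0.86 (0.05), 1.30 (0.14),
1.39 (0.29)·10⁻¹⁶). Truncation at physical bounds (positive lengths and
moduli, porosities in (0, 1)); no cross-field covariances are emulated
because none are reported. Observations are the forward-simulated sweep
times `(1 + ε_f)` with `ε_f ~ N(0, cv²)` i.i.d. per frequency,
`cv = 0.02` by default — consistent with the 3–4% RMS at which the real
fits land. All sampling is `numpy.random.default_rng`-seeded and
reproducible.

What the generator does **not** emulate: within-disk heterogeneity,
anulus fibre reinforcement and anisotropy, osmotic swelling, specimen
preparation artefacts, or any covariance between geometry and material.
Passing recovery tests therefore demonstrate the *method's* internal
consistency under the stated noise model, not its accuracy on real
tissue.

## Cohort statistics

Porosity is converted from the gravimetric water content `w` and tissue
density `ρ_t` as `φ = w·ρ_t/ρ_w` (AF density 1.06 g/cm³, NP 1.0 g/cm³).
Group comparisons use the pooled-variance (Student) two-sample t-test
with `n₁+n₂−2` degrees of freedom — the variant that reproduces the
published group-table p-values (0.442, 0.248, 0.013, 0.159 and the
<0.001 bounds) from their mean (SD) cells; a Welch test does not. The
discriminability of (E_NP, k) is summarised by a two-group linear
discriminant (pooled covariance, equal priors; scikit-learn behind the
module surface) with resubstitution per-group accuracy, matching the
"k of n correctly classified" style of report; feature scaling is
internal and the classification is affine-invariant.

## Frequency study

The group-mean "representative" disks are run at 0.01, 0.1, 1 and 10 Hz
(preload + cycling), and IDP, total fluid loss and maximum axial stress
are reported normalized to the intact disk at 0.01 Hz. The default
cyclic phase is 300 s; a full hour (36 to 36,000 cycles) is a
configuration flag away but changes only magnitudes, not the normalized
comparisons, at ~12× the cost.

Findings at the shipped configuration, stated as the model produces
them:

- normalized IDP at the nucleus centre is frequency-flat to ~0.05%
  (marginally decreasing: the final-cycle peak sits half a period before
  the segment end, and the consolidating baseline decays over that
  interval, which is longer at low frequency). The boundary layer where
  within-cycle drainage happens never reaches the centre at 0.01–10 Hz,
  so a marked IDP rise with frequency — like a marked fluid-loss fall —
  requires the nonlinear mechanisms outside this model's scope. The
  degenerated disk sits consistently below the intact one;
- total fluid loss of the degenerated disk is roughly half the intact
  value (lower permeability and a thinner disk both slow drainage);
- maximum axial effective stress is nearly frequency- and
  group-independent (≪ 15% variation);
- total fluid loss at fixed duration is *not* a decreasing function of
  frequency in this model: it is nearly flat and mildly increasing
  (mesh-converged values 10.50 / 11.28 / 11.52 mm³ at 0.01 / 0.1 / 1 Hz
  for the intact disk). A zero-mean load oscillation cannot rectify
  into net outflow in a linear poroelastic model; a decreasing trend
  requires nonlinearity (large-deformation kinematics and/or
  strain-dependent permeability), which is outside this package's
  scope. The corresponding acceptance check is intentionally left
  failing rather than weakened, and this is the model-class limitation
  to keep in mind when comparing with experiments.
- relatedly, at these timescales cumulative loss grows roughly with
  √t (early-time consolidation), so loss is not proportional to the
  cyclic-phase duration.

## Numerical choices and degenerate inputs

- Time step: fixed per protocol segment; sinusoids require ≥ 10 steps
  per cycle (guarded), default 20.
- The Schur complement `Q^T K⁻¹ Q + Δt·H` is SPD (H has its Dirichlet
  rows eliminated and the coupling block has full rank); Cholesky is
  used, and the per-step residual check would surface any loss of
  accuracy from the cached explicit inverse.
- Degenerate meshes (nr < 4, nz < 2), non-positive material constants,
  porosities outside (0, 1), degenerate search windows (lo ≥ hi) and
  rank-deficient response-surface designs are rejected with explicit
  errors.
- The quadratic box minimizer enumerates stationary/edge/corner
  candidates in fixed order with a lexicographic tie-break, so
  identification results are bit-reproducible for identical inputs.
- Identified parameters can land on DOE grid points (when a sampled
  point beats the surrogate optimum); this is by construction, see the
  incumbent rule.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own desk-scale defaults: identification runs use
the 6-frequency, 300 s-per-segment sweep at the default 144-element
mesh (~26 forward sweeps, ~25–40 s per specimen); the recovery study
uses 5 synthetic specimens per group at 2% noise; the frequency study
uses the 300 s cyclic phase; cohort-separation statistics use 200 seeded
replicates of 9-vs-9 sampled cohorts (no FE runs needed).

## Known limitations

Small-strain kinematics (see above); constant (strain-independent)
permeability; no anulus fibre reinforcement, anisotropy or osmotic
swelling; rigid impermeable platens instead of explicit vertebrae and
endplates; the NP/AF radial split is a fixed geometric fraction; ν is
assumed, not identified; the weak identifiability of k at 0.01–10 Hz is
inherent to the test design, and identified-k statistics inherit a
dependence on the chosen search windows.
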