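# Methods

This note records the models, the defaults and the numerical choices made
where the design was genuinely open, in enough detail to judge what the
package's tests do and do not demonstrate.

## Scattering models

### Displaced-core core–shell ellipsoid

The complex model is an ellipsoid of revolution: a surfactant-chain core
(equatorial radius `R_core` [Å], axis ratio `ε` = polar/equatorial) inside a
shell of head groups, protein and water of uniform thickness `D_head` [Å].
The core centre may be displaced by `s` [Å] perpendicular to the symmetry
axis, subject to the geometric constraint `s ≤ R₁ − R₂` (the core must stay
inside the shell). The orientational amplitude is

    A(q, θ) = k₁ Φ(q r₁(θ)) + k₂ Φ(q r₂(θ)) J₀(q s sinθ)

and the form factor is `P(q) = ∫₀^{π/2} A² sinθ dθ` (the sinθ weight is
normalised on [0, π/2], so `P(0) = (k₁+k₂)²`).

Two variants are implemented. The default squares the azimuthally averaged
amplitude, so the core self-term carries J₀² — this is the form most
closed-form treatments of displaced two-body scatterers use for this system.
The exact azimuthal average of the *intensity* keeps J₀ only in the
shell–core cross term and is available as `variant="exact"`. The two
coincide at s = 0 and differ by well under a percent at the offsets fitted
here; tests validate each against an independent brute-force orientation
average.

Shell uniformity: demanding shell thickness `D_shell` at both pole and
equator links the axis ratios, `ε₂ = (ε₁R₁ − D_shell)/(R₁ − D_shell)`;
internally the core geometry is primary and
`ε₁ = (ε₂R₂ + D_shell)/(R₂ + D_shell)`.

Numerics: Φ(x) switches to a 4-term Taylor series below x = 10⁻² (the
analytic form loses precision to cancellation); the θ integral uses
Gauss–Legendre quadrature in cosθ, default order 76 — doubling the order
changes model curves by < 10⁻⁶ relative over the fitted q-range for all
studied geometries.

### Random-flight cluster structure factor

Clusters of complexes are described by
`S(q) = 1 + (2/N)·Σ_{k=1}^{N−1}(N−k)xᵏ` with `x = sin(qD_mic)/(qD_mic)`,
`D_mic` the centre-to-centre distance (fixed at 50 Å in all series
protocols). The phase-factor argument uses `D_mic` throughout: only then
does `S(0) = N` hold, which is the quantity's defining property as a mean
cluster multiplicity (a published variant dividing by the shell thickness
instead is treated as a typographical slip). Non-integer N interpolates
linearly between the bracketing integers, preserving `S(0) = N` and
continuity at integers.

### Gaussian chain

Transiently unfolded monomer scattering is the Debye function
`I = I₀·2(e^{−x} − 1 + x)/x²`, `x = q²R_g²`, with the absolute prefactor
`I₀ = c·M·Δρ_m²/N_A`. With c = 2 mg/mL, M = 18 300 Da and the default
mass-specific contrast Δρ_m = 2.0×10¹⁰ cm/g this gives 0.0243 cm⁻¹.

## Absolute scale and composition

All contrast constants live in one JSON table
(`src/saxsflow/data/contrasts_default.json`), overridable per call:
C12 chain volume 350 Å³ (the Tanford convention), SDS head 60 Å³, C₁₂E₈
head 510 Å³, protein partial specific volume 0.735 cm³/g, water scattering
length density 9.42×10¹⁰ cm⁻², electron-based scattering lengths via the
Thomson radius. These defaults reproduce the micelle aggregation numbers
implied by the fitted geometries to within ~1–2% (84.0 for SDS where 85 is
conventionally quoted); the residual discrepancy reflects the volume
conventions and is documented rather than tuned away.

The core is assumed filled exactly by `N_agg = v_core/v_chain` alkyl
chains; the shell holds the `N_agg` head groups, `N_pro` proteins and
filling water (zero excess scattering length, volume only). A shell whose
head-group + protein volume exceeds the shell volume is a hard error —
the geometry is inconsistent with the composition. During optimisation the
evaluator converts that error into a large finite penalty so trust-region
steps recover. The number density follows from the bound-surfactant budget,
`n = C_bound·N_A/10⁶/(N_agg·N_mic)` cm⁻³, so `I(q) = n·P(q)·S(q)` is in
cm⁻¹ with total concentrations held at their pipetted values. Protein mass
consistency (`n·N_mic·N_pro·M` vs the pipetted concentration) is a reported
diagnostic, not a constraint: enforcing it together with the fixed
surfactant budget would over-determine the model when `N_pro` is fitted.

One protocol consequence of this bookkeeping: with the default volume
table, a 10 Å shell cannot host the ~2 proteins per complex of the lowest
SDS condition, so the 2.0 mM series protocol locks `D_head` at its
equilibrium value of 15 Å rather than a thinner average.

## Fitting

Frame fits use trust-region least squares (lmfit) weighted by the frame's
σ, with the goodness of fit `χ²_red = Σ((I−I_fit)/σ)²/(N−p)`. Design
choices:

- **Offset reparameterisation.** `s` is fitted as `u_s = s/D_head ∈ [0,1]`,
  keeping `s ≤ R₁ − R₂` satisfied for any geometry the optimizer visits.
- **Multi-start.** Oscillatory form factors have local minima; the fit runs
  a seeded Latin-hypercube of starts (default 8 for single frames) over the
  free parameters' boxes and keeps the best, never returning a cost above
  the supplied starting point.
- **Warm starts.** Series fits give frame 0 the full budget and start each
  subsequent frame from its predecessor's solution (structures evolve
  smoothly; identical frames are a fixed point).
- **Uncertainties** come from the linearised Jacobian covariance scaled by
  the residual variance.
- **Locking.** Series protocols lock `D_mic` (50 Å), `ε` (end-state value)
  and usually `D_head`; the 4.1 mM condition is a named preset with
  `D_head` and `R_core` free, relaxing from larger initial values.

## Species decomposition

Mass conservation `a₁ = 1 − a₃ − a₄` is substituted before optimisation, so
the free parameters are (a₂, a₃, a₄, a₅) solved by bounded weighted linear
least squares (non-negativity of the fractions is imposed as physically
required; a simplex re-solve handles the rare active `a₃+a₄ ≤ 1`
constraint). The χ² is evaluated in two passes: first with the frame's σ,
then with the basis noise propagated as `σ² = a₁²σ₁² + a₂²σ₂² + a₃²σ₃²`.
The replacement is literal by default; an opt-in flag adds the frame
variance in quadrature, which is the variant whose χ²_red calibrates to ~1
on synthetic data (the literal replacement under-counts total variance and
biases χ²_red upward — both behaviours are asserted in tests). The
chain's R_g follows a schedule: constant 30 Å by default with an optional
larger early-frame value, reflecting that the coil contracts within the
first fraction of a second after mixing. An SDS-micelle basis is
deliberately absent: its curve is nearly collinear with the mixed-micelle
basis, and only the mixed micelles are used.

## Kinetics

Multi-exponential fitting is initialised by variable projection over a
log-spaced rate grid (16 points spanning 0.05/t_max to 3/t_min; amplitudes
and offset are linear given rates, so each candidate rate tuple costs one
linear solve); the four best tuples seed full nonlinear refinements with
rates positive via log-parameterisation, and the best refinement wins. This
avoids the classic collapsed-rates degeneracy. Model order in `auto` mode
grows 1 → 2 → 3 while a nested F-test rejects the smaller model at α = 0.01.
Nearly equal rates are reported through the correlation matrix
(`rates-ill-conditioned` flag), never silently reduced. A window shorter
than 3× the slowest fitted half-time triggers a warning; uniform weights
are the default for spectroscopy traces without stated errors.

## Model-free analysis

Guinier fits (`ln I = ln I₀ − q²R_g²/3`) select a self-consistent low-q
window capped at the conventional `q_max·R_g ≤ 1.3` and then shrink it
while the fitted R_g still drifts beyond its statistical scatter; on smooth
model curves this removes the wide-window bias (sphere R_g accurate to
< 1%), while on noisy data the scatter stops the shrink at the conventional
window. A low-q upturn (apparent R_g in the conventional window exceeding
the doubled-window value by >30%) raises an aggregation warning.

p(r) uses the direct transform `p(r) = (r/2π²)∫qI(q)sin(qr)dq` of smooth
model curves — regularised indirect transforms, needed for noisy
experimental data, are out of scope. The integrand is resampled to a
uniform grid fine enough to resolve `sin(q·r_max)`, extended to q = 0 by
Guinier extrapolation (the missing low-q segment otherwise leaks a ~0.1%
tail that corrupts D_max detection), and damped by a Gaussian window above
0.7·q_max. D_max is the smallest r beyond which |p| stays below 10⁻³ of its
maximum; a negative lobe above 2% of the maximum warns that q_max is too
small.

## Structure scattering

Bead models are one bead per residue at Cα with residue-summed,
excluded-volume-corrected scattering lengths (0.533 e/Da, v̄ = 0.735 cm³/g).
The hydration layer is an explicit approximation: solvent-exposed beads
(neighbour-count criterion at the residue level) gain the scattering length
of a 3 Å water layer at +10% bulk density over a nominal 25 Å² patch; all
parameters configurable. The Debye sum has a `direct` path (exact, the test
oracle is an explicit double loop) and a `binned` fast path (0.1 Å distance
histogram, ~2% accurate through the fitted q-range). Monomer/dimer fitting
is a single bounded scalar because the two theoretical curves are
normalised to the same mass concentration.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical design* of a stopped-flow SAXS
experiment: log-spaced frame mid-times from a 4 ms instrument deadtime,
absolute-scale model intensities, and multiplicative Gaussian noise
`σ(q) = f_rel·I·(1 + (q/q_c)^m)` (defaults f_rel = 1%, q_c = 0.2 Å⁻¹,
m = 2) growing toward high q as counting statistics worsen. Noise is
Gaussian on the reduced curves, not Poisson on raw counts, which is the
appropriate abstraction for data already azimuthally averaged and
background-subtracted.

Unfolding series relax each model parameter exponentially,
`p(t) = p_end + (p₀ − p_end)·2^{−t/t_half}`, from a clustered initial state
(defaults: 4 proteins per complex, 6 complexes per cluster, core offset at
80% of its maximum, relaxation half-times 0.36 s for N_pro and N_mic and
1.38 s for s, matching the fast structural phases of this system); N_pro is
capped at the shell's geometric capacity. Refolding series are exact
mass-conserving mixtures: a burst coil fraction (0.50 at χ_SDS = 0.45, 0.65
at 0.30) appears within the deadtime, the coil folds with an intermediate
half-time (242 s / 101 s) and the remaining complexes convert slowly
(1110 s / 385 s); the mixed-micelle scale is constant. Burst fractions and
trajectory shapes are scenario parameters, not facts — they are chosen to
be qualitatively consistent with the narrative of the underlying study,
whose per-frame fractions are published only graphically.

Because frames are generated *by the same model family that is fitted*,
passing recovery tests demonstrates the correctness and conditioning of the
inference machinery — not that the models are adequate descriptions of any
particular experimental system. Real data add incoherent background,
instrument smearing, inter-particle interference at these surfactant
concentrations, and model misspecification, none of which are simulated.

Every generator writes a machine-readable truth table, and recovery tests
read expectations only from it.

## Problem sizes

Default test and script sizes are desk-scale by design: 200–300 q-points
per frame, 12–60 frames per series, quadrature order 76, 10⁵-cell
brute-force orientation grids, and 4–8 multi-starts for single-frame fits
(1–2 for warm-started series). These sizes hold all assertions with large
margins; heavier settings (more frames, more starts, higher order) are
plain arguments.

## Known limitations

- No polydispersity and no charged-particle interference structure factor;
  the random-flight factor is the only interparticle term.
- The Guinier/p(r) tools target smooth model curves; noisy-data p(r) needs
  regularised inversion not provided here.
- The hydration-layer parameterisation is a stand-in, so absolute bead-model
  intensities carry a few-percent systematic uncertainty.
- Decomposition assumes the basis curves span the mixture; a species whose
  spectrum is not in the basis surfaces only as elevated χ².
- The fitted "±" uncertainties are linearised; strongly correlated
  parameter pairs (e.g. N_pro with R_core at low contrast) can be
  underestimated.
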