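# Methods

## Model and units

Particles are identical spheres of diameter σ and mass m interacting through
a stepwise pair potential: u(r) = +∞ for r < σ, a constant value uᵢ inside
each shell σλᵢ₋₁ ≤ r < σλᵢ (attractive wells have uᵢ < 0), and 0 beyond the
last shell boundary. The pure hard sphere is the zero-shell case; the single
square well has one shell of value −ε out to λσ. All quantities are reduced:
σ = m = kT = 1, so time is σ√(m/kT) and the user-facing ε means βε. The
boundary convention is left-closed: u exactly at r = λᵢσ takes the inner
value; the same convention is used by the event mechanics, which is the only
thing that matters (the choice is measure-zero).

The packing fraction φ = ρπσ³/6 fixes the box: L = (Nπσ³/6φ)^{1/3}.

## Event-driven dynamics

Between events every particle moves ballistically, so a pair's next
interaction is the earliest positive root of |Δr + Δv t|² = d² over the
boundaries d adjacent to the pair's current potential region. Core contact
reverses the radial relative velocity (equal masses exchange radial
components); a shell crossing with potential step Δu either transmits with
(μ/2)v_r'² = (μ/2)v_r² − Δu (reduced mass μ = 1/2) or, when the radial
kinetic energy cannot pay a positive step, bounces elastically. Each pair's
region index is tracked explicitly (an N×N int8 matrix), which makes event
classification robust to roundoff at boundaries and gives an O(1) running
potential-energy ledger.

The production engine keeps one slot per particle holding its earliest known
event, maintained with symmetric pushes (any candidate computed for pair
(i, j) updates both slots if earlier). Slots are refreshed whenever a
particle's trajectory changes, whenever a stored partner collides, and on
cell-boundary crossings: the box is divided into M ≥ 3 cells per side with
cell edge at least the interaction range, pair candidates are drawn from the
27-cell stencil, and a crossing re-examines the new neighbourhood. When the
box is too small for M ≥ 3 (or N < 5) the same kernel runs in all-pairs mode
with predictions refreshed after L/8 of travel, which keeps minimum-image
displacements valid. All particles advance synchronously at each event; the
kernel is numba-compiled and processes 10⁵–10⁶ events/s at desk sizes.

Correctness is established two ways. A pure-Python reference engine
(`ReferenceEngine`) re-derives every event by exhaustive all-pairs search
with no queue and no cells; the optimised engine must reproduce its event
sequence and times (to 10⁻⁹) over horizons short enough that floating-point
chaos has not amplified last-bit differences — hard-sphere dynamics has a
positive Lyapunov exponent, so *exact* long-horizon agreement between any
two arithmetically distinct implementations is impossible, and we do not
pretend otherwise. For long horizons the kernel instead offers a `verify`
mode that, at every processed event, scans all pairs and confirms each
minimum-image distance is consistent with its tracked region to 10⁻⁹; a
missed or misordered event necessarily breaks this invariant. Conservation
(momentum to 10⁻¹³, energy to ~10⁻¹³ relative over 10⁵ square-well events)
and the absence of core overlap in every snapshot are asserted in the suite.

## Schedule: initialisation, equilibration, production

Positions start on randomly chosen sites of the smallest FCC lattice with at
least N sites (overlap-free whenever the lattice constant allows);
velocities are Maxwell–Boltzmann draws shifted to zero total momentum and
rescaled to KE/N = 3kT/2 exactly. One master seed fans out to named
substreams (placement, velocities, thermostat) through `SeedSequence`, and
sweep points derive their seeds purely from (master seed, point index), so
sweeps are reproducible and resumable point by point.

Equilibration runs in two phases: first with the attractive shells switched
off (pure hard spheres) to decorrelate the lattice start, then with the full
potential restored. Each phase monitors the virial pressure over successive
equal windows (default 1 time unit, grown until a window holds at least
10³ events) and stops when the last five window means have relative spread
below 10⁻² *or* below a noise floor of six times the expected window-to-
window fluctuation (the virial fraction of P divided by √window-events).
The floor matters at desk scale: a window's counting noise can exceed 1% at
N ≲ 512 indefinitely, and a spread criterion below the noise floor measures
noise, not drift. A velocity-rescaling thermostat (default) or an Andersen
kick is applied between windows; production is plain NVE, so the ensemble is
canonical only through the initial rescale — the usual DMD compromise, noted
here because square-well dynamics exchanges kinetic and potential energy.

Production records `snapshot_count` frames at equal time intervals (default
0.25 time units, a few collisions per particle per frame at liquid
densities). The full-scale protocol (N = 2¹²–2¹³, 10⁴ snapshots, ~10⁹
collisions, k ~ 10³ sweep points) is available through the same
configuration fields but the shipped defaults are desk-scale; see
"Problem sizes" below.

## g(r) estimation

Minimum-image pair distances are histogrammed into uniform bins of width
Δr = 0.01σ from 0 to r_max and normalised by the ideal-gas expectation
N(N−1)/2 · V_shell/V per snapshot, so g → 1 at large r with no further
calibration. r_max is capped at L/2 (minimum-image validity) and at 6σ;
for an N = 256 sweep reaching φ = 0.45 this gives r_max = 3.33σ. Bins are
half-open; no smoothing or tail correction is applied.

## SVD reduction and polynomial surrogates

The sweep matrix G (k rows of g(r), m > k bins) is factorised by a thin SVD
with a deterministic sign convention (each basis vector's largest-magnitude
entry is made positive). The truncation rank is the number of singular
values above δσ₁ (relative threshold, default δ = 10⁻⁶) or a user-supplied
p. The rank-p reconstruction is the Eckart–Young optimum, and the suite
checks the tail identity ‖G − G_p‖_F = √Σ_{n>p} σₙ².

Coefficient vectors uₙ(θ) are fitted by least squares with degree
deg(n) = n + 3 by default — linear growth with rank, with the offset
exposed (`degree_rule`) because only the growth law, not the absolute
degree, is robust across data sets. Fits use a Chebyshev basis on the
parameter mapped to [−1, 1] for conditioning; coefficients are stored in
the monomial basis of the scaled variable (with the domain alongside), and
`monomial_coefficients` converts a univariate fit to the raw parameter for
reporting. Two-parameter sweeps use a total-degree bivariate basis under
the same rule. The per-rank residual is reported as log₁₀ of the RMS over
the k grid points (the RMS convention is a documented choice; sum-of-squares
is the obvious alternative). The `CompactRepresentation` (grid, domain,
σ₁..σ_p, v₁..v_p, polynomial coefficients, format version) serialises to a
single JSON document and evaluates g̃(r; θ) = Σ σₙPₙ(θ)vₙ(r); evaluation
outside the trained domain raises by default (`strict=False` downgrades to
a warning) because extrapolation quality decays quickly.

## Validation

*Reconstruction error.* E = (1/k) Σ_θ ∫|g − g̃| dr / ∫ g dr with trapezoidal
quadrature over [σ, min(6σ, r_max)] — a normalised L1 "percentage
difference" averaged over the sweep. Dividing by the window length instead
of ∫g dr is available (`normalization="range"`); both are ~equal since
g → 1.

*Structure factor.* S(q) = 1 + 4πρ/q ∫ (g−1) r sin(qr) dr by trapezoid on
the measurement grid (sinc limit at q = 0; optional cosine taper). A g(r)
known only to r_max ≈ 3σ cannot determine S(q) where S is small: truncating
the oscillatory tail of h = g−1 produces ripple of order 0.1 at φ = 0.45 —
verified by transforming the *analytic* PY solution cut to the same window.
`structure_factor_extended` therefore implements the classical
OZ-consistent extension: c(r) = h − γ is short-ranged, so it is set to zero
beyond a cutoff (default 2.5σ) inside the measured window, the measured h
acts as the closure there, and γ is iterated through the OZ relation
(warm-started from the PY solution for stability at high density). The
positivity requirement min S(q) ≥ −10⁻³ is checked on this estimator when
r_max is small; with a 6σ window the plain transform suffices.

*Dilute limit.* At φ ≤ 0.02, g(r) must equal exp(−u(r)/kT); the check
excludes bins within one bin width of a potential discontinuity and the
first two bins above contact.

## Ornstein–Zernike closures

The solver iterates γ = h − c: the closure gives g from γ in real space
(PY: g = e^{−βu}(1+γ); HNC: g = e^{−βu}e^{γ}; RY:
g = e^{−βu}[1 + (e^{f γ}−1)/f] with f = 1 − e^{−αr}, α defaulting to 0.5),
and the OZ relation γ̂ = ρĉ²/(1−ρĉ) closes the loop in Fourier space via
type-I discrete sine transforms on 2¹² points with Δr = 0.005σ, Picard
mixing 0.2 with adaptive halving, convergence at 10⁻⁸ RMS in γ. Grid nodes
landing exactly on a potential discontinuity take the mean of the one-sided
Boltzmann factors, restoring O(Δr²) accuracy across the step. The RY α is a
fixed user parameter; a thermodynamic self-consistency search is not
implemented (the virial and compressibility routes are available separately
for users who wish to tune α by hand).

Accuracy against Wertheim's analytic PY hard-sphere solution: the contact
value (1+φ/2)/(1−φ)² is reproduced to ~10⁻⁴ at φ = 0.3 on the default grid
(quadratic extrapolation to σ⁺ from outside); c(r) matches the closed form
to 10⁻⁴ on r ∈ [0.05σ, σ) at Δr = 10⁻³. The innermost nodes (r < 0.05σ)
are worse — the 1/r factor of the inverse sine transform amplifies grid
error there — a known limitation of the plain DST scheme, irrelevant to
every quantity built from g(r).

## Sweeps and the single-phase guard

Sweep axes (φ, ε, λ) are uniform grids; two-parameter sweeps take the full
Cartesian product in row-major order. Measuring g(r) in a canonical box is
meaningless across a phase boundary, so enumeration rejects state points
beyond the hard-sphere freezing transition (φ ≥ 0.494) and, for attractive
wells, inside a conservative rectangle around the λ ≈ 1.25 liquid–vapour
region: ε ≥ 0.821 (the critical inverse temperature from the Vega
coexistence data) at 0.02 ≤ φ ≤ 0.40. The guard is a plain function the
user can replace with better coexistence data.

## Problem sizes and what the tests show

Shipped study conditions (chosen once for desk hardware): N = 256 and
Δr = 0.01σ for sweeps; 1200 snapshots/point for the k = 32 hard-sphere
sweep over φ ∈ [0.05, 0.45]; 600 snapshots/point for the matched k = 8
λ ∈ [1.05, 1.45] versus φ ∈ [0.10, 0.40] square-well contrast sweeps at
ε = 0.5 (supercritical, single phase throughout); N = 512 for the
equation-of-state check and N = 500 for the dilute-limit check.

At these sizes the statistical noise floor of the singular spectrum sits
near σ/σ₁ ≈ 2×10⁻³ (per-bin noise divided by √k): four components rise
clearly above it with mutual ratios ≥ 3, the fifth reaches the floor, and
smaller ones are pure noise. Larger N and more snapshots push the floor
down and expose further components; the desk-scale tests therefore
demonstrate the *mechanism* — sharp spectral decay for φ- and ε-sweeps,
slow decay and an order-of-magnitude worse 5-vector reconstruction for
λ-sweeps, S(q) positivity of rank-5 reconstructions, sub-percent
reconstruction error — not the ultimate accuracy attainable with 2¹³
particles and 10⁴ snapshots. The dilute and EOS checks validate the
mechanics against exact and quasi-exact references (Boltzmann factor,
Carnahan–Starling, Wertheim) rather than against other simulations.

Synthetic-data caveats: the generator *is* the simulator here (no external
data exists); what the tests do not probe are finite-size corrections
beyond N ≈ 512, the deep supercooled/metastable region excluded by the
phase guard, and continuous potentials.

## Known limitations

- NVE production after a rescale thermostat approximates the canonical
  ensemble; kinetic-temperature fluctuations are those of the
  microcanonical ensemble.
- Canonical-ensemble g(r) carries the usual O(1/N) sum-rule bias; at
  N = 256 this is visible as a ~1% depression of the far tail and is part
  of the desk-scale error budget.
- The OZ-extension estimator for S(q) inherits the c-cutoff assumption;
  it is exact only insofar as the true direct correlation vanishes beyond
  2.5σ (excellent for hard cores and short wells).
- The brute-force reference engine's L/8 refresh horizon assumes
  interaction ranges well inside L/2, satisfied for every configuration it
  is used on (N ≤ 32 test systems).
- λ-sweep compact models are supported but inherently inaccurate near
  r = λσ (Gibbs-type undershoot at the moving discontinuity); use dense
  λ grids or per-λ models instead.
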