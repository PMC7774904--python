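# Methods

## The model and its assumptions

The network couples a non-diffusing transcription factor (Pax6, P), two
secreted morphogens (follistatin F and Tgfβ2 T), their 1:1 sequestration
complex (C) and a membrane receptor signalling complex (B). The governing
reaction terms are listed in the README. Assumptions worth making
explicit:

- **Inhibition acts on activity, not abundance.** Receptor-activated
  Smad3 blocks Pax6–DNA binding, so every transcription term — including
  Pax6's own autoregulation — uses the effective activity
  P* = P/(1 + βB). There is no separate transcriptional-repression term.
- **Sequestration is reversible** (k_off > 0). The irreversible
  alternative (k_off = 0, which would instead require D_T > D_F) is
  expressible through the parameter file but is not the default.
- **Complex decay destroys both constituents.** δ_C removes F and T
  bound in C without release; ligand recovery happens only through
  k_off. This keeps the transport-only conservation laws (F+C and
  T+C+B) exact and testable.
- **Only F, T and C diffuse.** P is intracellular and B is
  membrane-bound. The reference set satisfies D_C ≫ D_F = D_T: the
  Fst:Tgfβ2 complex outruns free Fst, the network's key (and
  deliberately counter-intuitive) transport assumption. Slow monomer
  dispersal is attributed to matrix/cell-surface binding whose
  interaction surfaces are shielded in the complex.
- **1:1 stoichiometry**, mass-action binding, first-order decay
  everywhere; receptor conservation (free = R_tot − B) is structural.
- **Units are arbitrary but internally consistent** (space, time,
  concentration); nothing is fitted to measured rate constants.

Model variants: A freezes P (a prescribed regional source drives the
morphogens); B/C are the full self-organising network (1D line / 2D
explant capsule — identical kinetics); D multiplies Pax6 production by
h = 1/(1 + γS) with a static Shh field S. Loss-of-function mappings:
`tgfb_lof` → β = 0 (Smad3 inhibitor SIS3), `shh_lof` → γ = 0
(cyclopamine), `double_lof` → both.

## Reference parameter set

No published numeric parameter set is available for this network, so the
shipped reference values (`src/pax6rd/configs/reference_params.yaml`)
were located by a randomised log-uniform sweep over the kinetic space
(the same procedure is exposed as the `sweep` CLI verb) subject to, in
order of application:

1. the Pax6-only reaction (β = 0) is monostable — required so that the
   double-LOF network relaxes to a uniform state rather than freezing
   patches of a bistable switch; with n = 2, K = 1 this needs
   σ_P ≳ 0.15·ρ_P (the shipped set uses σ_P = 0.13·ρ_P, checked
   numerically);
2. the full homogeneous steady state is linearly stable without
   diffusion;
3. with the shipped diffusivities (D_F = D_T = 0.01, D_C = 1) a finite
   band of wavenumbers grows (Turing instability), and the instability
   vanishes entirely when D_C is lowered to D_F — differential complex
   diffusion is necessary, not merely helpful;
4. the nonlinear end states behave like the biological readouts at the
   shipped domain sizes: one pole per baseline domain across seeds,
   pole-count scaling with length, explant repolarisation, Shh
   orientation, and the LOF truth table.

The winning set was rounded to three significant figures and re-verified
before freezing. Headline linear properties: steady state P ≈ 0.98,
growth-rate maximum 0.092 at k = 3.32, pattern wavelength λ ≈ 1.89,
instability band k ∈ [1.2, 9.8] (wavelengths ≈ 0.64–5.3).

### Oscillatory regime: a negative result

The unstable band of the reference set is stationary (all growing modes
have zero frequency), and β controls its width: a 10% increase in β
leaves a stationary Turing band; a 20% increase stabilises the system.
We looked hard for a parameter regime whose *leading unstable mode is
oscillatory* (a wave/oscillatory-Turing classification) while preserving
requirement 3 above, and concluded it does not exist in this topology:
across ≈65,000 randomly sampled kinetics plus four directed strategies
(slowed receptor loops; complex-return delay tuning; eigenvalue
sensitivity continuation along directions that raise the complex pair's
growth while keeping it rising in k²; and a 30,000-sample algebraic
screen of the sequestration-as-sink subsystem) no compatible oscillatory
instability was found. The structural reason: the immobile (P, B) block
of the Jacobian is triangular (the receptor's kinetics do not read Pax6
directly), so any oscillation must run through the diffusible ligand,
and removing the complex at finite wavenumber — the only effect that
distinguishes D_C > D_F from D_C = D_F — consistently damps the
P→T→B negative loop instead of destabilising it. Transient or
sustained oscillations during pattern formation therefore do not occur
for the reference set, and the β oscillation-control experiment in
`scripts/acceptance.py` reports the (negative) classification outcomes
honestly rather than asserting them.

## Numerics

- **Discretisation.** Second-order central differences on regular,
  cell-centred grids. Zero-flux boundaries mirror across the cell face
  (the ghost value equals the boundary cell), which makes the discrete
  boundary flux exactly zero and conserves mass to round-off; the same
  mirror rule handles arbitrary masked 2D domains point-by-point.
  Dirichlet (fixed-value) boundaries are deliberately not implemented:
  zero-flux matches isolated explants in defined medium.
- **Time stepping.** Explicit Euler with an enforced diffusive bound
  dt ≤ dx²/(4·max D) and a reaction-resolution cap
  dt ≤ 0.2/(fastest linear rate). The hot loop is a numba-compiled
  kernel operating on flattened in-domain points with precomputed
  neighbour tables; a pure-numpy path implements the identical update
  and the test suite asserts float-identical agreement between the two.
  An independent brute-force Euler loop at dt/10 serves as the
  integration oracle in the tests (agreement to better than 1e-4
  relative).
- **Negativity.** Fields are clamped at zero; excursions below −1e−9
  are counted and reported in the result metadata, and tests assert the
  reference runs never trigger them.
- **Steady state.** The five algebraic balances reduce to a scalar root
  problem in P (the morphogen/receptor balances solve in closed form
  given P*, with an inner damped fixed point for the β feedback); the
  root is bracketed on a downward scan so the Pax6-positive branch is
  selected, and verified against damped pseudo-time iteration in tests.
- **Dispersion relation.** Eigenvalues of J − k²·diag(0, D_F, D_T,
  D_C, 0) on a log-spaced k grid from 2π/(10L) to the two-cell Nyquist
  wavenumber; an analytic Jacobian is cross-checked against central
  finite differences. Classification uses a ±1e−9 dead-band around zero
  growth so round-off cannot flip a label.
- **Grid convergence** is assessed with a deterministic smooth
  single-mode initial perturbation reproduced identically at both
  resolutions. (Seeded-noise runs are unsuitable for this check: the
  final pole position is an attractor choice, and comparing different
  noise realisations — or the same noise at different dt — measures
  basin boundaries, not discretisation error.)

## Scenario geometry and initial conditions

- **Baseline 1D domain: L = 1.2 ≈ 0.63λ** (32 cells). Under zero-flux
  boundaries the domain-filling mode cos(2πx/L) at L = λ has maxima at
  *both* ends, and that two-end-pole state is a genuine attractor
  (measured basin ≈20% over 20 seeds, stable to t = 500). A baseline at
  the single-spot scale — below the two-pole mode, matching the small
  collapsed explants the network is meant to describe — yields exactly
  one pole for every tested seed (20/20). Pole-count scaling runs use
  L ∈ {1, 2, 4}·λ explicitly.
- **Explant: 2:1 capsule, long = 0.7, short = 0.35** (dx = 0.04,
  ≈142 interior cells). The short axis sits below the instability
  band's half-wave cutoff (π/k_max ≈ 0.32) so the initial
  proximal-distal (short-axis) pre-pattern is unstable, and the pattern
  swings onto the long axis — the re-polarisation phenomenon. A capsule
  (rectangle with semicircular caps) gives an unambiguous long axis; an
  ellipse is available.
- **Noisy homogeneous IC:** P = P*(1 + ε), ε ~ Uniform(−a, a) i.i.d.
  per cell with a = 0.05 by default (only Pax6 is noisy; the other
  species start at steady state). The amplitude and distribution are
  this package's choice — 5% is small enough to stay in the linear
  regime yet seeds every mode.
- **Pre-pattern IC:** P graded linearly (or stepped) along the chosen
  axis with the other species in pointwise quasi-steady state given P,
  plus a small seeded multiplicative jitter (2% in the canonical
  repolarisation config). The jitter is necessary as well as realistic:
  an exactly axis-symmetric initial condition can never break symmetry
  in a deterministic solver.
- **Shh field:** static, linear by default, graded along the explant's
  long axis from `peak` at the ventral end to zero; `inverted` swaps
  ends; peak = 0 encodes Shh LOF. Default peak 1.0 with γ = 1 halves
  Pax6 production at the ventral end — a strong but not saturating cue.
- **Variant-A source:** P fixed at high level in the central third of
  the line, low elsewhere.

## What the synthetic scenarios do and do not emulate

The scenarios reproduce the *logical structure* of the explant and
gradient experiments: geometry, initial polarity, presence/absence and
orientation of the Shh cue, and the pharmacological switches. They do
not emulate tissue growth or deformation (domains are static), cell
movement, transcriptional delay or molecular noise during the run
(noise enters only through initial conditions), 3D geometry, or any
quantitative correspondence to measured concentrations — all units are
arbitrary. Passing tests therefore demonstrate that the proposed
network topology with the stated transport assumptions *can* produce
the observed class of behaviours, not that the embryo uses these
parameter values.

## Outcome metrics

Poles are connected supra-threshold components (threshold halfway
between in-domain min and max; 4-connectivity in 2D; wrap-aware on
periodic lines; components touching the boundary count in full), with a
5% relative-contrast dead-band below which a field is "uniform" — the
separation between numerical ripple and genuine pattern, surfaced as a
parameter. The polarisation index is |r_cm − r_geo|/R_max
(intensity-weighted centroid offset over the maximal centroid-to-edge
distance; R_max = L/2 in 1D), its angle measured from the +x axis with
y pointing down. Outcome classes: uniform (0 poles), polarised (1),
multipolar (≥2). Oscillation detection linearly detrends a probe-point
series and requires ≥3 alternating extrema with prominence above 5% of
the detrended range.

## Problem sizes

Shipped analyses use 32–192-cell lines and a ≈142-interior-cell
explant raster, with runs of 100–500 time units — sizes at which every
qualitative behaviour above is already stable and the full canonical
suite completes in about a minute on a single core. Halving dx changes
the final polarisation index by ≈1.5%, within the 2% convergence
target.

## Known limitations

- The governing equations encode the published interaction topology in
  the simplest consistent functional forms; other implementations of
  the same network may differ term-for-term.
- The oscillatory (wave-instability) regime discussed above is
  unreachable under the differential-diffusion constraint in this
  topology; oscillation-dependent behaviours cannot be reproduced.
- Explicit Euler is robust but first-order; stiff parameter corners
  (very large k_on·R_tot) shrink the usable dt through the
  reaction-resolution cap rather than failing gracefully.
- Mode selection near attractor-basin boundaries (e.g. domains close to
  integer multiples of λ) is genuinely stochastic across seeds; the
  shipped baseline sizes were chosen away from those boundaries.
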