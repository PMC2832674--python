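# Methods

## Scope and model

`crowdbd` simulates solutions of rigid macromolecules at cytoplasm-like
densities and analyses the resulting trajectories. The physical model
is deliberately minimal and follows the established rigid-body BD
methodology for crowded protein solutions:

* **Rigid bodies.** Every molecule type is a fixed arrangement of atoms
  (positions, radii, partial charges) in a body frame whose origin is
  the geometric centre of the atoms; rotations and torques are taken
  about it. Internal flexibility, reactions and hydrodynamic
  interactions are outside the model.
* **Overdamped dynamics.** The Ermak–McCammon propagator advances each
  body by the deterministic drift `(D⁰/kT)·F·Δt` plus an isotropic
  Gaussian displacement of variance `2 D⁰ Δt` per component, for both
  translation (Å²/ps) and rotation (rad²/ps, axis–angle increment
  applied to the rotation matrix, re-orthonormalized by SVD every 1000
  steps). `D⁰_trans`/`D⁰_rot` are *inputs* per molecule type; the
  package estimates them by Stokes–Einstein,
  `D⁰_trans = kT/(6πηR)`, `D⁰_rot = kT/(8πηR³)`, on a user-supplied
  hydrodynamic radius (default estimate: 1.29 × radius of gyration,
  floored at the bead radius for single beads) with η = 0.89 cP and
  T = 298.15 K by default.
* **Energy model.** Three modes. `steric`: a purely repulsive
  `ε_rep (r_m/r)¹²` between exposed heavy-atom pairs. `full`: a 12-6
  Lennard-Jones form `ε_LJ[(r_m/r)¹² − 2(r_m/r)⁶]` (minimum −ε_LJ at
  r_m), a single global contact distance r_m (default 5 Å) and a single
  well depth ε_LJ (default 0.285 kcal/mol) applied to all pairs — the
  model's one adjustable parameter — plus electrostatics.
  `steric_elec`: repulsion plus electrostatics. Short-range terms use a
  12 Å cutoff with no shift or switch (the discontinuity at the cutoff
  is ≤ 1e-3·ε for r_m ≤ 5.5 Å) and an exposed-atom pair list rebuilt
  every 40 steps (configurable skin).
* **Electrostatics.** Each type carries two scalar potential grids in
  its body frame (fine 2 Å grid covering a 20 Å shell beyond the
  surface; coarse 4 Å grid extending ≥50 % further per axis) and a
  reduced set of effective charges. The pair energy is the symmetrized
  average of "charges of i in the grid of j" and vice versa, with
  trilinear interpolation (fine grid where the point lies inside it,
  else coarse, else zero — benign because the Debye length at 150 mM is
  ~7.8 Å) and forces from the interpolant's analytic gradient.
  Symmetrization guarantees E(i,j) = E(j,i) and pairwise
  momentum conservation. Grids can be imported from an external
  Poisson–Boltzmann solver in OpenDX format; internally generated grids
  use Debye–Hückel screened Coulomb potentials (Coulomb constant
  332.06 kcal·Å/(mol·e²), solvent dielectric 78.0, 1:1 salt), with the
  source distance clamped at the atom radius so nodes inside the
  molecule stay finite.
* **Effective charges.** Fitted by linear least squares so that their
  screened-Coulomb field matches the grid over a shell of nodes whose
  distance to the nearest atom surface lies in [3, 11] Å; sites default
  to the charged-atom positions (k-means-reduced when `n_sites` is
  given). The relative RMS misfit is stored on the result; a
  rank-deficient system falls back to a ridge solve with a warning.
* **Exposure.** An atom is solvent-exposed iff any of 960
  golden-spiral sample points on its probe-inflated sphere (4 Å probe)
  lies outside all other inflated spheres; hydrogens are never flagged.
  Only exposed atoms enter short-range interactions, pair lists, the
  hard core and contact analysis.
* **Hard core.** After each trial step, any exposed-atom pair of
  distinct molecules closer than 4.5 Å (configurable; hard-sphere
  fluids use 2r) marks its molecules as offenders; their stochastic
  displacements are resampled (drift kept) up to 100 times, then the
  stragglers revert to their previous pose, iterating the revert until
  the configuration is clash-free. Resample-then-revert approximately
  preserves the equilibrium distribution at small Δt; with zero forces
  it is a valid equilibrium sampler for hard-sphere fluids.

Defaults mirror the conditions the methodology was built for: timestep
2.5 ps, poses recorded every 100 ps (40 steps), pair-list refresh 40
steps, cubic periodic box with minimum-image geometry, kT = 0.5925
kcal/mol at 298.15 K.

## Analysis stack

**Translation.** `D_trans(δt) = MSD(δt)/(6 δt)` averaged over all
molecules of a type and all time origins (maximum-overlap origins;
replicate SDs only across independent trajectories). The anomality
exponent is the numerical log-derivative
`α = 1 + Δln D/Δln δt` evaluated at logarithmic midpoints
`δt_mid = √(δt_k δt_{k+1})` of the 100, 200, 300, 600, 1000, … ps
ladder (reported rounded to whole ps: 141, 245, 424, …). α(δt) is
fitted with the empirical form

    α(δt) = α₀ − a e^(−δt/τ_short) − b (e^(−δt/τ_long) − e^(−δt/τ_short)),

after truncating at the first point whose replicate percent error
exceeds ~25 %. The fit parametrizes `τ_long = τ_short(1+g)`, g > 0, so
the timescale ordering holds by construction, and multi-starts over the
timescale decades because the short-time component's effective
amplitude (a − b) can be small and the objective correspondingly flat.
The asymptotic coefficient integrates
`ln Dᴸ = ln D(100 ps) + ∫(α−1) d ln δt` decade by decade until the
increment falls below 1e-4 (cap 1e9 ps).

**Rotation.** `θ(δt)` is the body-axis autocorrelation averaged over
the three axes (= tr(R₀ᵀR_δt)/3), molecules, and origins; a free
isotropic rotor decays as `exp(−2 D⁰_rot δt)` (rank-1 axis convention).
Transiently anomalous rotation is fitted, with uniform weighting, by

    θ(δt) = e^(−δt/τ_rot) · e^(−a (1 − e^(−δt/τ_rel))),

whence `Dᴸ_rot = 1/(2τ_rot)` and the initial-slope coefficient
`Dˢ_rot = ½(1/τ_rot + a/τ_rel) ≥ Dᴸ_rot`. For a pure exponential, a
and τ_rel are individually unidentifiable; the meaningful combination
a/τ_rel → 0 and Dˢ = Dᴸ.

**Relative viscosities.** `η_rel^T = D⁰_trans/Dᴸ_trans` (experiments
measure translation over µs–s) and `η_rel^R = D⁰_rot/Dˢ_rot`
(fluorescence depolarization sees the ns decay). The literature
comparison implements `η_m/η₀ = exp(Ac/(1−Bc))` with the HSA constants
A = 2.7×10⁻³, B = 1.3×10⁻³ ml/mg, and the empirical exponents 1.28/0.44
mapping macroscopic to translational/rotational effective viscosity.

**Neighbors.** Two molecules are neighbors when any exposed-atom pair
is within 12 Å (minimum image). Survival S(δt) counts the fraction of
the origin's neighbors present again at δt — present-at-δt, with no
continuity requirement between the endpoints, which makes the estimator
insensitive to the 100 ps recording granularity — and is fitted with
`A_f e^(−δt/τ_fast) + (1−A_f) e^(−δt/τ_slow)`, τ_slow > τ_fast by
parametrization; collapsing timescales or a vanishing amplitude
degrade to a single exponential with a warning. The shed count fires
one event whenever the live neighbor set first shares no member with
the reference set, then resets the reference; empty shells do not fire
(losing everyone to dilution is not a replacement). This is one
concrete realization of a "complete neighbor-exchange" count; other
conventions would shift absolute values but not trends.

**Widom insertion.** `ΔG = −RT ln⟨e^(−E_int/RT)⟩` over uniform random
positions and orientations in the snapshot box; clashes contribute
`e^(−∞) = 0` to the average but stay in the denominator. Steric
scoring is binary (clash/no-clash ⇒ `ΔG = −RT ln(accepted/attempted)`);
full scoring evaluates LJ + grid electrostatics for non-clashing poses,
with a hard-core clash still scoring +∞ so the Boltzmann average stays
bounded. Two clash conventions are provided: the 4.5 Å fixed
atom–atom threshold used during dynamics, and a `radii` rule (clash
when centre distance < r_i + r_j) giving true hard-sphere contact —
required whenever atom radii, not a uniform 4.5 Å shell, define the
excluded volume, as in the scaled-particle-theory validation and the
bead-vs-sphere-fluid cycle calculations. Energy histograms can be
smoothed by a 3-Gaussian mixture fitted to the 0.25 kcal/mol-binned
density (components initialized from sample quantile slices); the
Boltzmann average is then analytic per component,
`w_i exp(−μ_i/RT + σ_i²/(2RT²))`, scaled by the acceptance fraction,
falling back to the raw estimator when the fit fails or samples are
few.

**Thermodynamic cycles.** Folding: `ΔΔG = −(ΔG_ins(folded) −
ΔG_ins(unfolded))`, positive = folded state stabilized by the crowded
environment; the unfolded leg pools equal trial counts over every
ensemble conformation into one Boltzmann average. Association inserts
all components simultaneously with independent poses; placements with
inter-component contacts below the hard core are resampled and not
counted, because that interaction appears identically in the dilute
reference leg and cancels from the cycle. Uncertainties are standard
deviations across snapshots (the final frames of independent runs).

**Scaled particle theory.** For a solute of radius r in a hard-sphere
fluid (radius a, packing y, x = r/a):

    βW = −ln(1−y) + 3xy/(1−y) + x²[3y/(1−y) + 9y²/(2(1−y)²)]
         + x³ y(1+y+y²)/(1−y)³,

exact in the point limit. Monte Carlo insertion into equilibrated
sphere fluids reproduces it within across-snapshot Monte Carlo error —
the package's primary end-to-end correctness check.

## Synthetic systems

All tests run on generated systems; no external data are read.

* **Hard-sphere fluids** — n identical neutral spheres, hard core and
  contact distance 2r, `ε_rep = 0` so equilibration is free diffusion
  plus hard-core rejection. Initial placement is random sequential
  insertion; because RSA configurations are not the equilibrium
  hard-sphere ensemble, insertion measurements use snapshots after a
  BD equilibration long enough for mixing over a particle diameter
  (≥1500 steps at r = 10 Å).
* **Bead proteins** — touching-bead chains or FCC-compact globules with
  optional per-bead charges; the bead charges double as the effective
  charges, which is exact for the internally generated screened-Coulomb
  grids. Mass derives from bead volume at 0.73 ml/g.
* **Unfolded coils** — self-avoiding freely jointed chains at fixed
  bond length (default touching), regenerated on self-avoidance
  failure. This stands in for statistical-coil ensembles of unfolded
  proteins: it reproduces qualitative features (Rg growth with chain
  length, excluded-volume statistics) but no sequence-specific
  dimensions, so cycle results on these fixtures demonstrate
  directionality and estimator correctness, not protein-specific
  magnitudes.

What desk-scale tests show — and what they do not: the validation
systems are tens to hundreds of molecules for nanoseconds to
microseconds of simulated time, enough to verify the propagator's
statistics, the estimators against closed forms, and crowding
directionality. They do not reproduce headline many-type cytoplasm
results (e.g. ten-fold GFP slow-down or kcal-scale folding shifts at
275 g/l with atomically detailed molecules), which required ~1000
molecules for tens of microseconds at cluster scale with curated
structure inputs.

## Numerical choices

* Coulomb constant 332.06 kcal·Å/(mol·e²); kT = 0.5925 kcal/mol at
  298.15 K; Debye κ from `κ² = 8π λ_B I N_A ×10⁻²⁷` (λ_D ≈ 7.8 Å at
  150 mM).
* Minimum image maps components to (−L/2, L/2]; pair lists come from a
  periodic KD-tree on wrapped coordinates.
* LJ distances below the hard core are clamped to it during scoring
  (the dynamics keeps them out separately).
* Trajectories are plain text (`repr` floats, bit-exact round-trip);
  states serialize to JSON including the RNG bit-generator state, so a
  reloaded run continues bit-identically.
* One RNG stream per simulation, seeded explicitly; fixture generators
  and insertion runs take their own seeds. Hard-core resampling draws
  from the same stream, so trajectories are deterministic per seed.
* Tracers: 8 copies go to the octant centres (±L/4 per axis, first at
  (L/4, L/4, L/4)); other counts place uniformly at random.
* Degenerate inputs raise: empty PQR, non-positive radii/viscosity,
  spacing ≤ 0, schedule outside the trajectory span, packing
  infeasibility (with the achieved fraction), undersampled insertion
  legs.

## Known limitations

No hydrodynamic interactions (free-draining BD); isotropic diffusion
tensors; a single global LJ contact distance rather than per-atom
parameters; internal electrostatics are linearized Debye–Hückel (use
OpenDX import for nonlinear PB fields); no electrostatic desolvation
or many-body hydrophobic terms; the shed-count and survival
definitions are stated conventions among several defensible ones.
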