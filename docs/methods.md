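# Methods

## Model

Particles are independent point walkers in a closed rectangle
`[0, W] × [0, H]` (default 1.0 × 0.45 μm, the aspect ratio of an
*E. coli* cell). Each epoch of length `dt` (default 50 μs) every
particle moves along each axis by an independent draw from the uniform
distribution U(−S, S), where the step limit is set by the diffusivity
at the particle's current position:

    S(x) = sqrt(6 · D(x) · dt).

The uniform distribution has variance S²/3 = 2·D·dt per axis, so free
diffusion accrues MSD 4·D·t in 2D and the nominal diffusivity is
recovered as an emergent property of the trajectories. Sampling at the
*departure* point makes the walk non-anticipatory — the Itô
interpretation of multiplicative noise. The step limit is held fixed
for the whole step even if it crosses a diffusivity interface; there
is no sub-step interface handling, which is exactly the Itô rule at
the resolution of the timestep. Walls reflect via the mirror-image
rule, applied repeatedly (implemented in closed form as a period-2L
triangle wave), which conserves particle number exactly.

Consequences probed by the assays:

* **Lensing.** At steady state the Itô walk concentrates particles in
  low-diffusivity zones, c(x) ∝ 1/D(x). This is *convention-bound*:
  the companion grid solver exposes the full α-family (see below).
* **Interactions.** With the neighbor-sensing rule the per-particle
  step limit becomes S_eff = S·exp(−k·n), with n the number of other
  particles within a cutoff distance (closed ball) measured
  synchronously at the start of the epoch. This is an effective
  attraction: crowded particles slow down and crowds self-reinforce.

## Convention-parameterized grid solver

The 1D Fokker–Planck forms for the Itô (α = 0), Stratonovich
(α = 1/2) and isothermal (α = 1) conventions are advanced as the single
conservative family

    ∂c/∂t = ∂x( D(x)^α · ∂x( D(x)^(1−α) · c ) ),

with fluxes on cell faces (face coefficient = arithmetic mean of the
adjacent D^α) and zero-flux ends. The discrete steady state of this
scheme is exactly c ∝ D^(α−1) on the grid — the printed steady-state
relation c·D^(1−α) = const — so spatial discretization error vanishes
at steady state and convergence is limited only by relaxation time.
Mass is conserved to round-off (asserted < 1e-8 relative in tests).
The timestep is checked a priori against the von Neumann bound
dt ≤ dx²/(2·max D) and the solver refuses to run otherwise. Reference
grid settings are dx = 1e-3 and dt = 5e-7 in dimensionless units; the
Gaussian-well profile used in tests is D(x) = 1 − 0.5·exp(−(x −
0.25)²/(2·0.05²)) on a 500-cell domain [0, 0.5], chosen so the slowest
relaxation mode equilibrates in a few × 10⁵ steps at the reference dt.

## Granule packings

Low-diffusive granules are non-overlapping closed discs of common
radius r; diffusivity is μ_ratio·μo inside any disc and μo outside
(membership at the boundary counts as inside, used consistently by the
field lookup and the dwell-time assay). Defaults: r = 0.01 μm,
φ = 0.6, μ_ratio = 0.05, μo = 5 μm²/s.

Placement: below φ = 0.6, random sequential adsorption (uniform
candidate centers, rejecting overlap and wall violation, capped at 10⁶
attempts with a deterministic failure mode). At or above φ = 0.6 — past
the practical RSA saturation density (~0.55 for discs) — discs start on
a touching hexagonal lattice (the 2D close packing), a random subset of
sites is selected to hit the requested φ, and positions are jittered
for 100 sweeps of per-disc displacements drawn uniformly from a disc of
radius 0.1·r, accepted only when all invariants hold. Jittering
measurably reduces the fraction of nearest-neighbor distances pinned at
the lattice spacing. Achieved φ is validated to ±0.02; when single
discs are so large that achievable φ is quantized more coarsely than
that (e.g. r = 0.1 μm in the default region, where one disc covers 7%
of the area), the tolerance widens to half a disc-area fraction.
Requests at or above the hexagonal limit π/(2√3) ≈ 0.9069 are rejected
as infeasible. Packings can be frozen to a CSV of (x_center, y_center,
radius) and reloaded.

Membership queries run on a uniform-grid candidate table (cell size
2r) rather than a KD-tree; the same static geometry is queried every
epoch, and the vectorized table lookup is the engine's hot path.

## Assays

**MSD.** Ensemble convention: the squared displacement of each
particle from its own position at lag zero, averaged over particles;
SEM is across particles. (A time-averaged per-trajectory MSD is the
other common convention; the ensemble form matches curves computed
over many independent trajectories.) The fitted diffusion coefficient
is the least-squares slope over a stated pre-saturation window divided
by 4. The saturation MSD is the mean over the trailing quarter of
lags, guarded by a flatness check; for a closed box it tends to
(Lx² + Ly²)/6 — the sum of twice the per-axis uniform variances —
independent of D (≈ 0.2004 μm² for the default region).

**FRAP.** After a burn-in to steady state, every particle inside a
circular ROI (default radius 0.2 μm) is instantaneously and permanently
labelled bleached; bleached particles keep diffusing and keep counting
toward crowding — photobleaching alters fluorescence, not mobility.
The recovery curve counts unbleached particles in the ROI each epoch.
Normalization is the steady-state unbleached ROI count of a *matched
uniform-diffusivity run* at the bulk diffusivity (the standardized
background), taken as the mean over the trailing quarter of the
reference recovery. t½ is the first time the normalized curve, after a
5-frame moving average, reaches 0.5; curves that never reach 0.5 are
reported censored (absent value plus flag, never a sentinel).

Replicates: three ROIs centered on the long-axis midline at
x = 0.25, 0.5, 0.75 μm. With the 0.2 μm ROI radius three disjoint ROIs
cannot fit on a 1 μm axis, so replicate ROIs partially overlap in
space; each is bleached in an independent recovery continuation of the
shared equilibrated state (separate RNG streams), so replicate bleach
events never interact. Summary statistics pool 3 ROIs × 3 seeds.

**Dwell times.** A dwell episode is a maximal run of consecutive
recorded frames with the particle inside any disc; an episode of k
frames counts k·(frame spacing) seconds against a total observation
time of n_frames·(frame spacing), so a particle resident for a whole
run has normalized fraction exactly 1. With no granules the statistics
are reported absent rather than zero.

**Local density / clustering.** Per-particle neighbor counts within
the interaction cutoff, normalized by the mean count of the uniform
initialization. The uniformity control uses a χ² test across axis bins.

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| dt | 5e-5 | s | 50 μs epoch |
| D (bulk, μo) | 5.0 | μm²/s | small-protein mobility scale |
| region | 1.0 × 0.45 | μm | cell-like box; 5 × 5 μm "large bounds" for unconfined curves |
| r, φ, μi/μo | 0.01, 0.6, 0.05 | μm, –, – | granule defaults |
| interaction k | 0.04 / 0.1 | – | weak / strong regimes |
| neighbor cutoff | 2.5·S(D_max) | μm | scales with step geometry |
| ROI radius | 0.2 | μm | FRAP |
| FTCS dx, dt | 1e-3, 5e-7 | arb. | dt at the stability bound for D = 1 |

The interacting-run study conditions (region size and number density
are not fixed by the gradient geometry itself) are set to a 3 × 3 μm
region with 10³ particles and a 0.5→5 μm²/s linear gradient; with the
default cutoff rule this gives ~3 neighbors per particle at
initialization, so k = 0.04 starts in the weak-suppression regime and
clustering emerges dynamically rather than freezing the initial
condition.

Seeding: one integer seed per run, split deterministically into a
packing stream and a dynamics stream; the dynamics stream is consumed
as one (N, 2) uniform block per epoch after the initial placement
block. Identical config + seed ⇒ bit-identical trajectories.

## Problem sizes used in the checks

The claim-by-claim tests run at roughly one tenth of the full study
scale: FRAP uses 10⁴ particles with a 10³-epoch burn-in (granule
occupancy equilibrates within ~500 epochs; measured) and 10³-epoch
recovery windows; the emergent-coefficient fit uses 2×10³ particles ×
10⁴ steps; steady-state histograms pool the trailing quarter of a 10⁴-
epoch run of 10⁴ particles; the clustering run is the full 10³ × 2×10⁴
condition. The unconfined fit uses a 50 × 50 μm region with the fit
window confined to the first tenth of the run: in smaller boxes, wall
contacts measurably depress the fitted slope before the window ends.

## What the generator does and does not emulate

The synthetic fields are idealizations: static diffusivity maps,
monodisperse immobile granules, no hydrodynamics, no explicit
potentials, no binding chemistry, and bleaching without photophysics
(no bleach profile, no diffusion during the flash). Passing tests
therefore demonstrate the internal consistency of the Itô walk, its
agreement with the convention-indexed continuum forms, and the
direction and rough magnitude of geometry-driven transport effects —
not quantitative agreement with any particular cellular measurement.
Real cytoplasm adds crowding correlations, granule turnover and
exchange dynamics that this model deliberately omits.

## Numerical choices and edge cases

* Step-limit mapping S = √(6·D·dt): fixed by requiring the emergent D
  to equal the nominal D; only proportionality S ∝ √D is fundamental.
* Closed-ball conventions for disc membership and neighbor counting
  (with a relative 1e-9 float tolerance on the disc boundary).
* Step fields have sharp interfaces (no smoothing); the walk resolves
  them at the scale of one step length, so measured interface widths
  are O(S).
* D = 0 is allowed in the engine (particles freeze) but not in fields,
  which require strictly positive diffusivity.
* Degenerate inputs: empty ROI at bleach time is an error;
  non-saturated MSD curves refuse a saturation estimate; packings that
  cannot reach the requested φ fail loudly.

## Known limitations

* The discrete walk's trapping strength in granule fields depends on
  the ratio of step length to granule radius; with the default bulk
  step (≈ 0.039 μm) granules of r = 0.01 μm are smaller than one step,
  so trapping is much weaker than the continuum c ∝ 1/D prediction
  (measured granule occupancy ≈ 0.68 at μi/μo = 0.1 and φ = 0.6 versus
  ≈ 0.93 for the continuum limit). Conclusions at granule scales near
  or below the step length are resolution-dependent.
* FRAP recovery in strongly trapping fields (large r, low μi/μo) is
  dominated by slow granule refill; the measured half-time then
  exceeds simple effective-medium estimates, and a uniform control at
  the area-weighted mean diffusivity recovers *faster* than the
  granular field at the default φ = 0.6 — the ROI-count recovery is
  rate-limited by whichever phase holds the majority of the
  steady-state count.
* The α-family solver is 1D; the particle engine is 2D. Per-axis
  separability of the underlying equations makes the 1D comparisons
  meaningful for axis-aligned profiles.
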