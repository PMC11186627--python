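# difflens

Agent-based simulation of **diffusive lensing**: the accumulation of
diffusing particles in regions of low diffusivity that arises under the
Itô (non-anticipatory) interpretation of heterogeneous diffusion, and
its consequences for microrheology and mesoscale transport in cell-like
geometries.

The package is aimed at biophysicists who want to explore how spatially
inhomogeneous diffusivity — viscogen patches, membrane-less granules,
intracellular gradients — reshapes particle distributions and apparent
transport coefficients, without committing to any molecular detail
beyond a diffusivity map D(x).

## What it computes

**Random-walk engine (Itô).** Point particles in a 2D region take
independent per-axis steps drawn from U(−S, S) with the step limit set
by the diffusivity at the particle's *present* position,

    S(x) = sqrt(6 · D(x) · dt),

so that a uniform field reproduces free-diffusion statistics,
MSD(t) = 4·D·t, with D an emergent property of the trajectories rather
than an input to a Gaussian sampler. Walls reflect by the mirror-image
rule. An optional neighbor-sensing interaction rescales the step limit
as S_eff = S·exp(−k·n), where n counts neighbors within a cutoff — an
effective attraction that produces clustering.

**Diffusivity fields.** Uniform, sharp two-level step, linear gradient,
1D Gaussian well, and packed low-diffusive discs ("granules") with
radius r, packing density φ, and interior:exterior diffusivity ratio
μi/μo (defaults r = 0.01 μm, φ = 0.6, μi/μo = 0.05, μo = 5 μm²/s).
Packings use random sequential adsorption below φ = 0.6 and a jittered
hexagonal lattice at and above it.

**Convention-parameterized Fokker–Planck solver.** The 1D equations
for the Itô (α = 0), Stratonovich (α = 1/2) and isothermal (α = 1)
conventions, unified as ∂c/∂t = ∂x(D^α ∂x(D^(1−α) c)), solved by an
explicit conservative FTCS scheme with no-flux boundaries. Steady
states obey c·D^(1−α) = const: Itô dynamics accumulate mass where D is
low (c ∝ 1/D); only the isothermal convention stays uniform — the
computational content of the Itô–Stratonovich dilemma.

**In silico assays.** Ensemble MSD with fitted diffusion coefficient
and saturation value; FRAP (instantaneous photobleaching of a circular
ROI, recovery half-time t½ normalized to a uniform-diffusivity
background); granule dwell-time statistics; neighbor-count local
densities and steady-state concentration profiles with the closed-form
overlay.

## Worked example

```python
from difflens import Region
from difflens.config import FieldSpec, ParticleSpec, RunConfig, RunSpec
from difflens.engine import run_simulation
from difflens.assays import compute_msd, fit_diffusion_coefficient, concentration_profile

# emergent diffusion coefficient of a homogeneous walk
cfg = RunConfig(
    region=Region(50.0, 50.0),
    field=FieldSpec(kind="uniform", D=5.0),
    particles=ParticleSpec(n=2_000, dt=5e-5),
    run=RunSpec(epochs=10_000, snapshot_interval=25, seed=1),
)
curve = compute_msd(run_simulation(cfg))
print(fit_diffusion_coefficient(curve, (0.0, 0.05)))
# 4.966367223862728   <- μm²/s, nominal 5

# Itô steady state of a 1:4 diffusivity step (low zone = left quarter)
cfg = RunConfig(
    field=FieldSpec(kind="step", D_low=1.25, D_high=5.0),
    particles=ParticleSpec(n=10_000, dt=5e-5),
    run=RunSpec(epochs=10_000, snapshot_interval=100, seed=1),
)
store = run_simulation(cfg)
prof = concentration_profile(store, n_bins=20, field=cfg.build_field())
low = prof.density[prof.bin_centers <= 0.2].mean()
high = prof.density[prof.bin_centers >= 0.35].mean()
print(low / high)
# 4.042402457460837   <- density ratio ≈ D_high/D_low = 4 (c ∝ 1/D)
```

The first number is the diffusion coefficient recovered from the MSD
slope of 2,000 trajectories — within 1% of the nominal 5 μm²/s, showing
the step-limit mapping is calibrated. The second is the steady-state
density ratio across the diffusivity step: particles concentrate in the
low-diffusivity zone in inverse proportion to D, the lensing effect.

A CLI mirrors the library:

```bash
difflens simulate --config run.yaml --out run.npz
difflens msd --store run.npz --out msd.csv
difflens pde --alpha 0.5 --out strat.csv
difflens report --preset fig4_frap --scale 0.1 --out report/
```

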