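# Methods

## Model

A protein population of N identical, non-interacting molecules moves in
an ellipsoidal cytoplasm (semi-axes a = 25, b = 15, c = 15 µm; AP axis
along x).  Each molecule is in one of two kinetic states:

* **slow** — dephosphorylated, RNA-bound; diffusivity `D_slow`;
* **fast** — phosphorylated by the PAR-1 kinase; diffusivity `D_fast`.

Interconversion is a position-dependent two-state Markov switch: slow →
fast at the kinase rate k(x), linear from `k_kinase_low` at the anterior
pole to `k_kinase_upp` at the posterior pole (the cortical PAR domain
enters the model only through this profile), and fast → slow at the
uniform phosphatase rate `k_phosp`.  RNA binding is not modelled
explicitly; it is subsumed in the slow-state diffusivity.  There is no
advection, no particle interaction, and no cortical compartment.

Absent transport, the stationary slow-state occupancy at x is
`k_phosp / (k_phosp + k(x))` — only kinase-to-phosphatase *ratios*
matter for the steady state, which is why jointly rescaling all three
rates changes the kinetics but (to good approximation) not the
steady-state gradient.  The approximation is not exact: rescaling rates
while D stays fixed changes the screening lengths sqrt(D/k); over the
factor 0.5–2 the continuum steady gradient moves from 0.88 to 0.94
(total span ~7%), comparable to replicate noise at the default
simulation sizes.

## Discretisation

Diffusion is a fixed-speed isotropic random walk: per timestep Δt a
molecule moves a distance v·Δt in a direction uniform on the sphere,
with v = √(6D/Δt) so the per-step mean-squared displacement is exactly
6DΔt (directions are independent, so MSD(t) = 6Dt at all lag times — the
free-walk test recovers D to < 1% at 2·10⁴ walkers).  The default
Δt = 0.75 s is the value at which this conversion reproduces the
tabulated step speeds of both proteins: 1.81 → 3.81 (tabulated 3.80) and
3.00 → 4.90 µm/s exactly, and the slow speeds within 10% (0.283 vs 0.29;
0.449 vs 0.45).  Speeds are always re-derived from (D, Δt), so changing
the timestep preserves the physical diffusivity.

State switching uses the exact exponential probability 1 − exp(−kΔt)
(a linearised kΔt variant is selectable; at default rates they differ by
< 0.1%).  Moves are applied first, switching is evaluated at the
post-move position; any ordering bias is O(kΔt) ≈ 0.004, far below
sampling noise.

**Boundary handling.**  A displacement crossing the surface is
specularly reflected: the crossing point is found from the quadratic in
scaled coordinates, the remaining displacement is mirrored about the
local normal, and the (rare) multiply-reflecting cases iterate up to
five bounces, falling back to rejecting the move.  Reflection was
chosen after a direct comparison of candidate rules on a free,
uniformly seeded ensemble: direction-*redrawing* (resample until the
step stays inside) is not measure-preserving and visibly depletes the
boundary layer (outer 10%-shell occupancy 0.19 instead of the uniform
0.27 at the fast step length of 2.85 µm), which biases concentration
profiles; move-*rejection* preserves uniformity (it is a Metropolis
kernel for the uniform target) but damps near-wall mobility.  Specular
reflection preserves the uniform equilibrium within counting error
*and* bulk transport, and is the default (`boundary_rule` in
`SimConfig`; the alternatives remain available for comparison).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `D_slow`, `D_fast` (MEX-6) | 0.01, 1.81 | µm²/s | from the two-region mixture inversion of the anterior/posterior averages 0.55 / 0.91 µm²/s at 70% / 50% slow occupancy |
| `D_slow`, `D_fast` (MEX-5) | 0.03, 3.00 | µm²/s | literature component values |
| `k_kinase_low` | 0.001 | 1/s | anterior kinase rate |
| `k_kinase_upp` | 0.005 (MEX-6), 0.0055 (MEX-5) | 1/s | posterior kinase rate |
| `k_phosp` | 0.005 | 1/s | uniform phosphatase rate |
| `timestep` | 0.75 | s | see discretisation |
| `duration` | 1200 | s | the 20-minute operational steady-state readout |
| `n_particles` | 50 000 | — | default production size |
| `n_replicates` | 5 | — | replicate r uses seed + r |
| slab thickness | 5 | µm | central readout slice |

The embryo dimensions are a modelling choice (typical ~50 µm AP
length); the readout is normalised, so absolute size mainly sets
timescales.  The posterior kinase rate for MEX-6 is taken equal to the
phosphatase rate — the only choice consistent with the 50/50 posterior
steady-state split, since the stationary slow fraction is
k_p/(k_p + k).  Note one deliberate inconsistency kept visible rather
than patched: at the *anterior*, the same formula with k = 0.001 gives
83% slow, while the measured anterior occupancy used for the
diffusivity decomposition is 70%.  Transport narrows but does not close
this gap (the simulated anterior slow share settles near 73%); both
numbers are reported and neither is forced onto the other.

## Readouts

Concentration profiles count molecules with |z| ≤ 2.5 µm in bins along
the normalised AP coordinate x̂.  Two conventions: raw count fraction
(per-bin count ÷ total particles) and, by default, the chord-corrected
density (count fraction ÷ exact in-embryo bin volume, rescaled by embryo
volume) under which a uniform ensemble is flat.  Bin volumes use the
closed-form area of an ellipse truncated at |z| ≤ h, integrated along x.
Bins outside the ellipse cross-section are absent (NaN), not zero.

The gradient statistic is the OLS slope of the mean-normalised profile
versus x̂, sign-flipped so anterior-rich is positive.  The outermost 5%
of the axis is excluded (partial-voxel pole artefacts).  Units are
mean-normalised intensity per embryo length; the statistic is invariant
to detector gain but **not** to additive offsets (background must be
subtracted before quantification), which is why absolute comparisons
with differently normalised measurements are treated as
convention-dependent.  The experimentally observed steady-state scale
(≈0.55) is therefore never used as a hard simulation target.

Steady-state values are the mean over the final 10% of a series, with a
drift flag when the residual linear trend across that window exceeds
the replicate spread.

## Validation against an independent continuum solution

The test suite solves the 1D finite-volume reduction of the same model
(`(1/A) ∂x(A D ∂x c)` transport with the ellipse cross-section area A(x),
no-flux boundaries, scipy BDF) completely independently of the particle
engine.  Monte Carlo and continuum agree throughout: steady total
gradient 0.92 ± 0.05 (MC) vs 0.917 (PDE) for default MEX-6; smoothing
scenarios 0.82/0.65/0.50/0.14 (MC) vs 0.86/0.67/0.52/0.15 (PDE);
anterior slow fractions 73/69/66% vs 74/70/66%.

Two timing observations from this cross-check are worth stating
explicitly.  First, at steady state the total flux vanishes, forcing
`D_s ∇c_s = −D_f ∇c_f`; the fast component is then flat to within
D_s/D_f ≈ 0.6% of the slow-component slope — the model's signature
"homogeneous fast species".  Second, the slowest relaxation is governed
by anterior unlocking at rate ~`k_kinase_low` (τ ≈ 600 s in the
gradient statistic), so at the 20-minute operational readout the
gradient has reached ≈85% of its plateau and the fast component still
carries a small transient counter-slope.  Stability and homogeneity
checks therefore read the 30-minute end of the window, and the
rate-scaling comparison runs each condition to the same *scaled*
horizon (3600 s ÷ scale) so all conditions are equally equilibrated.

## Synthetic data

The generators emulate the statistical structure of the real inputs,
not their optics:

* **images** — I(x̂) = mean·(1 + slope·(0.5 − x̂)) inside an elliptical
  mask, additive Gaussian noise (fraction of mean; Poisson not needed at
  these SNRs since the readout is a linear fit), zero background, no
  PSF, no photobleaching during acquisition.  Ensemble snapshots are
  rendered as midplane count images over a mask shrunk so the 5-µm slab
  is fully contained at every pixel (uniform optical depth; trims a
  ~1.4% rim).
* **staged series** — per-embryo slopes drawn around a monotone stage
  template ending at 0.55, aggregated to mean ± SD.
* **FRAP curves** — free particles at a known D, a cylindrical bleach
  column of radius 5 µm, region-mean brightness at 0.2 s sampling.

Passing tests on these inputs demonstrates that the quantification is
unbiased and calibrated *for data obeying the model's assumptions*;
they say nothing about segmentation, background structure, bleaching
during acquisition or stage misassignment in real movies.

## FRAP estimation

The recovery estimator normalises the post-bleach curve, fits the
hyperbolic shape F(t) = F_inf·t/(t_half + t), and converts the
half-time with the uniform-disc relation D = 0.224·r²/t_half.  The
generator–estimator round trip recovers D = 1 µm²/s within 15%
(typically +10–12%; the hyperbolic shape and the finite reservoir both
bias the half-time slightly short).  Fits are flagged low-confidence
when half-recovery is not reached inside the window; curves without a
bleach drop or without recovery raise a structured error with
diagnostics.  This estimator exists to validate the simulator against
region-averaged diffusivities; it is deliberately single-component (no
anomalous diffusion, no two-population fits).

## Test conditions and statistical conventions

Quantitative simulation checks run at 20 000 particles and 3 replicates
(seed 0), sized so each check completes in seconds-to-minutes on one
CPU while keeping replicate SD of the gradient near 0.05.  Two
stochastic estimates are considered consistent when they differ by at
most twice the combined replicate SD; with 3 replicates the sample SD
is itself noisy, so a 1-sigma band would reject true nulls too often.
"Near-uniform" in the smoothing scenarios is operationalised as a
steady gradient below 25% of the control scenario's, a convention-free
reading of an almost-flat profile.

## Known limitations

* No cytoplasmic flows, no RNA particles, no cortical dynamics; the
  PAR domain acts only through the static linear kinase profile.
* The kinase profile is stationary; real PAR polarity is established
  concurrently with the early gradient.
* The gradient statistic's absolute scale is normalisation-dependent;
  comparisons to intensity-based measurements need matching conventions.
* Specular reflection on a curved surface preserves the uniform
  measure only approximately (exactly for planar walls); residual bias
  is below counting noise at the default step lengths.
* The FRAP estimator assumes effectively 2D recovery of a uniform disc
  and a single diffusing component.
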