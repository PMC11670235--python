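# mexdiff

Monte Carlo modelling of cytoplasmic protein gradients formed by
**differential diffusion** in the one-cell *C. elegans* embryo, built
around the RNA-binding proteins MEX-5 and MEX-6.

## The problem

MEX-5 and MEX-6 are enriched at the anterior of the zygote even though
individual molecules diffuse freely.  The gradient arises from a
two-state switch: the posterior-enriched kinase PAR-1 phosphorylates the
protein, releasing it from RNA complexes into a **fast** diffusive state
(D ≈ 1.8–3 µm²/s), while a uniform phosphatase returns it to the
**slow**, RNA-bound state (D ≈ 0.01–0.03 µm²/s).  Because the kinase
rate k(x) increases from the anterior to the posterior pole while the
phosphatase rate k_p is uniform, slow molecules pile up anteriorly.

`mexdiff` implements this model as an agent-based simulation for anyone
studying intracellular reaction–diffusion patterning: each molecule
performs an isotropic fixed-speed random walk inside an ellipsoidal
embryo (step speed v = √(6D/Δt)) and switches state stochastically with
probabilities 1 − exp(−k(x)Δt) and 1 − exp(−k_p Δt).  The package also
provides the quantification used on real time-lapse data:

* **diffusivity decomposition** — two region-averaged (FRAP-style)
  diffusivities with known slow-state occupancies f_A, f_P invert the
  mixture relations `f·D_slow + (1−f)·D_fast = D_region` to give the
  component diffusivities;
* **concentration profiles** — molecule counts in a central 5-µm slab,
  binned along the anterior–posterior (AP) axis, with exact geometric
  (chord-volume) correction;
* **gradient statistic** — the OLS slope ∂I/∂x of the mean-normalised
  profile against the normalised AP coordinate (anterior-rich →
  positive);
* **parameter experiments** — joint rate scaling, a (k_upp × k_phosp)
  scan, and anterior-kinase "smoothing" scenarios that emulate an
  expanded posterior PAR domain;
* **synthetic data** — graded embryo images, staged gradient series and
  FRAP recovery curves with known ground truth, so the full pipeline is
  testable without microscope data.

## Worked example

```python
import dataclasses
import mexdiff as m

# decompose the two FRAP region averages into component diffusivities
anterior = m.RegionDiffusivity("anterior", 0.55, 0.70)
posterior = m.RegionDiffusivity("posterior", 0.91, 0.50)
d_slow, d_fast = m.split_diffusivities(anterior, posterior)
print(f"D_slow = {d_slow:.2f} um^2/s, D_fast = {d_fast:.2f} um^2/s")

# simulate MEX-6 gradient formation (small, fast demo)
species, rates, fractions, config = m.default_mex6_params()
config = dataclasses.replace(config, n_particles=10_000, n_replicates=3,
                             duration=1800.0, rng_seed=0)
geometry = m.EmbryoGeometry()
runs = m.run_replicates(config, geometry, species, rates,
                        output_times=[600.0, 1200.0, 1800.0])
series = m.gradient_timeseries(runs, geometry)
for t, g, sd in zip(series.times, series.gradient, series.spread):
    print(f"t = {t:6.0f} s   gradient = {g:5.2f} +/- {sd:.2f}")
```

prints

```
D_slow = 0.01 um^2/s, D_fast = 1.81 um^2/s
t =      0 s   gradient =  0.02 +/- 0.06
t =    600 s   gradient =  0.53 +/- 0.09
t =   1200 s   gradient =  0.82 +/- 0.11
t =   1800 s   gradient =  0.86 +/- 0.05
```

The decomposition returns the slow/fast component diffusivities of
MEX-6 (0.01 and 1.81 µm²/s) from the anterior and posterior region
averages.  The simulated gradient starts at zero (uniform initial
condition), rises as slow molecules accumulate anteriorly, and
approaches its plateau; the ± numbers are the SD over three replicate
runs.  Units of the gradient are mean-normalised concentration per
embryo length, so a value of 0.86 means the fitted line spans roughly
±43% of the mean concentration across the embryo.

A CLI mirrors the library (`mexdiff simulate|analyze|scan|scenarios|
synth|frap-fit`); every run writes a `manifest.yaml` with the resolved
configuration, seeds and output checksums, from which the run can be
reproduced exactly.

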