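# morphograd

Cell-based stochastic simulation of steady-state morphogen gradients,
for quantifying how precisely a gradient can position cell-fate
boundaries under linear versus non-linear (self-enhanced) morphogen
decay.

## The problem

During development, a morphogen secreted from a localized source
spreads into a tissue and decays, forming a concentration gradient.
Cells adopt fates by comparing the local concentration to thresholds
C<sub>θ</sub> (the French flag model), so fluctuations in the gradient
translate into fluctuations of the fate-boundary positions. The
central precision metric is the **positional error**

σ<sub>x</sub> = stddev<sub>j</sub>[x<sub>θ,j</sub>],

the standard deviation of the threshold readout position across
independent gradient realizations *j* (different embryos).

Morphogen dynamics are modelled by the steady-state reaction–diffusion
equation on a 1D line of discrete cells,

0 = D C″ − d Cⁿ / C<sub>ref</sub>ⁿ⁻¹ + p·H(−x),

with production at rate p in source cells (x < 0), diffusivity D,
decay rate d, decay exponent n, and zero-flux outer boundaries.
Linear decay (n = 1) gives exponential gradients
C = C₀ e^(−x/λ) with λ = √(D/d); self-enhanced decay (n > 1) gives
shifted power laws C = C₀(1 + x/(m λ<sub>m</sub>))^(−m) with
m = 2/(n − 1) and
λ<sub>m</sub> = √((m+1)/m · D/d · (C<sub>ref</sub>/C₀)^(n−1)).

Each cell draws its own kinetic parameters (p, d, D) and its
cross-sectional area from log-normal distributions, emulating
cell-to-cell molecular variability. Ensembles of such noisy gradients
are read out at threshold concentrations, and σ<sub>x</sub> is
estimated with bootstrap standard errors. This lets one ask: does
non-linear decay, which buffers readout positions against source
fluctuations in deterministic theory, actually improve patterning
precision once realistic cell-level noise is included? (Short answer
from the simulations: only marginally near the source, and it is
substantially *worse* far from the source when the tissue boundary
blocks morphogen efflux.)

## Worked example

```python
from morphograd import EnsembleConfig, default_kinetics, run_ensemble, positional_error

cfg = EnsembleConfig(kinetics=default_kinetics())   # n=1, CVp,d,D=0.3, CVA=0.5
ens = run_ensemble(cfg, x_targets=[25.0, 375.0], n_replicates=300, seed=1)
for x, e in ens.items():
    s = positional_error(e)
    print(f"x_theta = {x:5.0f} um: sigma_x = {s.sigma_x:5.2f} um "
          f"({s.sigma_x / 5:.2f} cell diameters), bootstrap SE {s.sigma_x_se:.2f} um")
```

prints

```
x_theta =    25 um: sigma_x =  4.45 um (0.89 cell diameters), bootstrap SE 0.18 um
x_theta =   375 um: sigma_x = 10.33 um (2.07 cell diameters), bootstrap SE 0.44 um
```

i.e. with default noise levels and a mean cell diameter of 5 µm
(λ/4), the fate boundary five cells from the source is positioned to
better than one cell diameter, while 75 cells into the tissue the
error has grown to about two cell diameters.

The same is available from the shell:

```
morphograd simulate --n 2 --replicates 300 --seed 1 --targets 5,75 --out out/
morphograd sweep --preset fig3c --replicates 300 --seed 1 --out out/
morphograd diff-decay --results out/results.csv
morphograd validate
```

`sweep` writes a tidy `results.csv` (one row per condition and readout
position) plus a `manifest.json` with the config hash and seed;
presets cover cell-area-CV sweeps, cell-size scaling, readout along
the domain for n ∈ {1..4}, production-only noise, source
boundary-condition comparisons (explicit source domain vs imposed flux
vs imposed amplitude), and source-strength sweeps. Custom sweeps are
YAML configs mirroring `ExperimentConfig` one-to-one.

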