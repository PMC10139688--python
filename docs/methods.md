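# Methods

## Model

The tissue is a 1D line of cells spanning a morphogen source region
[−L_s, 0) and a patterning region [0, L_p]. The steady-state morphogen
concentration obeys

    0 = D C'' − d C^n / C_ref^(n−1) + p H(−x)

with per-cell constant production p, decay rate d and diffusivity D,
and zero-flux conditions at both outer tissue ends (an impermeable
boundary). Production is restricted to source cells by the Heaviside
factor. The decay exponent n models linear (n = 1) or self-enhanced
(n > 1) ligand degradation; C_ref is a reference concentration that
keeps the units of the decay term independent of n (set to 1 arb.
unit, so concentrations are reported relative to it). At every cell
border the concentration and the flux −D C' are continuous; C' itself
jumps where D does.

Two simplified source representations are also available, replacing
the explicit source cells by a boundary condition at x = 0: an imposed
influx −D C'(0) = j0 (Neumann) or an imposed amplitude C(0) = C0
(Dirichlet). Their default means, μ_j0 = μ_D C_ref / μ_λ and
μ_C0 = C_ref, put the three source models on a comparable footing.

Closed-form references used throughout: for n = 1 with uniform
parameters the solution is piecewise cosh (a·cosh((x+L_s)/λ) shifted
by p/d in the source, b·cosh((L_p−x)/λ) in the patterning region,
matched at x = 0); for n > 1 on a semi-infinite domain it is the
shifted power law C0 (1 + x/(m λ_m))^(−m) with m = 2/(n−1). The
length scale λ_m = sqrt((m+1)/m · (D/d) · (C_ref/C0)^(n−1)) was
derived by substituting the power law into the steady-state equation
and is verified both symbolically (sympy) and against a numerical
ODE-residual oracle in the test suite.

## Default parameters

| quantity | default | unit | rationale |
| --- | --- | --- | --- |
| μ_D | 0.033 | µm²/s | measured Hedgehog-gradient scale |
| μ_λ | 20 | µm | measured gradient decay length; sets μ_d = μ_D/μ_λ² = 8.25e−5 /s |
| μ_p | μ_d·C_ref | conc/s | normalizes the deterministic amplitude to O(C_ref) |
| CV_p, CV_d, CV_D | 0.3 | — | physiological molecular noise level |
| CV_A | 0.5 | — | typical apical-area variability (0.9 is the reported extreme) |
| μ_δ | 5 = μ_λ/4 | µm | cell diameter a quarter of the gradient length |
| L_s, L_p | 5 μ_δ, 200 μ_δ | µm | source of 5 cells, patterning domain of 200 cells |
| n | 1 (sweeps use 2–4) | — | linear decay baseline |

Only the ratio D/d matters at steady state; absolute rates would only
change the (unmodelled) time to reach it.

## Synthetic gradient generator

Each replicate draws, independently per cell, a cross-sectional area
A_i and kinetic parameters (p_i, d_i, D_i) from log-normal
distributions; in flux/Dirichlet mode a j0 or C0 draw replaces the
production field, independent of the kinetic draws. Log-normals are
moment-matched: σ_ln² = ln(1+CV²), μ_ln = ln μ − σ_ln²/2. Areas are
converted to diameters δ_i = 2√(A_i/π); the mean area is
μ_A = π(μ_δ/2)²(1+CV_A²)^(1/4), whose quarter-power factor corrects
the concavity of the square root so the mean *diameter* is exactly
μ_δ. Cells are appended until each region is filled; because a
continuous draw never hits the region length exactly, the final cell
is truncated so that L_s and L_p are exact for every replicate (fixed
domain lengths are required for readout positions to be comparable
across replicates; rescaling or overshooting were the alternatives).
No cell straddles x = 0, so production switches off exactly at the
source boundary.

The generator emulates static, spatially uncorrelated cell-to-cell
variability. It does not model temporal fluctuations within a
realization, correlations between neighbouring cells, discrete
molecule numbers at low concentration, 2D/3D geometry, or cell growth
and division — conclusions from passing tests therefore apply to
quenched kinetic heterogeneity, not to intrinsic reaction noise.

## Numerics

The boundary-value problem is solved in flux form, y = (C, F) with
F = −D C', using `scipy.integrate.solve_bvp` (4th-order collocation):
both state components are continuous across cell borders, so interface
conditions are automatic. Per-cell constant coefficients are
represented as continuous functions that ramp linearly across a
transition layer of 1e−7 cell widths at each border, with mesh knots
at the layer edges; a genuine jump located exactly at a mesh node
leaves an O(1) inconsistency in the collocation residual that no
refinement can remove, whereas the thin ramp is resolved exactly and
perturbs the solution by far less than the solver tolerance.

Defaults: 4 mesh subintervals per cell, residual tolerance 1e−6
(1e−8 for the closed-form validation solves), initial guess from the
mean-parameter analytic profile clipped below at 1e−12 C_ref (for
n > 1 with an explicit source, the guess amplitude balances source
production against decay plus the efflux of a semi-infinite power-law
tail, solved by bracketing). The decay term is evaluated as
d·C·|C/C_ref|^(n−1) (odd extension) so Newton iterates that dip below
zero remain well-defined. A solve that fails to converge is retried
up to twice with doubled mesh density; persistent failures raise an
error carrying diagnostics, and ensembles count and exclude them
(with their replicate indices logged) rather than silently dropping
them. Solutions more negative than 1e−8 of the amplitude are treated
as failures. Cell readout concentrations are length-normalized
integrals of the collocation solution over each patterning cell
(7-point Gauss–Legendre per cell), not midpoint samples.

## Readout and statistics

A target position x_θ is mapped to a threshold C_θ as the
cell-averaged concentration of the *noise-free, mean-parameter*
reference gradient in the cell containing x_θ — a reproducible,
noise-independent definition (the alternative, the mean of the noisy
ensemble, differs only by the small nonlinearity of the averaging).
For each replicate, patterning cells are scanned from the source
outward and the *first* cell whose average concentration falls below
C_θ defines the readout; its source-facing border is recorded, since
fate boundaries form at cell borders (recording cell centres instead
shifts σ_x by O(μ_δ/√12)). Replicates in which no cell subceeds the
threshold are censored: they are excluded from σ_x and reported, not
imputed to L_p, because imputation would artificially cap σ_x exactly
in the distal-boundary regime of interest. Ensembles with more than
20% censoring or solver failures are flagged unreliable.

σ_x is the sample standard deviation (ddof = 1) of the uncensored
readout positions; its standard error comes from 1000 bootstrap
resamples (enough that the SE of the SE is far below plotted error
bars). Randomness is handled with one master seed per experiment;
replicate j uses an independently spawned substream, so any single
replicate can be re-simulated in isolation and results are invariant
to worker count when run in parallel.

## Experiment designs and problem sizes

Sweep presets mirror the study designs: cell-area-CV sweeps, readout
along the domain for n ∈ {1,2,3,4}, production-only noise
(CV_p = 0.3, CV_d,D = 0 — configured by zeroing CVs, not a separate
code path), source boundary-condition comparisons, source-strength
sweeps, and finite-domain-size sweeps (L_p ∈ {50,100,150,200} μ_δ;
the exact lengths behind the original finite-size panel are not
published, these span the qualitative range). The preset replicate
default is 300; the acceptance script uses 1000-replicate ensembles.
Test-suite ensembles use 300–1000 replicates, which reproduce all
qualitative orderings of the full-scale design at a few percent
statistical precision.

For the cell-diameter scaling analysis, σ_x is measured at a *fixed
absolute* readout position (100 µm) on a fixed 500 µm domain while
μ_δ spans 1.25–10 µm. Scaling the readout position with μ_δ would
conflate the √μ_δ cell-size mechanism with the growth of σ_x along
the domain; the fixed-position design isolates it. The fitted
exponent still sits slightly below 1/2 because amplitude noise from
the (fixed-cell-count) source contributes a μ_δ-independent floor
that is relatively larger for small cells.

## Known limitations

- Pre-steady-state dynamics are out of scope; all results are
  steady-state.
- At large distances the concentration falls through many orders of
  magnitude; the continuum description ignores discreteness of
  molecule numbers there.
- Only log-normal parameter distributions are implemented (strictly
  positive, thin near zero); other distributions meeting those
  criteria are expected to behave similarly but are not provided.
- The n = 4 ensembles at very low production flatten so strongly that
  censoring limits the measurable parameter range, mirroring the
  reliability limits of the original sweeps.
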