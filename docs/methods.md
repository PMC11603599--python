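# Methods

## Model and estimators

### Osmotic second virial coefficient from RDFs

McMillan–Mayer theory relates the osmotic second virial coefficient of
two dilute solutes to their centre-of-mass pair distribution function,

```
B_ij = -2π N_A ∫₀^∞ [g_ij(r) − 1] r² dr .
```

In a finite periodic box the large-distance limit of a sampled `g(r)`
is not exactly 1: number conservation and box-size effects shift the
plateau by a small constant `c − 1`, which makes the truncated integral
grow like `(c − 1)·r*³`. The corrected estimator substitutes the
empirical plateau for the ideal limit:

```
c(r*, Δ)  = mean of g over bins with centres in [r* − Δ, r*]
B(r*)     = -2π N_A ∫₀^{r*} [g(r) − c(r*, Δ)] r² dr .
```

A *trailing* window is used because the natural choice `r* = 10 nm`
coincides with the end of the RDF grid, so a window ahead of `r*` could
not exist; it also makes the plateau-averaging range below coincide
with the windows actually averaged. The window mean is unweighted by
default; an `r²`-weighted variant is available behind a flag because
the integral itself weights the tail that way and the convention is not
uniquely determined.

Quadrature is the trapezoid rule on bin centres, with `g` taken as 0
between `r = 0` and the first bin centre (any physically sensible RDF
has an excluded core there). On a 0.01 nm grid the discretisation error
against closed forms is below 0.1%; on the production 0.1 nm grid it is
still well below the run-to-run scatter.

Reported values average `B(r*)` over a plateau window and over
independent runs: the per-run plateau mean is the mean of `B(r*)` for
`r*` in the window; the ensemble value is the mean of per-run means and
the quoted uncertainty is their standard error (for a single run, the
standard error across `r*` values in the window — an optimistic proxy,
flagged as such by `n_runs = 1`). The plateau estimate `c` is computed
per run, never pooled, so run-to-run drifts in the baseline are
corrected run by run.

Defaults follow the coarse-grained protein–osmolyte protocol: bin
0.1 nm, range 10 nm, `Δ = 2 nm`, plateau window 8–10 nm for
protein–sugar; `Δ = 1 nm`, `r* = 5 nm` are the conventional choices for
sugar–sugar pairs. All virial coefficients are reported in L/mol
(≡ M⁻¹) via the conversion 1 nm³ ↔ `N_A·10⁻²⁴ ≈ 0.602214` L/mol.

### RDF protocol

Distances are measured between mass-weighted molecular centres of mass.
Molecules straddling the periodic boundary are made whole by
minimum-image unwrapping relative to the molecule's first bead before
mass weighting (adequate for molecules much smaller than half the box,
which holds for every intended input). Distances use the minimum-image
convention; bins are half-open `[edge_k, edge_{k+1})` with a distance
exactly at the maximum range discarded. Normalisation is by
spherical-shell volume times the ideal-gas pair density `N_i N_j / V`
for distinct species (`N(N−1)/2` unordered pairs for identical
species). Orientational averaging is implicit in the spherical
histogram. A `stride` option subsamples frames, standing in for a
sampling cadence in time for frame sets that carry no clock.

### Cross-interaction scaling

Lennard-Jones well depths for selected bead-pair groups are mapped as
`ε_λ = ε₀ + λ(ε − ε₀)` with floor `ε₀ = 2 kJ/mol` — weak enough to act
as a purely repulsive reference, so `λ` interpolates between "excluded
volume only" (λ=0) and the unmodified table (λ=1). Only `ε` is ever
touched; `σ` and unselected pairs pass through verbatim, and the writer
preserves comments and ordering so scaled files diff cleanly. Pairs
absent from the table are an error rather than being synthesised from
combination rules: unreliable mixing rules are the very reason a cross
calibration is needed, and `mixing_lambda(α, γ) = √(αγ)` is provided
only as the reference point to compare a calibrated `λ` against.

### Calibration

`B23(λ)` decreases monotonically in λ (stronger cross attraction lowers
the virial coefficient). The calibrated `λ*` is read off the scan by
piecewise-linear interpolation at the target value — interpolation, not
curve fitting, because no functional form for `B23(λ)` is claimed. The
uncertainty interval re-interpolates at target ± 1 combined SEM (target
SEM and the scan SEM at `λ*`, combined in quadrature). A scanned point
is reported "consistent" with the target when `|B23 − target|` is below
one combined SEM — a formalisation of reading agreement off a plot with
error bars. Rises between adjacent scan points are tolerated up to one
combined SEM of the two points (and flattened onto the running-minimum
envelope for the inversion); larger rises are an error. Targets outside
the scanned range raise rather than extrapolate.

### Dimer stability and kinetics

The osmolyte effect on a monomer–dimer equilibrium is summarised by
`ΔB23 = 2 B23^mon − B23^dim` (positive when the osmolyte is
preferentially excluded from the dimer, i.e. stabilising) and the
apparent dissociation constant `Kd(C) = Kd⁰ exp(−ΔB23·C)`.

Dissociation rates come from repeated runs started in the bound state
with administrative censoring: the maximum-likelihood rate for
exponential lifetimes observed over finite windows is
`k = n_events / Σ tᵢ`, where `tᵢ` is the event time for runs that
dissociated and the full duration otherwise. Zero-event records return
rate 0 with an explicit flag plus the rule-of-three upper bound
`3 / Σ tᵢ` as a diagnostic, since a confidence procedure is otherwise
undefined there. Event detection in distance time series uses a
threshold-plus-dwell criterion (defaults 6 nm, 10 samples) — these are
stated conventions with no measured counterpart, exposed as parameters.

Residue–sugar contacts: a sugar molecule contacts a residue when any of
its beads is within 0.94 nm of the residue's centre of mass, counted
once per molecule per frame (a per-bead mode exists behind a flag
because either reading of "contacting beads" is defensible). The CNR
curve counts residues with mean contacts *strictly below* a threshold,
so its value just above zero equals the number of residues that made no
contact at all.

## Synthetic ground truth

The generators produce every input the pipeline consumes, with known
expected outputs:

* **Analytic RDFs** use the dilute-limit closure `g = c·exp(−βu)` for
  hard-sphere, square-well and Lennard-Jones potentials, for which the
  McMillan–Mayer integral is exactly the potential's second virial
  coefficient — closed-form for hard sphere
  (`(2π/3)N_Aσ³`) and square well
  (`(2π/3)N_Aσ³[1 − (e^{βε} − 1)(λ_w³ − 1)]`), adaptive quadrature (rel.
  tol. 1e−8) for Lennard-Jones. The `baseline` parameter plays the role
  of the finite-size plateau offset; per-bin independent Gaussian noise
  (applied only where `g > 0`, clipped at 0) models sampling scatter.
* **Ideal-gas frames** (uniform single-bead molecules) have `g ≡ 1`;
  **excluded-sphere frames** hold one central "protein" bead with a
  hard exclusion of radius σ in a "sugar" bath, whose protein–sugar RDF
  is a hard-sphere step — note the bath density `N/V` overestimates the
  accessible density by `V/(V − 4πσ³/3)`, which is precisely the
  plateau artifact the tail correction removes.
* **Survival records** draw exponential event times truncated at the
  run length. Default inverse temperature corresponds to 300 K.

What the synthetic route does *not* emulate: protein shape and
flexibility beyond a sphere, solvent-mediated structure in `g(r)`
(layering near the surface), correlated noise across bins, or
finite-density corrections to the dilute closure. Passing tests
therefore validate the *estimators* (integration, correction,
normalisation, likelihood), not any force field; quantities that
require tens of μs of coarse-grained MD in 30–40 nm boxes (a specific
protein's B23(λ), its ΔB23, contact counts) are out of desk-top reach
by construction, and the pipeline ingests externally produced RDFs for
those.

## Numerical choices and problem sizes

* Trapezoid quadrature; oracle comparisons on 0.01 nm grids.
* Estimator validation on point processes uses 50-frame runs of 1000
  ideal-gas beads and 600-frame excluded-sphere baths of 2000 beads in
  30 nm boxes, four independent runs each — sizes chosen so binomial
  sampling error puts the statistical checks at the few-percent level
  while the whole suite runs in about two minutes.
* All generators take explicit integer seeds (NumPy `default_rng`) and
  are bit-reproducible; the pipeline derives per-run seeds from a
  single master seed and records them in its manifest.
* Degenerate inputs fail loudly: empty species selections, RDF windows
  off the grid, non-monotone scans, targets outside the scanned range,
  zero bound time, missing cross pairs.

## Known limitations

* The plateau correction assumes a *constant* baseline offset; it does
  not implement grand-canonical or Kirkwood–Buff finite-size
  extrapolations.
* COM unwrapping anchors on a molecule's first bead and fails for
  molecules extending beyond half the box.
* Single-run SEMs understate uncertainty (r* values within a window are
  correlated); multi-run inputs are the supported path to honest error
  bars.
* The GRO reader handles one frame per file and assigns a uniform bead
  mass (the format carries none); the CSV dialect is the lossless
  interchange format.
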