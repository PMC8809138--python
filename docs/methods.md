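# Methods

## The quantity being computed

The solvation free energy ΔG_sol of a rigid solute held at a fixed position
is the reversible work of switching on its interactions with the surrounding
solvent, equivalently the transfer free energy from vacuum into solution.
For a solute in an electrolyte, the slope of ΔG_sol with salt concentration
c_s gives the Setschenow coefficient in the natural-log convention,

    ln[S(0)/S(c_s)] = k_s c_s,      ΔΔG_sol(c_s) = R T k_s c_s,

with k_s > 0 meaning salting-out.  The package estimates ΔG_sol from
*energy-representation* statistics: the one-dimensional distributions of the
solute–molecule pair interaction energy ε, accumulated per solvent species i
(anion, cation, water),

* ρ_i(ε): frame-averaged counts in the solution system (solute present),
* ρ0_i(ε): insertion-averaged counts from uniform test insertions of the
  solute into the reference system (solute absent), together with the
  bin-pair second moments of the per-insertion counts.

Because the estimator is additive over species and over the energy
coordinate, ΔG_sol decomposes exactly into per-species terms and, within
each species, into an attractive-interaction part (ε < ε_max) and an
excluded-volume part (ε ≥ ε_max).  The same linearity carries the
decomposition through the OLS fit to k_s.

## The free-energy functional

For each species (bins b, solution masses m_b, reference masses m0_b per
insertion; ε̄_b denotes the in-bin sample-mean energy):

    ΔG_i = ⟨ν⟩_i + ΔG_i^reorg,

where ⟨ν⟩_i = Σ_b (energy-weighted histogram) is the exact mean
solute–solvent interaction energy of species i, and the solvent
reorganization term is assembled from two closures:

* **Attractive side (ε < 0)** — solution-side relative-entropy (endpoint)
  form per bin:

      r_b = RT [ m_b ln(m_b/m0_b) − m_b + m0_b ].

  This vanishes identically when ρ = ρ0, is first-order exact in a weak
  coupling, and reproduces the linear-response result
  ΔG = (⟨ν⟩ + ⟨ν⟩0)/2 exactly for equal-variance Gaussian distributions.

* **Repulsive side (ε ≥ 0, including the overflow bin at ε ≥ ε_max)** — a
  count-model closure built from the reference-side insertion statistics.
  With region mean count M = Σ m0_b, per-molecule Boltzmann factor
  φ = Σ m0_b e^{−βε̄_b} / M, and region count variance V from the second
  moments, the repulsive free-energy cost is

      A = RT · (−ln E[φ^N]),

  where the count law of N is the binomial (V < M) / Poisson (V = M) /
  negative-binomial (V > M) family matched to (M, V).  For a hard core
  (φ = 0) this is −RT ln P(0), the cavity-formation cost; in the Poisson
  limit it reduces to RT Σ m0_b (1 − e^{−βε̄_b}), which is exact for an
  ideal-gas solvent at any repulsion strength.  A is distributed over bins
  proportionally to m0_b (1 − e^{−βε̄_b}) so that any later energy-domain
  partition remains exactly additive.

  Per bin the two rules are blended by the depletion factor
  α_b = clip(1 − m_b/m0_b, 0, 1): fully depleted bins (hard overlap) follow
  the count closure, unperturbed bins (m = m0) contribute nothing, and the
  crossover is smooth.  This keeps the ρ = ρ0 identity, the weak-coupling
  limit and the Gaussian limit exact while giving sub-Poisson (correlated
  fluid) cavity statistics their proper super-Poissonian cost.

The per-species profile f(ε) = r_b / m_b (reported where m_b > 0) is the
reorganization free energy per molecule on the energy coordinate; its
integral against ρ_i recovers ΔG_i − ⟨ν⟩_i wherever the solution density is
nonzero.  In the excluded-volume region the solution density vanishes, so
the per-bin reorganization contributions themselves (not ρ·f) carry the
cavity cost; all downstream decompositions use those per-bin terms, which is
why every closure (species, components, Setschenow) holds at machine
precision by construction.

**Accuracy.** The functional is approximate away from its exact limits.
Against Widom/BAR ground truth on a weakly coupled LJ solute the deviation
grows with solvent packing: ≈ 0.02, 0.07 and 0.25 kcal/mol at
ρσ³ ≈ 0.28, 0.37 and 0.51 respectively (the two-moment count model
saturates below the true cavity cost in strongly correlated fluids).  The
oracle-validation suite therefore runs at ρσ³ ≈ 0.28 (110 particles,
L = 22 Å); the salt-scan studies run at liquid-like ρσ³ ≈ 0.69, where the
residual bias largely cancels in the concentration *differences* that enter
k_s.

**Degenerate inputs.** Bins where both densities vanish contribute zero.  A
bin with solution mass but zero reference mass signals insufficient
insertion sampling and raises by default, naming the bin; with
`regularize_empty_reference=True` the reference mass is floored at 0.5
pseudo-counts per insertion sample and the number of floored bins is
recorded on the result.  Solution masses below 10⁻¹² molecules are treated
as numerical zero.

## Corrections

Two additive corrections keep the species decomposition closed:

* **Periodic self-energy**: for a solute of net charge q in a cubic box of
  side L under periodic electrostatics, ΔG_self = ξ k_e q²/(2L) with the
  cubic Wigner constant ξ = −2.837297 (mode `constant`); externally computed
  values can be supplied instead (mode `external`).  Zero for the neutral
  default solute.
* **Dispersion tail**: Σ_i 4π ρ_i ∫_{r_c}^∞ u_LJ(r) r² dr in closed form per
  species and solute site, compensating the truncated attraction beyond the
  cutoff.

## The toy simulator

The generator is a Metropolis NVT Monte Carlo engine for single-site
solvent species (a neutral "water", cations, anions) with an optional rigid
multi-site solute fixed at the box centre.  Interactions are
truncated-and-shifted 12-6 Lennard-Jones with Lorentz–Berthelot mixing;
electrostatics, when enabled, use shifted-force Coulomb truncation, so the
Hamiltonian is strictly finite-ranged and the periodic self-energy enters
only as the explicit additive correction above.  Two further interaction
styles exist because the analysis probes them directly: `repulsive` (the
r⁻¹² wall only, a near-WCA particle) and `hard` (a hard sphere of diameter
σ), the latter giving an exact −RT ln p0 cavity oracle.

Moves are single-particle displacements (default max 0.45 Å, acceptance
≈ 0.3–0.5 at liquid density) of which a fraction (default 0.1) are uniform
relocations.  Relocation proposals are symmetric, so detailed balance is
untouched; they exist because binding/unbinding of a strongly
solute-attracted species equilibrates far too slowly by local diffusion
alone, which otherwise leaves replicate-level free energies bimodal.
Configurations are stored every `sample_interval` sweeps (default 10,
chosen from energy-autocorrelation diagnostics at the default liquid
density); reference-system insertions draw uniform positions and, for
multi-site solutes, uniform quaternion orientations.

Units throughout: kcal/mol, Å, K, elementary charges;
k_e = 332.0636 kcal Å/(mol e²), R = 1.987204×10⁻³ kcal/(mol K).

### What the generator emulates — and what it does not

It reproduces the statistical *structure* the analysis needs: three tagged
solvent species sampled canonically with and without the solute, a
concentration series realized as ion-pair counts in a fixed box, replicate
runs from independent seeds, and insertion statistics with genuine
excluded-volume correlations.  It does not emulate water's hydrogen-bond
network or polarizability, ion-specific dispersion beyond σ/ε, constant
pressure (the series is NVT; density effects enter only through the sampled
distributions), or solute flexibility (the solute is rigid, so no
vacuum-state conformational reweighting exists).  Passing tests therefore
validate the estimator and its decompositions, not any force-field-level
prediction for a real solute.

## Energy mesh

`build_mesh` lays linear bins across the thermally populated range
[ε_min, 2 kcal/mol] and geometrically widening bins up to ε_max, with one
overflow bin on [ε_max, ∞).  Defaults: ε_min = −12, ε_max = 20 kcal/mol,
150 linear + 40 log bins.  Finite bins are half-open [lo, hi); a sample at
exactly ε_max goes to the overflow bin; samples below ε_min raise rather
than clip.  ε_max = 20 kcal/mol is far above any thermally accessible
solution-system energy, so the split is insensitive to its exact value
(tested over {10, 20, 40}); one global value is used, with per-call
override.  Because the histogrammer also accumulates the per-bin energy sum,
⟨ν⟩_i is exact rather than bin-midpoint approximate, and the binding
scenario uses a deliberately coarser mesh (60 + 20 bins) since the plug-in
log-ratio term is noisy in sparsely populated bins.

## Setschenow fits

k_s = slope/(R T) from ordinary least squares of replicate-mean ΔG values
against concentration with a free intercept; an anchored variant forcing
the line through the zero-salt mean is available
(`anchor_zero=True`) — the free intercept is the default because it does
not propagate the zero-salt point's own error into every difference.  R²
and the two-sided p-value are reported both over concentration means and
over all replicate points, labelled separately.  Confidence intervals are
percentile bootstrap: replicate values resampled with replacement
independently at each concentration, refit each time (default
n_boot = 10⁵); the estimator is deterministic given a seed.  Decimal-log
k_s is exposed only as a ×1/ln 10 conversion.

## Study conditions (pipeline presets)

* `default_config` — dipolar two-site solute (±0.15 e, σ 3.4/3.2 Å) in 150
  "water" particles (σ 3.0 Å, ε 0.5 kcal/mol) with ±0.25 e ions
  (σ 2.5/4.2 Å) under shifted-force electrostatics, L = 18 Å, T = 298.15 K,
  ion-pair scan {0, 2, 4, 6} (≈ 0–1.7 mol/L), 3 replicates, 1500 production
  sweeps sampled every 10, 60 insertions per frame.
* `repulsive_salt_config` — both ion species near-WCA (`repulsive` style,
  σ 4.2/4.6 Å): a pure excluded-volume salt; expected signature k_s > 0
  carried by the EV components.
* `binding_cation_config` — an uncharged "cation" with a deep LJ well to
  the solute (σ 2.6 Å, ε 2.2 kcal/mol): direct association; expected
  signature a negative cation contribution to k_s.  The association signal
  is the small residual of mean attraction against reorganization (a
  second-virial-scale effect), so this preset runs 4000 production sweeps,
  80 insertions per frame, scan {0, 6, 12, 18}, and the coarser mesh.

Problem sizes (box, particle counts, sweep counts, insertion counts,
replicate counts) are chosen so a full scan completes in about a minute on
one core while every qualitative assertion is resolved outside its
bootstrap interval; they are desk-scale study conditions, not estimates of
any published system.

## Validation layout

Independent oracles live alongside the estimator and never share its code
path: Widom insertion (−RT ln⟨e^{−βν}⟩, log-sum-exp, block bootstrap over
frames), BAR (self-consistent Bennett equation solved by bracketed Brent
iteration to 10⁻¹⁰, paired bootstrap errors), the linear-response average,
and the hard-core acceptance estimate −RT ln p0.  Non-convergence (zero
acceptance, non-overlapping work distributions) is returned as a flag, not
an exception.  The test suite checks the engine against closed-form pair
energies and a two-particle Boltzmann distribution (KS test), the
histogrammer against hand counts and conservation, the functional against
its exact limits and the oracles, the corrections against an Ewald lattice
sum and adaptive quadrature, and the fits against known slopes and a
500-study bootstrap coverage experiment.

## Known limitations

* The count-model closure uses two moments per species region; cross-species
  overlap correlations are ignored, and accuracy degrades at high packing
  (numbers above).
* The per-species cavity decomposition is additive by construction, which
  overstates independence when two species' excluded volumes overlap
  strongly.
* NVT concentration series conflate salt addition with a slight pressure
  change; at the default densities this is below the replicate noise.
* OLS assumes linearity of ΔG(c_s); no quadratic Setschenow extension is
  provided.
* The bootstrap is percentile-based and mildly undercovers for very few
  replicates per concentration (coverage ≈ 0.91–0.94 at 10 replicates in
  the synthetic experiment).
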