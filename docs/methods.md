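# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a methods appendix. Units throughout: energies
kcal/mol, lengths Å, charges e, angles radians; k_B = 0.0019872
kcal mol⁻¹ K⁻¹ and T = 300 K (overridable via `PhysicalConstants`), the
Coulomb conversion factor is 332.0636 kcal Å mol⁻¹ e⁻².

## End-state model

The binding free energy is the ensemble difference
ΔG = ⟨G_complex⟩ − ⟨G_receptor⟩ − ⟨G_ligand⟩, with each per-frame G the sum
of five components evaluated in implicit solvent. The ensemble average is
taken over replica means: frames within a replica are serially correlated,
so the replica — not the frame — is the statistical unit for both the mean
and the bootstrap. Six protocols define where the receptor/ligand terms
come from (complex-frame extraction, an independent ensemble, or an
averaged-receptor constant over a declared comparable-ligand set). When the
receptor term is the same constant for every ligand, protocols differing
only in that constant produce ΔG series offset by a constant, and all four
ranking metrics are offset-invariant — which is why `1traj-ar`/`2traj-fr`
and `2traj-ar`/`3traj` give identical rankings in that regime; this
identity is covered by tests.

## Component energies

**MM nonbonded.** Pairwise Coulomb (q_i q_j·332.0636/r) and Lennard-Jones
(Lorentz–Berthelot combination) sums with no cutoff — the single-frame
analysis convention, even though MD production would use one. Exclusions
follow the bonded graph: 1-2 and 1-3 pairs excluded, 1-4 pairs divided by
1.2 (electrostatics) and 2.0 (LJ); both divisors are configurable
(`NonbondedOptions`). Coincident non-excluded atoms raise a singularity
error rather than returning ±inf.

**MM internal.** AMBER functional forms without the ½ factor:
k(r−r₀)² bonds, k(θ−θ₀)² angles, (V/2)(1+cos(nφ−δ)) dihedrals. A collinear
angle triple is reported as a degenerate-geometry error because θ is not
differentiable there and force-field angles should never reach it.

**Nonpolar solvation.** The one-term surface-area model γ·SASA + β with
γ = 0.00542 kcal mol⁻¹ Å⁻² and β = 0.92 kcal mol⁻¹. The offset applies
even at zero area. SASA is Shrake–Rupley with a probe of 1.4 Å and a
deterministic Fibonacci-lattice quadrature (960 points/atom by default);
per-atom areas sum to the total by construction. The quadrature is exact
for an isolated sphere and agrees with the two-intersecting-spheres closed
form to well under 2% at the default density.

**Polar solvation (PB).** The linearized Poisson–Boltzmann equation is
solved by finite differences on a cubic grid whose edge is
fill_ratio × the solute extent (defaults 4.0 and 0.5 Å spacing; the node
count is forced odd so a centred solute sits on a node). Charges are
spread to the eight neighbouring nodes by trilinear weighting. The
dielectric is ε_in inside the union of atom spheres at their intrinsic
radii and ε_out outside; each grid-edge coefficient is the harmonic mean
over the edge's exact inside/outside length fractions (1-D
homogenization), which restores near-quadratic convergence of the Born
energy in the spacing. A probe-inflated ("sas") boundary is available as
an option but is not the default: for a single ion it would move the
cavity boundary from r to r + 1.4 Å and break the Born closed form that
anchors the solver's validation (0.55% error at 0.5 Å, 0.11% at 0.25 Å on
a +1e, 2.0 Å ion). Outer boundary values are a Debye–Hückel superposition
of the atomic charges; the ionic strength defaults to 0 (pure Poisson),
and κ² acts only on solvent nodes. The reported energy is
½Σ q(φ_solvated − φ_reference), where the reference solves the identical
grid with ε ≡ ε_in — subtracting per-charge grid self-energy exactly, so
discretization artifacts cancel charge-by-charge. The linear system is
symmetric positive definite and solved with Jacobi-preconditioned
conjugate gradients to a 1e-6 relative residual; the iteration is
deterministic, and non-convergence raises an error carrying the final
residual. Because the grid is anchored to the solute bounding box,
translations (and axis-aligned symmetries such as mirrors) reproduce the
energy exactly; arbitrary rotations change the discretization at the
sub-percent level of the scheme's truncation error.

Atomic radii are whatever the topology supplies; the toy fixtures use
element-typical values (C 1.7, O 1.6, H 0.3 Å). No claim is made that
these match any particular published radius set.

## Water shell

The N water molecules closest to the ligand are relabelled as receptor
atoms for the frame being analysed; all other waters leave the analysis
species. Distance is min(water oxygen ↔ ligand heavy atom) — the oxygen
carries the molecule's position and hydrogens are noisier; centre-of-mass
and any-atom metrics are available. Ties break on the water molecule id.
Selection is per frame by default; a per-trajectory (majority-vote) switch
exists but is not the canonical mode. Selected waters enter both the
complex and the receptor species, so their self-energy cancels in the
end-state difference except through interaction and desolvation terms;
with N = 0 the pipeline is bit-identical to a water-free calculation.

## Variational entropy

−TΔS_var = k_B T ln⟨exp(β ΔE_inter)⟩ with ΔE_inter the fluctuation of the
receptor–ligand interaction energy E_inter = G_ele^MM + G_vdW^MM about its
mean, computed from the complex-trajectory (1traj) data. The package
evaluates E_inter as complex − receptor − ligand on the same frame, which
equals the receptor↔ligand cross terms. The exponential average pools
frames across replicas by default — the average is nonlinear, so pooling
and per-replica averaging are different estimators; the per-replica mode is
provided behind a flag and labelled non-canonical. Evaluation is in
log-sum-exp form (no overflow for fluctuations of hundreds of kT), returns
exactly 0 for a constant series and is non-negative by Jensen's
inequality. For Gaussian fluctuations of width σ the estimator converges
to σ²/2k_BT (0.8387 kcal/mol at σ = 1); the two-point series {−10, −12}
gives k_BT ln cosh(1/k_BT) = 0.607 kcal/mol.

## Statistics

Bootstrap: resample the replica-level ΔG averages (or ligand-level
(calc, expt) pairs for ranking metrics) with replacement, B = 5000 by
default; the SD of the bootstrap distribution is the quoted error and the
2.5/97.5 percentiles give the 95% CI. Correlation resamples with zero
variance in either margin (or all-equal experimental weights for PI) are
redrawn rather than scored; the redraw count is reported for auditing.
cMUE resamples at the ligand level — the resampling unit for error metrics
is an interpretation, documented as such. The PI uses the
Pearlman–Charifson definition: weights |ΔΔG_expt|, scores +1/−1 for
sign agreement/disagreement of the calculated difference, 0 for an exactly
zero calculated difference. Spearman uses mid-rank ties. pIC50 converts to
ΔG as −k_B·T·ln(10)·pIC50 at 300 K; 300 K (not 298.15 K) is the package
default because it matches the simulation thermostat and reproduces the
tabulated conversions to one decimal.

Calibration: over 500 synthetic bivariate-normal datasets (n = 25 pairs,
population Spearman 0.7), the percentile CI covers the truth ~96% of the
time — nominal within the expected small-n behaviour of percentile
bootstrap intervals.

## Synthetic generators

`gen_energy_ensembles` emulates collated per-frame component tables with a
known answer. Per ligand, the complex row of each frame is constructed as
receptor-extract + ligand-extract + interaction, component by component,
so single-trajectory cancellation is exact (ΔG_int ≡ 0, and 1traj variance
comes only from interaction fluctuations — demonstrating why 1traj is
low-noise). Strain offsets shift the extracted species relative to the
free ensembles, making expected protocol values differ exactly as the
protocol definitions predict: E[3traj] = true ΔG,
E[1traj] = true − both strains, etc. The manifest records every expected
value and the generator's own standard error per protocol so tests audit
recovery against the generator's bookkeeping, not hand-tuned tolerances.
Defaults: 25 replicas × 40 frames, frame noise 3 kcal/mol, replica spread
1 kcal/mol, interaction fluctuation 1.5 kcal/mol, strains 2.0/1.0
kcal/mol — a mid-range picture of the replica variability reported for
ensemble MMPBSA studies. Noise draws are allocated across the five
components by fixed weights, so components are perfectly correlated within
a frame; real data correlate only partially, which no test here depends
on. Randomness flows from one seed via `SeedSequence` splits per ligand:
tables are bit-reproducible across platforms.

`gen_toy_complex` builds a rigid cage "host" (neutral overall, alternating
charges), a small bonded ligand cluster in the cavity, and 3-atom waters on
concentric shells, with optional Gaussian frame jitter. Water molecules
carry zero-constant bonds/angles: they supply the usual intramolecular
nonbonded exclusions without internal energetics. It is a geometric stand
for a solvated complex, not a parameterized force field; no claim of
chemical realism is made beyond charge neutrality, clash-free placement
(minimum separation 0.8 Å enforced) and TIP3P-like water geometry.

## What the tests do and do not show

Synthetic ensembles have Gaussian, frame-independent noise and exactly
linear protocol structure; real MMPBSA series are autocorrelated,
heavy-tailed and force-field-dependent. Passing recovery tests therefore
validates the estimators and their bookkeeping, not the physical accuracy
of MMPBSA for any real target. The PB solver is validated against
closed-form oracles (Born ion, symmetry, sign constraints) on desk-scale
systems; production-size proteins would need a multigrid or similar
accelerated solver and a molecular-surface dielectric, both out of scope.
Normal-mode entropy, nonlinear PB, the two-term nonpolar model and AMBER
prmtop/DCD parsing are deliberately not implemented.

## Problem sizes used in validation

Born ion at 0.5/0.35/0.25 Å spacing (33³–65³ nodes); toy complexes of
~20–30 atoms; ensembles of 25 replicas × 40 frames; 100 seeded recovery
runs of a 10-ligand study; 500 datasets × 1000 resamples for CI coverage.
These sizes keep the full validation suite in the minutes range on one
CPU while leaving every estimator on its default settings.
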