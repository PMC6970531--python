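# Methods

`rnapconf` packages three quantitative analyses of bacterial RNA polymerase
(RNAP) conformational regulation: rigid-body domain-motion measurement
between atomic models of different conformational states, quantification of
continuous clamp heterogeneity from cryo-EM multibody per-particle
eigenvalues, and a four-step free-energy/flux model of transcription
initiation that explains how one regulator can inhibit some promoters while
activating others.  This note records the models, the assumptions, the
numerical choices, and what the synthetic-data tests do and do not show.

## Coordinate models and domain definitions

Structures are read through gemmi (PDB v3.3 and mmCIF/PDBx) into an ordered
atom list keyed by author residue numbering; all residue ranges in the
package are author-numbered, 1-based, and inclusive on both ends, matching
how such ranges are conventionally quoted.  Alternate locations are resolved
to the highest-occupancy conformer (ties: first occurrence).  Insertion
codes are carried as distinct residues ordered after the base number; *E.
coli* RNAP models rarely use them.

The built-in domain table for *E. coli* RNAP:

| domain           | subunit(s), residues                                        |
|------------------|-------------------------------------------------------------|
| clamp            | β 1319–1342; β′ 1–342, 1318–1344; σ70 92–137, 353–449       |
| β′shelf (+jaw)   | β′ 787–931, 1135–1150, 1216–1317                            |
| Si3              | β′ 948–1126 (trigger-loop insertion, SBHMa+SBHMb)           |
| Si1              | β 225–343 (β-lobe insertion)                                |
| bridge helix     | β′ 770–805 (window bracketing the kink residue β′L788)      |
| βlobe-Si1        | β 151–453                                                   |

The bridge-helix window width and the βlobe boundaries are package choices
(no standard printed definition of the *Eco* βlobe exists); both are
overridable, and any rotation measured for βlobe-Si1 therefore depends on
the chosen boundary and should not be read as exact.

## Rigid-body superposition and domain rotations

Superposition is closed-form least squares: SVD of the weighted covariance
(Kabsch) with a reflection guard so a proper rotation is always returned.
An independent route via Horn's quaternion eigen-method is kept in the
package purely as a cross-check; the two agree in RMSD to better than 1e-9 Å
on random clouds, which the test suite and acceptance script verify on
10,000 cases.

Domain rotations use the standard two-stage "core-then-domain" protocol:
superpose state B onto state A over a core selection (everything that does
not move), then fit the residual rigid transform carrying the domain of A
onto the core-aligned domain of B.  The transform is decomposed into a screw
axis: angle from atan2 of the antisymmetric-part norm against the trace
(numerically stable at both the 0° and 180° branch points, where a plain
arccos loses half the working precision), axis from the antisymmetric part
(from the symmetric part within ~1e-7 of 180°), screw translation along the
axis, and a pivot chosen as the axis point nearest the domain centroid.
Axes for rotations under 0.1° are flagged unreliable.

Helix kink angles fit a local axis to the Cα of each flank (default 12
residues; the kink residue belongs to neither flank) using the
bisector-cross-product construction: at each interior residue the bisector
of the vectors to its neighbours points at the helix axis, and cross
products of successive bisectors give the local axis direction.  This is
exact for an ideal helix regardless of how many fractional turns the flank
covers; a principal-component axis, by contrast, is biased by several
degrees for non-integer turn counts.  Kink values still depend on the flank
window on real, irregular helices, so measured kinks should be quoted with
a ±3° method tolerance.

Buried interface area uses the one-sided convention
[SASA(A) + SASA(B) − SASA(A∪B)]/2 with Shrake–Rupley sampling (960
points/atom) through biotite, using a Bondi van der Waals radii table
shipped with the package (1.80 Å fallback for unlisted elements).  Against
the closed-form two-sphere overlap the sampled value is within 2%;
cross-implementation agreement should only be expected at the ±10% level.

## Clamp heterogeneity from multibody eigenvalues

Multibody refinement of a cryo-EM dataset assigns every particle an
amplitude (eigenvalue) along each principal component of relative body
motion.  For the RNAP clamp these amplitudes behave as a continuous
conformational coordinate whose histogram is close to Gaussian.  The
pipeline:

1. **Gaussian fit** — either moment-based ("mle": mean and *population*
   standard deviation, since the fit describes the observed ensemble rather
   than estimating a superpopulation; the n−1 convention is available by
   flag) or a least-squares fit of a Gaussian density to the normalized
   histogram (60 equal-width bins spanning mean ± 4 sd).  Both report the
   sum of squared residuals on that histogram as goodness.
2. **Tercile binning** — stable sort by eigenvalue (ties keep input order),
   lowest third → low bin, highest third → high bin, remainder distributed
   low → mid → high, so counts differ by at most one particle.
3. **Calibration** — an externally measured rotation `theta_bin` between
   the mean conformations of the low and high bins (from per-bin
   reconstructions and rigid-body fitting upstream, or from the geometry
   module on synthetic constructs) divided by the eigenvalue gap between
   the outer-bin means gives degrees per eigenvalue unit.  The rotation is
   assumed *linear* in the eigenvalue — the same assumption implicit in the
   upstream procedure, whose middle bin sits half-way between the outer
   two.
4. **98% range** — `theta_98 = dpu × 2 z σ` with z = 2.326348 (1% excluded
   per tail; the tail fraction is configurable).

For Gaussian amplitudes the ratio theta_98/theta_bin is a universal
constant: the outer-tercile mean of a standard normal is
E[Z | top third] = 3 φ(Φ⁻¹(2/3)) ≈ 1.09079, so
theta_98/theta_bin = 2·2.326348 σ / (2·1.09079 σ) ≈ 2.1327 independent of
mean, width, and calibration.  The tests verify this to ±0.02 on 10⁶
simulated particles, plus shift/scale equivariance and the restriction
ordering (narrower eigenvalue distributions report strictly narrower
ranges at fixed calibration).

## The four-step initiation flux model

Transcription initiation is modeled as a linear pathway

    R+P ⇄ RP1 ⇄ RP2 ⇄ RPo → RP_ITC

over a free-energy landscape: four well energies, three reversible
transition-state energies, and one final transition-state energy for the
irreversible promoter-escape step.  Energies are in kBT (dimensionless);
rates follow k = A·exp(−(G‡ − G_well)) with a single prefactor A (default
1), so detailed balance k_fwd/k_rev = exp(ΔG) holds per transition by
construction.  Absolute times are not interpretable — only ratios and fold
changes are, and that is all the package asserts.  The first forward rate
carries an optional RNAP-activity factor (pseudo-first-order binding).

RP_ITC formation regenerates free promoter — the minimal closure that
admits a nonequilibrium steady state.  The steady state is solved exactly
(null-space linear solve with the normalization row); an independent oracle
integrates the master equation with a stiff BDF integrator (rtol 1e-11,
atol 1e-14, horizon doubled until the residual max|dp/dt| < 1e-12).  The
two agree in flux to better than 1e-8 relative over 1,000 random schemes,
and as the escape rate vanishes the occupancies converge to the Boltzmann
weights of the landscape (verified to 1e-8).

**Perturbation operators.**  The regulator TraR is modeled as lowering the
RP1⇄RP2 barrier, lowering the RP2 well relative to RPo, and lowering the
RP2⇄RPo barrier (default −2 kBT each); deleting σ70 region 1.1 — the
domain that occupies the DNA channel and must be ejected late on the way to
RPo — is modeled as lowering the RP2⇄RPo barrier only (default −2 kBT).
Neither touches the initial binding step, consistent with kinetic evidence
that such regulators act after binding.  An optional factor f_dissoc ∈
(0, 1] on the escape rate expresses that bound TraR must dissociate before
escape; the default of 1 keeps the scenario a pure landscape perturbation.

**Preset landscapes.**  The exact rate inputs behind the published
illustrations are not available, so the shipped presets are package-chosen
energies realizing the qualitative promoter classes:

- *inhibited* (rRNA-promoter-like): wells (0, −1, −2, −3) kBT, barriers
  (2.5, 1.5, 1.0), escape barrier 7.0.  All internal steps are fast
  relative to escape, so the pathway stays near equilibrium and the flux
  samples the Boltzmann occupancy of a shallow RPo well.  Lowering an
  internal barrier then changes nothing (fold ≈ 1.001 for the σ1.1
  scenario), while stabilizing RP2 drains RPo occupancy → TraR fold ≈ 0.40.
- *activated* (amino-acid-promoter-like): wells (0, −0.5, −1, −8) kBT,
  barriers (2.5, 1.5, 6.0), escape barrier −3.0.  The high RP2→RPo barrier
  is rate-limiting and the deep RPo well escapes forward rather than
  dissociating.  Lowering that barrier raises the flux ~5-fold (σ1.1
  scenario); the composite TraR perturbation nets ~1.7-fold activation
  (the barrier drop wins over the flux lost to stabilizing RP2).

These numbers are design choices documented here, not fitted values; a
user-supplied landscape in the same JSON config format replaces them.

## Synthetic data: what it emulates, and what it does not

- **Two-domain constructs** (Gaussian Cα clusters on two chains, one rigid
  rotation applied, optional isotropic coordinate noise on the moved copy)
  emulate the rigid-body motions between conformational states at the sizes
  of the real modules: noise-free recovery is exact to 1e-6°, and with a
  188-residue domain (Si3-sized, ~12 Å positional spread) and 0.2 Å noise
  the angle is recovered within 0.3° across 100 replicates.  Real domains
  deviate from rigidity and pairing can be incomplete; the constructs test
  the estimator, not model quality.
- **Ideal/kinked helices** (Cα on a 2.3 Å cylinder, 1.5 Å rise, 100°
  twist, downstream half rotated about an axis through the kink residue
  perpendicular to the helix axis) give exact kink recovery; real bridge
  helices are irregular, hence the ±3° method tolerance above.
- **Eigenvalue ensembles** are exactly Gaussian with an exactly linear
  eigenvalue→rotation map — the idealization under which theta_98 is
  derived.  Real amplitude distributions are only approximately Gaussian
  and the linearity is an assumption; passing tests validate the estimator
  under its own model, not that model's fit to any particular dataset.
- **Landscape presets** are qualitative promoter classes, not measured
  promoters.

All generators take explicit seeds (default 0) and are bit-reproducible.

## Problem sizes and degenerate inputs

The shipped tests and the acceptance script run entirely on synthetic data
at desk scale: 10,000 random clouds for the superposition cross-check,
10⁶ particles for the range-ratio law (terciles of the 370,965-particle
matched dataset size are also exercised), 1,000 random schemes for the flux
oracle, 100 noise replicates for rotation recovery.  Validation of the
structural measurements against deposited coordinate entries (6N57, 6N58,
6P1K, 6OUL and comparison crystal structures) requires a one-time download
via `rnapconf fetch`; no network access happens inside library code or
tests.

Degenerate inputs are handled explicitly: rotations under 0.1° flag their
axis unreliable; near-collinear point sets never return a reflection;
zero-variance eigenvalue series, empty selections, barriers below flanking
wells, and all-zero rate schemes raise typed errors.

## Known limitations

- Atom pairing assumes shared author numbering across models of the same
  protein; there is no sequence alignment fallback.
- The βlobe boundary (and hence any βlobe-Si1 rotation) is a package
  default, not a published definition.
- theta_98 inherits both the Gaussian and the linearity assumptions;
  heavier-tailed eigenvalue distributions would widen the true range
  relative to the estimate.
- The flux model is unicyclic and deterministic; no stochastic simulation,
  no NTP-concentration mass action, and no fitting to experimental
  transcription data.
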