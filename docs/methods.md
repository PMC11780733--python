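# Methods

This note documents the models, conventions and numerical choices behind
puckerfit, and what the synthetic fixtures do and do not emulate.

## Pseudorotation algebra

Ring torsions are indexed ν0 = C4′–O4′–C1′–C2′ … ν4 = C3′–C4′–O4′–C1′
with ν<sub>j</sub> = τ<sub>m</sub> cos(P + (j−2)·144°), so
ν2 = τ<sub>m</sub> cos P. The forward map uses
P = atan2(((ν4+ν1)−(ν3+ν0)) / (2(sin 36° + sin 72°)), ν2) and
τ<sub>m</sub> as the hypotenuse of the two atan2 arguments, avoiding the
cos P = 0 pole of the tangent form and keeping τ<sub>m</sub> ≥ 0. The
round trip is exact to machine precision; an all-zero ring raises a
planar-ring error rather than returning an arbitrary phase. North is
the open interval −90° < P < 90°; both boundaries classify south.

Angles are wrapped explicitly: raw torsions in [−180°, 180°), backbone
angles and P in [0°, 360°). `wrap180`/`wrap360` guard against the
floating-point modulo returning exactly 360 for tiny negative inputs.

**Scan constraints.** The constrained scan fixes two dihedrals per
conformer: τ1 (configurable; default the ring torsion ν1 =
O4′–C1′–C2′–C3′, since the fitted ring torsion's atom quadruple is a
configuration choice) directly from the inverse map, and δ
(C5′–C4′–C3′–O3′, not itself a ring torsion) as ν3 + Δδ. Δδ was
calibrated once against the idealized fixture geometry: δ − ν3 is
120.9° on the B-form and 122.1° on the A-form duplex, so the default
constant is 120.9° and is exposed as a parameter.

## Torsion model and refit

The dihedral energy is the AMBER sum Σ (V<sub>n</sub>/2)/IDIVF ·
(1 + cos(nφ − γ)). Phases are restricted to {0°, 180°} so the refit is
an ordinary weighted linear least squares in the signed half-barriers; a
negative fitted amplitude is reported as a positive one with γ = 180°
(the induced additive constant is absorbed by the always-fitted offset,
and energies are reported relative to the scan minimum). Periodicities
default to n ∈ {1, 2, 3} per fitted type and are configurable.
Per-conformer weights default to 1, with optional Boltzmann
down-weighting of high-energy points. The design matrix is checked by
SVD; a relative smallest singular value below 1e−10 raises an error
naming the collinear columns. Instances of the same torsion type are
summed per conformer before solving.

The fit target is ΔE = (E_QM_gas + G_solv_QM) − (E_MM_nontorsion +
G_solv_MM) per conformer, which books conformation-dependent solvation
on both sides exactly once. Composite reference energies combine a
two-point X⁻³ CBS extrapolation of the MP2 correlation energy and a
two-point X⁻⁵ power law for HF (both on TZ/QZ; the HF scheme is a
package choice among the common two-point forms and is recorded in fit
metadata), a CCSD(T)−MP2 correction at DZ, and the solvation energy.
Inputs must be in kcal/mol (1 hartree = 627.509474 kcal/mol; a
converter is provided).

**Targeted adjustment.** `empirical_adjustment` applies the final
empirical touch sometimes needed after a refit: shifting the energy of
one pseudorotation region (e.g. stabilizing the north minimum) while
holding another (the south minimum) fixed. Because torsion profiles are
defined up to an additive constant, achieved changes are measured
relative to the hold point. The correction is a least-squares solve
over the allowed periodicities at sample points across both windows;
if the achieved changes deviate from the request by more than 10%
(configurable) an infeasibility error carries the achieved numbers. The
magnitude of any such adjustment is a user decision, not a default.

**frcmod I/O.** Only the DIHE block is interpreted; all other blocks
pass through verbatim, making read → write → read a byte-stable fixed
point. Multi-term dihedrals use the negative-periodicity continuation
convention on all but the last term. Atom-type quadruples match
palindromically.

## Trajectory statistics

%N is the per-residue fraction of frames with north pucker; aggregates
exclude a configurable number of terminal residues per chain end
(duplex termini fray and are conventionally excluded). The PMF of P is
−RT ln(n_bin/n_max) on 3° bins (R = 1.987204×10⁻³ kcal/(mol·K), default
298.15 K). Empty bins are reported as missing values, never clamped.
Count CIs are ±1.96×SEM with the SEM from block averaging over 10 equal
time blocks, because frames from a trajectory are autocorrelated; with
independent draws the block SEM reduces to the binomial one. The CI is
propagated to the PMF holding n_max fixed; a lower count bound at or
below zero yields a missing upper CI.

Rotamer windows are the standard tripartite convention g⁺ = [0°, 120°),
t = [120°, 240°), g⁻ = [240°, 360°). BI is ε/ζ = t/g⁻, BII is g⁻/t;
the canonical α/γ combination is g⁻/g⁺ and the common flipped substate
g⁺/t. Substate percentages sum to 100 per residue by construction.

## Helical analysis

Base frames come from a least-squares (Kabsch) superposition of
standard-reference-frame base geometries onto the observed ring atoms
(≥3 required); the fitted rigid transform *is* the frame. Intra-pair,
step and helical parameters all use the same mid-frame construction:
the two triads are rotated by ±half the bend angle about their common
hinge, translations are read in the mid triad, and the bend splits into
tilt/roll (or buckle/propeller, with opening the twist-like component)
by the hinge phase. The strand-2 base frame is flipped (y, z negated)
before pairing; `pair_parameters` takes already-flipped frames by
default so that coincident frames give identically zero parameters.

Helical parameters derive from the screw decomposition of the step
transform: htwist and hrise are the rotation about and translation
along the local helical axis; inclination/tip decompose the angle
between each pair z-axis and the axis (inclination is the x-rotation,
i.e. the long-axis tilt); x/y-displacement locate the pair origins
relative to the screw axis in the axis-aligned triads. The sign
convention was fixed so that A-DNA geometry — base planes tilted such
that a covalently connected backbone exists — reports positive
inclination, matching the standard reference values (A: +20.7°, −5.3 Å;
B: +1.5°, 0 Å). Construction (`helical_frames`) and analysis are exact
inverses, which the rebuild-oracle tests check to 1e−9.

Groove widths are cross-strand P–P distances in the El Hassan–Calladine
convention, here implemented with a fixed ±3-step index offset along
the duplex (the offset giving the canonical minor-groove separation on
idealized B-DNA), minus a 5.8 Å phosphate-radius correction. The
correction is a parameter: some tools report raw P–P distances, and
passing 0 reproduces that convention. Whether averages use all levels
or interior levels only is a flag (`interior_only`).

## Synthetic fixtures

`simulate_pucker_series` draws, per residue, an exact two-state Markov
chain with stationary north fraction p_N and visit-averaged mean dwell
`switch_time` (τ_N = 2·switch_time·p_N, τ_S = 2·switch_time·(1−p_N));
emitted P values are the state mean (18° north, 150° south by default,
matching typical N/S minima) plus wrapped Gaussian noise (σ = 12°).
Backbone substates are i.i.d. categorical draws per frame (default 25%
BII, 1.5% α/γ flips — a typical B-DNA magnitude) emitted around window
centers with σ = 8°. The generator returns the realized hidden-state
fractions and dwell times so estimator tests can separate estimation
error from sampling noise. It does not emulate sequence dependence,
inter-residue coupling, or fraying kinetics; passing tests show the
estimators are correct on their stated model, not that the model
captures all features of real trajectories.

`synth_scan` builds 36-point scans whose four energy components are
smooth planted functions arranged so the fit target equals the planted
Fourier profile exactly at zero noise; Gaussian noise is added to the
QM gas term only.

`build_fiber_duplex` propagates standard base-pair frames along a
regular helix with per-form canonical helical parameters (B: htwist 36°,
hrise 3.38 Å, inclination 1.5°, x-displacement 0; A: 32.7°, 2.81 Å,
20.7°, −5.3 Å) and attaches a deoxyribose ring generated at the form's
pucker (B: P = 155°, τ<sub>m</sub> = 36°, χ = 250°; A: P = 18°,
τ<sub>m</sub> = 38°, χ = 202°). The ring is a pentagon with
out-of-plane displacements solved numerically so the Altona–
Sundaralingam state matches the request; exocyclic atoms use idealized
tetrahedral geometry with face choices that reproduce the
β-D-deoxyribose chirality (validated against CCD idealized nucleotide
geometry: δ agrees to ~0.4°). Phosphates are bonded to the previous
residue's O3′ (1.60 Å) along a canonical ε torsion and O5′ closes both
bonds exactly where the two bond spheres intersect, steering ζ toward
its canonical rotamer; both strands are optimized separately because
the pair dyad does not carry the 5′-arm construction across strands
exactly. The result is covalently connected (O3′–P 1.59–1.71 Å on both
strands and both forms) with near-canonical backbone torsions, but it
remains an idealized fiber model: bond angles at the closure are not
force-field-relaxed and no hydrogens are built.

## Problem sizes and determinism

All estimator validations run at desk scale chosen to make the
statistical assertions sharp: 5×10⁵ frames for %N recovery (binomial
SE corrected for the switching correlation time), 200 seeds for noisy
fit recovery, 10 seeds for PMF well-depth coverage, 12-mer duplexes for
the geometry round trips. Every stochastic path takes an explicit seed
through `numpy.random.default_rng`, so all results are bit-reproducible
across platforms.

## Known limitations

* The frcmod reader handles the common frcmod dialect (whitespace-
  tolerant DIHE entries, verbatim other blocks), not every historical
  AMBER format variant.
* Base-pair identification in `duplex_report` is positional (or an
  explicit pairing map); there is no hydrogen-bond inference.
* The groove-width index offset is fixed (±3); for strongly distorted
  duplexes a curve-based method would be more faithful.
* `empirical_adjustment` measures energy changes relative to the hold
  region, the natural gauge for torsion profiles; absolute single-point
  shifts are not meaningful in this representation.
* Trajectory ingestion is via extracted angle tables or PDB snapshots;
  binary trajectory formats are out of scope by design.
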