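# puckerfit

Computational machinery for refining deoxyribose sugar-pucker torsion
parameters in AMBER-style DNA force fields, together with the
conformational-analysis battery used to validate such parameters:
sugar-pucker populations, pseudorotation potentials of mean force,
backbone substate statistics, base-pair/step/helical parameters and
groove widths.

It is aimed at force-field developers and simulators of nucleic acids
who need to (a) construct pseudorotation-constrained torsion scans,
(b) refit dihedral Fourier terms against solvation-corrected quantum
reference energies, and (c) quantify how close a simulated duplex is to
the A- or B-form.

## The science in brief

**Pseudorotation.** The five endocyclic furanose torsions are summarized
by a phase *P* and amplitude τ<sub>m</sub> (Altona–Sundaralingam):
ν<sub>j</sub> = τ<sub>m</sub> cos(*P* + (j−2)·144°). A sugar is north
(N, C3′-endo, A-form-like) iff −90° < *P* < 90°, otherwise south (S,
C2′-endo, B-form-like). Constrained scans place conformers on a 0–360°
grid of *P* at 10° intervals by constraining the ring torsion τ1 and the
backbone torsion δ to the values the inverse pseudorotation map implies.

**Torsion refitting.** Dihedral energies use the AMBER form
E(φ) = Σ<sub>n</sub> (V<sub>n</sub>/2)(1 + cos(nφ − γ)) with γ ∈ {0°, 180°},
which makes the refit linear in the half-barriers. The fit target per
conformer is the solvation-aware residual

    ΔE_i = (E_QM_gas + G_solv_QM)_i − (E_MM_nontorsion + G_solv_MM)_i

so conformation-dependent solvation enters both sides once and is never
double counted. High-level reference energies are assembled from
two-point CBS extrapolations of HF (X⁻⁵) and MP2 correlation (X⁻³)
energies at aug-cc-pVTZ/QZ, a CCSD(T)−MP2 correction at aug-cc-pVDZ,
and the solvation energy.

**Conformational analysis.** Helical parameters follow the mid-frame
(CEHS/3DNA-style) construction on base reference frames fitted from
standard base geometries; inclination and x-displacement are the primary
A/B monitors (B-DNA ≈ 1.5°, 0 Å; A-DNA ≈ 20.7°, −5.3 Å). PMFs of *P*
use −RT ln(n<sub>bin</sub>/n<sub>max</sub>) in 3° bins with ±1.96×SEM
CIs from block averaging. BI/BII (ε/ζ = t/g⁻ vs g⁻/t) and α/γ substate
populations use the standard tripartite rotamer windows. Flat-well
restraint energies (terminal base-pair H-bonds, χ anti-window) are
provided as bookkeeping functions.

A synthetic-fixture module generates every input with planted ground
truth: two-state N/S pucker time series with prescribed stationary
populations and switching kinetics, Fourier-planted torsion scans, and
idealized A-/B-form duplex coordinates built from canonical helical
parameters with covalently connected sugar-phosphate backbones.

## Worked example

Build an idealized A-form hexamer and analyze it:

```sh
puckerfit build --form A --sequence GGGCCC -o a.pdb
puckerfit helix a.pdb --exclude-terminal 1
```

yields (abridged):

```
parameter        mean       n
delta            85.93      8
chi             201.99      8
P                18.00      8
percent_N       100.0       8
x_displacement   -5.2997    3
inclination      20.6853    3
htwist           32.6989    3
hrise             2.8106    3
```

The sugars are all north (*P* = 18°, δ ≈ 86°, χ anti), and the helical
monitors reproduce the canonical A-DNA reference values (inclination
20.7°, x-displacement −5.3 Å) because the analysis algebra inverts the
construction exactly. The same library calls are available from Python
(`puckerfit.build_fiber_duplex`, `puckerfit.duplex_report`,
`puckerfit.fit_fourier`, ...).

Other subcommands: `pucker` (per-residue angles from a PDB), `fit`
(torsion refit from a scan table), `energy`, `pmf`, `classify`,
`populations`, `simulate`, `restraint-energy`.

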