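# Methods

## Scope and model of the system

The package analyzes a ternary complex of an αβ T-cell receptor (TCR) bound
to an MHC class II molecule (HLA-DRB1) presenting a citrullinated
self-peptide, plus the unliganded (apo) TCR, and the two binding assays used
to quantify the interaction: steady-state surface plasmon resonance (SPR)
and fluorescence-polarization (FP) peptide competition. All structural
criteria are heavy-atom based: crystal structures in the 2.4–3.2 Å
resolution range carry no reliable hydrogens, so hydrogens are dropped at
parse time and every cutoff below refers to heavy atoms.

## Structure parsing and annotation

Coordinates are read with gemmi from mmCIF or PDB. Alternate locations are
resolved by keeping the highest-occupancy conformer, ties broken toward
altloc A. Modified residues are retained in the polymer — citrulline (CIR),
the deiminated, charge-neutral form of arginine that creates the
autoantigenic epitope, must survive parsing at its sequence position.
Waters and non-polymer ligands are kept separately and excluded from every
interface computation, which are therefore strictly protein–protein.
Author residue numbering is used verbatim; no renumbering is performed.

Chain roles (mhc_alpha, mhc_beta, peptide, tcr_alpha, tcr_beta) come from an
explicit chain→role map; a chain left unmapped whose length falls in 9–25
residues is auto-assigned as the peptide (an MHC-II-bound epitope with
flanking residues is typically a 12–16-mer; the analyzed epitope with its
two solubility lysines is a 14-mer).

TCR variable domains are assumed to follow IMGT unique numbering as
deposited, with CDR1 27–38, CDR2 56–65, CDR3 105–117 and framework (FW)
elsewhere in 1–129; the intervals are configurable. Residues numbered above
129 belong to the constant domains, whose numbering convention in deposited
files is not guaranteed, and are deliberately left unlabelled (they are
still part of the TCR side for BSA totals, but outside the region
percentages).

The peptide register maps residues onto MHC-II pockets P-2…P9 anchored at a
caller-supplied P1 residue (the P1-tyrosine of the epitope); there is no
pocket P0, and residues outside the groove span are labelled `flank`. The
shared-epitope test compares the β-chain 70–74 pentapeptide against QKRAA,
QRRAA and RRRAA, case-insensitively; it is a pure function of that window.

## Surface areas

SASA uses the Shrake–Rupley construction: each atom's expanded sphere
(van der Waals radius + probe, probe 1.4 Å) is sampled on a deterministic
Fibonacci (golden-angle) lattice, default 960 points, and the accessible
fraction times 4π(r+p)² is the atom's area. Determinism matters more here
than marginal accuracy: identical inputs give bit-identical areas, and the
960-point default keeps single-sphere and two-sphere closed forms within 1%
(the convergence test bounds the 960→3840-point drift below 0.5%). The
default radii table is element-based (C 1.70, N 1.55, O 1.52, S 1.80 Å); a
Chothia-style protein set is shipped as an alternative. Unknown elements are
an error, never a silent default. Citrulline needs no special casing — its
side-chain atoms are ordinary C/N/O.

Buried surface area is the two-sided sum
SASA(TCR) + SASA(pMHC) − SASA(complex). Because both sides are evaluated on
the same lattice, each atom's burial is non-negative and the per-residue
decomposition is exact bookkeeping. Region percentages are the partition of
the labelled (variable-domain) TCR-side burial and always sum to 100; chain
shares are over the full TCR-side burial. The reported total is the
two-sided sum — if a single-sided convention is wanted, the per-side fields
are reported alongside.

## Contacts

Every inter-side heavy-atom pair within 4.0 Å is a van der Waals contact.
Pairs of polar atoms (N, O, or S, but not S–S) within 3.5 Å are additionally
hydrogen bonds — a purely distance-based definition with no angular term,
matching the distance-only criteria the interface tables are built on.
SG–SG pairs within 4.5 Å are disulfides. Salt bridges are charged-group
nitrogen–oxygen pairs (Lys NZ, Arg NH1/NH2/NE vs Asp OD1/OD2, Glu OE1/OE2)
within 4.0 Å; citrulline is neutral and its side chain can never form one.
A pair may carry several kinds; reports order them most-specific-first
(disulfide > salt_bridge > hbond > vdw). Detection uses a k-d tree
restricted to the largest cutoff and is required, by test, to agree exactly
with the exhaustive all-pairs scan.

## Geometry

The docking angle is measured between the Vα→Vβ centroid vector (centroids
over variable-domain Cα only, mirroring the center-of-mass spheres used in
footprint figures) and the total-least-squares axis through the peptide Cα
trace, folded into [0°, 90°] so the convention carries no sign ambiguity.
The peptide axis is oriented from the N-terminal (P-2) end toward P9, but
the folding makes the result independent of that choice. Superposition is
the SVD form of the Kabsch algorithm with the determinant correction, so
reflections are never returned; r.m.s.d. is reported over the matched
selection and is invariant under rigid pre-motion of either input.

## Binding models

Steady-state SPR responses follow the one-site isotherm
R_eq(C) = R_max·C/(K_D + C). Replicate points are pooled into a single
unweighted nonlinear least-squares fit (scipy `curve_fit`), with standard
errors from the Jacobian. A per-replicate mode (fit each replicate, average
K_D geometrically) is exposed because averaged per-experiment fits are a
common alternative convention; both agree exactly on noiseless data.
Initialization: K_D at the concentration nearest half-maximal response,
R_max at 1.1× the maximum response — robust on sparse dilution series.
Inputs are assumed reference-cell subtracted.

FP competition curves are fitted with the four-parameter logistic; the
reported IC50 is the inflection parameter (the convention of the
"sigmoidal dose-response" fit in Prism-style software). A fitted bottom
plateau above 20% residual binding flags `reached_full_inhibition = False`;
a curve that never drops 25% below its upper plateau within the tested range
is reported as "IC50 > max tested" rather than an extrapolated number.
`fix_hill=1.0` reproduces the classic fixed-slope model.

Mutational impact is binned on fold = K_D(mut)/K_D(wt) with left-closed
intervals [0,2), [2,5), [5,10), [10,∞) → no_effect, moderate, severe,
deleterious. The prose convention ("2–5-fold", ">10-fold") is ambiguous
exactly at the boundaries; left-closed bins are the deliberate tie-break,
so a fold of exactly 5 is "severe". Improved affinity (fold < 1) is
no_effect with an "improved" note.

## Synthetic data: what it emulates, and what it does not

The sphere clusters carry exact expected areas from the isolated-sphere and
two-sphere spherical-cap formulas; the pairwise-cap expectation is exact
whenever no sample point is occluded by two neighbors at once, and all
shipped fixtures stay in that regime. The miniature five-chain complex
plants, by construction: one H-bond from a CDR3α residue to the P-1
citrulline, one C–C van der Waals pair at pocket P5, one CDR2β
lysine–glutamate salt bridge to the MHC, one framework disulfide at 4.2 Å,
a QKRAA window at β70–74, a 12-mer register anchored at Tyr-P1, and an
exact, configurable docking angle (the Vα/Vβ Cα sets are placed symmetric
about their centroids). Every other inter-side atom pair is kept beyond the
4.5 Å maximum cutoff.

The simulators draw additive Gaussian noise around the exact model curves:
SPR as a duplicate 10-point twofold dilution from 200 μM with R_max 100 RU
and σ = 2 RU; FP as a triplicate 12-point threefold dilution from 500 μM
with σ = 3% between plateaus at 100% and 0%. The threefold factor is a
design choice: a competition series must cover both plateaus of a
low-micromolar IC50 to identify the logistic, and a twofold ladder from
500 μM bottoms out at 0.24 μM, leaving the lower plateau unobserved (its
200-simulation IC50 spread is ~15% versus ~6% for the threefold design).
Seeds are mandatory and all generators are bit-reproducible.

None of the synthetic structures have realistic stereochemistry, side-chain
rotamers or crystallographic disorder, and the noise models omit
systematic SPR artifacts (drift, depletion, mass transport) and FP
plate effects. Passing tests therefore demonstrate correctness of the
computations and estimators under the stated models — not robustness to
every pathology of real data.

## Numerical choices and degenerate inputs

Fits are bounded to positive parameters; non-convergence returns a flagged
result with diagnostics, never a silent number. Steady-state fitting
requires ≥5 distinct concentrations and warns when the series spans less
than one order of magnitude; competition fitting requires ≥6. The docking
angle requires ≥5 peptide Cα; superposition requires ≥3 matched atoms and
warns on collinear selections. An empty interface yields an empty contact
set and a complete all-zero footprint table, not an error. Report files are
byte-deterministic for identical configuration and inputs: sorted keys,
fixed float precision (1 decimal for Å² and %, 2 for Å, 3 significant
figures for μM), and an embedded configuration digest that excludes
output-location and verbosity settings.

## Problem sizes

The shipped analyses run on the synthetic fixtures (tens of atoms, so
exhaustive O(n²) oracles are instantaneous) and on simulated assay designs
of 20–36 points; the consistency study uses 200 simulated experiments.
The structural pipeline itself scales to full deposited complexes
(~19,000 atoms) through the k-d-tree neighbor search.

## Known limitations

- H-bonds have no angular or chemical-environment term; counts are upper
  bounds relative to geometry-aware definitions.
- SASA differs from Lee–Richards-family implementations (e.g. Areaimol) at
  the percent level; BSA comparisons across programs should allow ~10%.
- The "total BSA" of an interface is reported as the two-sided sum; some
  papers print a one-sided value, roughly half.
- Constant-domain residues are unlabelled (their numbering convention in
  deposited files is not guaranteed), so region percentages describe the
  variable domain only.
- No water-mediated contacts, electrostatic surfaces, or kinetic
  (on/off-rate) sensorgram fitting.
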