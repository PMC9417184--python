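# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate model and conventions

Structures are held as chains → residues → atoms with author residue
numbering as the canonical numbering (the positions quoted for deposited
structures, e.g. 98/131/256, are author numbers). Hydrogens, waters and
ligand HETATM records are excluded from every geometric analysis; ligands
(e.g. the active-site inhibitor CABP) are retained on a separate list so
they survive round trips. Alternate locations are resolved to a single
conformer — highest occupancy, ties broken alphabetically. Non-standard
residues map to `X` in one-letter sequences, except selenomethionine → `M`.
PDB-format only; the chain partition (which chains constitute which
sub-assembly) is persisted in `REMARK 400 GROUP` records. Chain masses use
IUPAC average residue masses plus one water per chain (Biopython's tables).

## Symmetry definitions

A symmetry definition is an ordered list of rigid transforms, identity
first, mapping a reference subunit onto every subunit position. Derivation
superposes the reference chain's CA atoms onto each chain (Kabsch /
`Rotation.align_vectors`), residues matched positionally for identical
sequences and by global alignment (BLOSUM62, gap open −11 / extend −1)
otherwise. Chains under 70 % identity to the reference are rejected (not a
homomer), as are chains with fewer than 20 matched CA atoms or a
superposition RMSD above 2.0 Å — deposited structures deviate from ideal
point-group symmetry, and the tolerance separates genuine symmetry mates
from wrong pairings. The point-group label (C*n*/D*n*) is inferred from
rotation angles and axes and is reported, never enforced. Applying a
definition relabels chains deterministically (A, B, C, …) and assigns one
partition group per copy.

## Interface atlas

All cross-partition heavy-atom pairs within a cutoff are found with a k-d
tree (near-linear in atom count); brute-force all-pairs enumeration serves
as the test oracle, never the implementation. Definitions:

- **Contact**: any heavy-atom pair ≤ 5.5 Å (the interfacial proximity
  criterion; configurable).
- **Hydrogen bond**: donor-capable N/O vs acceptor-capable N/O at ≤ 3.6 Å,
  by a fixed residue/atom-name table. Deliberately distance-only — no
  hydrogens, no angular term — matching how the interface bonds were
  defined in the engineering protocol this reimplements.
- **Salt bridge**: Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2,
  Glu OE1/OE2 at ≤ 4.0 Å (a standard literature cutoff; configurable). A
  guanidinium-carboxylate pair at 3.2 Å is both a hydrogen bond and a salt
  bridge and appears in both lists.
- **Interface residue**: (i) any heavy atom within 5.5 Å of the opposite
  group, or (ii) the side-chain centroid within 9 Å of the nearest opposite
  atom *and* pointing toward it — the angle between CA→centroid and
  CA→nearest-opposite-atom at most 90°. "Points toward" has no standard
  formula; the centroid/angle operationalisation is simple, testable and
  configurable. Glycine can only satisfy (i); residues without CA are
  skipped with a warning.

Percent identity is computed over aligned ungapped columns of a global
BLOSUM62 alignment (open −11 / extend −1). Coarse bead models participate
in the typing through their single side-chain pseudo-atom `SC`, whose
element encodes polarity (N for Arg/Lys/His/Trp/Asn/Gln, O for
Asp/Glu/Ser/Thr/Tyr, S for Met/Cys, C otherwise).

## Scattering

The theoretical intensity is the orientationally averaged Debye sum with
constant per-scatterer form factors (electron counts); `sin(qr)/(qr)` is
evaluated with its q→0 limit so I(0) = (Σf)² exactly. Hydration-layer and
excluded-volume corrections used by full-profile predictors are **not**
modelled: classification among candidate assemblies rests on shape, which
the vacuum Debye sum captures; absolute intensities are arbitrary units and
a multiplicative scale is always fitted. Residue granularity (one scatterer
per residue at its heavy-atom centroid, form factor = residue electron
count) is the default; atom granularity is available for small models.

Guinier analysis fits ln I against q² by unweighted least squares on a
deterministic window: start from the 10 lowest-q points, shrink until
q·R<sub>g</sub> ≤ 1.5, then grow while the refitted window still satisfies
the limit. Negative intensities inside the window or fewer than 5 usable
points raise. Note the known bias of the Guinier approximation on globular
bodies: for a uniform sphere fitted out to qR<sub>g</sub> = 1.5 the fitted
R<sub>g</sub> overshoots by ~2 %; sampling the low-q region densely (e.g. a
log-spaced grid) keeps recovery inside 2 % of √(3/5)·R.

The χ fit minimises Σ((I_exp − c·I_model)/σ)² over the scale c (closed
form), with σ = 1 when uncertainties are absent and
χ = √(Σr²/(N−1)). The model curve is linearly interpolated onto the
experimental grid; extrapolation is forbidden. Only the scale is fitted —
no constant background term. Classification computes one Debye profile per
candidate assembly and calls the minimum χ; when a measured mass and
subunit mass are supplied, round(mass/subunit) is compared with the winning
model's chain count. Elution-frame merging keeps the longest contiguous
run of frames whose Guinier R<sub>g</sub> stays within 5 % (default;
configurable) of the run median — the uniformity tolerance is this
package's choice — and averages pointwise with σ/√n propagation.

## Design screen

The screen reproduces a procedure, not an energy function: enumerate all
2ᵏ mutation subsets (binary-counter order, wild type first), rebuild each
mutant under the template symmetry so every copy carries the mutations,
sample each 50 times, rank by the best (minimum) sample score, and assess
the top 5 finalists by interface hydrogen-bond count; the selected mutant
maximises finalist H-bonds, with ties broken by better score then lower
enumeration index (the original protocol's manual inspection cannot be
reproduced, so tie-breaking is fully specified). The published protocol is
ambiguous about whether "the five … with the lowest total energy" are five
samples of one mutant or five mutants; this implementation assesses the
top-five *mutants* by their best sample.

The score is a deliberate surrogate for the molecular-mechanics energy it
replaces: over cross-group heavy-atom pairs within 8 Å, a soft-sphere clash
penalty 10·max(0, 3.0 − d)² per pair, −1 per donor/acceptor pair ≤ 3.6 Å,
and −2 per salt-bridge pair ≤ 4.0 Å (all weights configurable). Lower is
better; an empty interface scores 0 with a warning. Mutated side chains are
a single pseudo-atom at an idealised per-residue-type centroid distance
along the existing CA→side-chain direction (radially outward from the
subunit centroid when the wild type was glycine) — rotamer sampling is out
of scope. Sampling jitters side-chain pseudo-atoms within 12 Å of any
mutation site with Gaussian σ = 0.3 Å, emulating local relaxation around
the mutated sphere; per-candidate seeds derive from one root seed, making
the whole screen a pure function of its inputs and seed.

## Synthetic data

Generators emulate the study conditions end to end: subunits are single
chains of 60 pseudo-residues (CA bead + polarity-typed side-chain bead,
glycine bare) packed at ≥ 3.5 Å separation in a 12 Å sphere — roughly the
coarse footprint of a ~50 kDa subunit — then centred. Assemblies apply
exact rotation groups to a pre-offset subunit: C2 (two-fold about z), D3
(three vertical dimers on a ring), and a dimer-of-dimers D2 whose two
dimer axes are tilted by a configurable angle (0° recovers the parallel,
octamer-core-like stacking; the default 30° emulates the angled tetramer
arrangement). Default spacings are derived from the subunit radius so that
the worst-case cross-subunit approach stays above 2.5 Å for any seed; the
returned symmetry definition contains the exact generating transforms, so
derivation recovers them to numerical precision (< 10⁻⁶ Å RMSD).

Noisy profiles add multiplicative Gaussian noise (σ = 2 % of I by default,
the constant-relative-error approximation standard for merged SEC-SAXS
curves) on a 0.01–0.46 Å⁻¹ grid matching the instrument range, with the
true noise level stored in the σ column. Homolog pairs plant their
interfacial differences constructively: dedicated beads are added across
the inter-subunit two-folds so each bead's symmetry image sits exactly
4.5 Å away (inside the 5.5 Å criterion, outside the clash radius), making
recovery ground truth exact for every seed; non-interfacial differences are
drawn from positions verified non-interfacial. The deterministic design
fixture lays seven glycine sites opposite their two-fold images such that
mutating a site to glutamine creates exactly one cross-interface hydrogen
bond at 3.05 Å rest distance — a typical N···O hydrogen bond, just outside
the clash onset — so the all-sites mutant is the known screen optimum.

What the generators do **not** emulate: real protein folds and packing
density, sequence-correlated interface chemistry, solvent effects on
scattering, Poisson counting statistics, and inter-frame drift in SEC
elution. Passing tests therefore demonstrate the correctness of the
geometry, scattering, screening and algebra machinery under controlled
conditions — not predictive accuracy on deposited structures, for which
the energy surrogate in particular is no substitute for an all-atom force
field.

## Problem sizes and determinism

Default problem sizes keep every stage desk-scale: 60-bead subunits (≤ 360
scatterers per assembly at residue granularity), 100 seeded trials for the
classification-recovery rate, 2⁷ × 50 samples for the full screen, and a
~4 200-bead sphere for the Guinier recovery check. Every stochastic
component takes an explicit seed; reports embed the tool version, the full
configuration snapshot, the seeds, and SHA-256 checksums of all inputs, and
repeated runs are byte-identical.

## Known limitations

- The Debye sum ignores solvent contrast; χ values against real measured
  curves will differ from full-profile predictors even for the correct
  state (ranking is what the classifier relies on).
- Distance-only hydrogen bonds over-count relative to geometric
  (angle-aware) definitions; this matches the reimplemented protocol but
  should not be compared against angle-filtered contact atlases.
- The surrogate score has no electrostatics, desolvation or torsional
  terms; it orders coarse designed interfaces, nothing more.
- Guinier R<sub>g</sub> carries the ~2 % sphere bias discussed above when
  the window runs to qR<sub>g</sub> = 1.5.
- kcat_O derivation from a table uses the printed means; values derived
  from unrounded laboratory means can differ in the last printed digit.
- mmCIF input, crystallographic symmetry expansion, P(r) inversion and
  ab initio shape reconstruction are out of scope.
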