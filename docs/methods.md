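# Methods

This note records the models, conventions and numerical choices behind
`tcrstalk`, and what the synthetic fixtures do and do not establish.

## Structure model and IMGT anchoring

PDB files are parsed with gemmi; only polymer ATOM records are kept (HETATM
groups and waters dropped). Alternate locations keep the first conformer
(altloc A) with a warning; insertion codes are part of residue identity and
ordering follows file order. Nonstandard residues map to `X` and are excluded
from anchoring. Multi-MODEL files become trajectory frames.

The CDR3β is anchored from explicit inputs — a β-chain id and the CDR3
sequence, supplied per structure in a manifest — rather than auto-detected,
because chain labelling of deposited TCR structures is inconsistent. The
CDR3 sequence must start with the conserved cysteine (IMGT 104) and occur
exactly once in the chain; position 107 is its 4th residue by construction.
Author numbering does not follow IMGT, so the framework tyrosine (IMGT 40) is
located as the unique tyrosine inside a small author-numbering window around a
per-structure hint; the residue at IMGT 42 is taken two residues downstream of
the position-40 residue in chain order. When the hinted residue is not a
tyrosine the hydroxyl-dependent quantities are NA, but position 42 (which
needs only a Cα) remains defined.

## Geometry criteria

* **Hydrogen bonds.** Crystal structures carry no hydrogens, so a heavy-atom
  criterion is used: donor–acceptor N/O distance in [2.4, 3.5] Å and a
  donor-antecedent–donor–acceptor angle ≥ 90°, where the antecedent is the
  nearest heavy atom of the same residue. Every N/O is treated as both
  potential donor and acceptor; a pair is reported once, oriented by
  whichever side satisfies the angle. All cutoffs live in `GeometryConfig`
  and are overridable from a YAML file.
* **Clashes.** Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80 Å) with a 0.4 Å
  tolerance: a pair clashes when d < r₁ + r₂ − 0.4. For a placed side chain,
  the target residue's own atoms and the backbone atoms of its chain
  neighbours (within a few covalent bonds of the new Cβ/Oγ, where vdW
  criteria do not apply) are exempt.
* **Cavity probe.** At a probe center, the free radius is
  min(d(center, atom) − r_vdw(atom)); a gap is present when a water-sized
  probe (1.4 Å) fits. The gap/no-gap contrast between the unmutated and
  mutated site is the meaningful output; absolute radii depend on the probe
  convention.
* **Superposition.** Least-squares rigid-body fits use the Kabsch solution
  via scipy's rotation estimator, constrained to proper rotations; inputs of
  fewer than 3 points or (near-)collinear point sets raise a degeneracy
  error. Tests check it against an independent nested Euler-grid search.

## Stalk distance triple

Distance *a* is measured from Cα(107) to the nearest backbone carbonyl carbon
among "countercurrent" residues, operationalized as loop residues from the
apex (ordinal ⌈L/2⌉ of the L-residue CDR3 match) through IMGT 119, excluding
positions 104–108 so a sequence neighbour can never be picked. The chosen
partner residue is recorded in the output so discrepancies are diagnosable.
Distance *b* uses the Y40 side-chain hydroxyl oxygen (OH), not the backbone O.
Group statistics are NA-aware; the sample SD uses the n−1 denominator (this
choice reproduces the published summary cells exactly; the n denominator does
not). Reported values are rounded to 2 decimals.

## G107S placement

The substitution model is deliberately minimal: rigid backbone, ideal internal
coordinates (Cα–Cβ 1.53 Å, Cβ–Oγ 1.42 Å, angles 110.5°), and the three
staggered χ1 rotamers (−60°, 60°, 180°). The claim being tested is
existential — the serine fits without moving any other atom — so a clash-free
canonical rotamer suffices and continuous optimization would overstate the
method. The Cβ constructor is validated against the chemical component
dictionary's ideal serine (0.06 Å deviation) and is chirality-fixed: it
always builds the L-side of the (N, Cα, C) frame. Among feasible rotamers the
"best" maximizes hydrogen bonds, then minimizes steric strain, then prefers
gauche− (the most common serine rotamer). The mutated structure is emitted by
copying every input atom bit-identically and adding only Cβ and Oγ.

## Quasi-harmonic entropy

Frames are superposed onto their mean structure (fit → recompute mean →
refit, two iterations, then a final fit; configurable off). Displacements are
mass-weighted (√mᵢ per coordinate; masses from the element), the covariance
uses the n−1 normalization, and eigenvalues below 1e-8 amu·Å² — the six
rigid-body modes removed by superposition, plus numerically empty modes — are
excluded and reported via `n_modes_used`. Each retained mode contributes the
quantum harmonic oscillator entropy with ω = √(k_B T/λ); constants are kept
in one table and the result is reported in cal mol⁻¹ K⁻¹ (the natural unit
for molar configurational entropy; 300 K default). A warning is issued when
frames < 3N, where the covariance is necessarily rank-deficient.

RMSD series fit each frame on a fit selection and report RMSD over a report
selection, so a deliberately displaced subset is measurable against an
otherwise-fixed frame.

## Synthetic fixtures and what they show

* **Hairpins.** Two antiparallel strands (Cα steps 3.5/3.8 Å, separation
  4.8 Å to echo the ~5 Å stalk scale) joined by a four-residue arc. The
  stalk strand is rolled 50° about its axis so the 107 side chain leaves the
  strand plane, as the serine hydroxymethyl does in CASS structures. The
  carbonyl of residue 108 is oriented toward the reference rotamer's Oγ site,
  and the optional framework strand places the Y40 hydroxyl at the requested
  distance *b* while staying within hydrogen-bond range of that site; the
  flank position is chosen by a deterministic search that keeps every flank
  atom clear of the placement region. Requested (a, b, c) values are hit
  exactly: the countercurrent strand is translated until the minimum carbonyl
  distance equals *a*, and residues 40/42 are solved on the corresponding
  spheres. These fixtures are geometric stand-ins, not physical loop models:
  backbone torsions, the turn, and the schematic tyrosine arm are idealized,
  and side chains other than the stalk Cβ/Oγ and the Y40 arm are absent.
  Passing tests on them shows the measurement/placement machinery is correct,
  not that any particular deposited structure has these coordinates; the
  stand-ins used for published entries are labelled `synthetic` in their
  filenames.
* **Gaussian trajectories.** Fluctuation modes are generated directly in
  mass-weighted coordinate space on a random orthonormal basis constructed
  orthogonal to the six rigid-body vectors, so the true spectrum is exact by
  construction, superposition leaves it intact, and the closed-form entropy
  is a genuine oracle. Amplitudes are kept small (0.02–0.2 amu·Å² per mode)
  so the linearization of rotational alignment is negligible. Real MD
  trajectories have anharmonic, correlated dynamics that these ensembles do
  not emulate; agreement here validates the estimator, not any force field.
  Entropy checks use 9 atoms (21 internal modes) and 1200–2000 frames, which
  keeps the whole suite at desk scale while leaving sampling error well below
  the tested tolerances; statistical tolerances are 3 delta-method standard
  errors of the estimator.
* **V-gene FASTA.** Sequences are built as non-motif prefixes/suffixes around
  an exact CASS/CASG/other motif, so the census must return the requested
  composition. The motif anchor is the last C-followed-by-A within the final
  12 residues, matching germline C-termini that end shortly after the
  conserved C104; unanchorable sequences count as "other" with a warning.
  Percentages are rounded to integers.

All generators are pure functions of (spec, seed): identical inputs produce
byte-identical files.

## Known limitations

* Deposited coordinate files for the published TCR entries are not bundled;
  per-structure acceptance checks run on the engineered stand-ins above. With
  real files in hand, the same manifest-driven pipeline
  (`tcrstalk stalk-table --manifest ... --pdb-dir ...`) applies unchanged.
* The hydrogen-bond criterion is geometric, not energetic, and the reference
  viewer's exact thresholds are unknown; only the presence of the specific
  named bonds is asserted, not bond-for-bond agreement.
* MD generation (force fields, equilibration, implicit solvent) is out of
  scope; trajectories are an input format (multi-MODEL PDB).
* mmCIF parsing, automatic TCR domain annotation, structure repair and
  protonation are not implemented.
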