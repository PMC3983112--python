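# Methods

This note records the models, numerical choices, and limitations behind
`peptscan`. It documents what the code computes; every figure quoted here
is produced by the test suite or `scripts/acceptance.py`.

## Solvent-accessible surface area

SASA is computed by sphere-point sampling. Each atom's solvent sphere
(radius `r_atom + probe`) is covered with a generalized-spiral (Fibonacci)
point set; a point is occluded when it lies inside any neighbour's solvent
sphere (`|x_point − x_j| < r_j + probe`); the accessible fraction times
`4π (r + probe)²` is the atom's area.

* **Point set.** Deterministic, no random seed; n_points defaults to 960
  with a hard floor of 100. The discretization error for an isolated
  sphere is bounded in the tests by `3/√n_points` relative (asserted at
  200, 960 and 5000 points); in practice the isolated-sphere case is exact
  because every point of a free sphere is accessible.
* **Occlusion at zero distance.** Exactly coincident atoms are resolved
  deterministically rather than raising: a larger-radius atom swallows a
  smaller one, and at equal radii the lower-index atom occludes the
  higher-index one. A duplicated atom therefore contributes zero area and
  the pair's total equals one sphere — robust behavior for noisy or
  degenerate synthetic input.
* **Waters and monatomic ions never act as occluders**; SASA here is a
  protein-surface concept and solvent is handled by the probe.

## RASAS

For a site, numerator = site SASA with all non-water atoms (including the
ligand role) as context; denominator = the same with ligand atoms removed.
Receptor and cofactor atoms appear in both contexts, so conformational
self-occlusion cancels; the ratio moves only when ligand atoms occlude
site points. Consequences asserted as properties:

* empty ligand role ⇒ ratio exactly 1 in every frame;
* ratio ≤ 1 always (occlusion only removes points);
* onset of RASAS < 1 at a ligand–site vdW surface gap of `2 × probe`
  (2.8 Å at the 1.4 Å default). With 960 points the measured onset in a
  0.01 Å radial scan is 2.79 Å — the finite point set delays onset by
  roughly the angular spacing, well inside the 0.05 Å tolerance used.

RASAS is evaluated on **side-chain atoms only** by default (backbone N,
CA, C, O and hydrogens excluded), because side chains form the functional
binding surface; glycine keeps CA as a pseudo-side-chain so its ratio is
always defined. Surface coverage is `1 − RASAS` of the whole receptor at a
2.5 Å probe, and the identity `coverage = 1 − RASAS(whole receptor)` holds
to machine precision (tested).

## Nonbonded energetics

Post-hoc pairwise analysis energies, not simulation forces:

* Coulomb: `332.0636 · q_i q_j / (ε_r · r)` kcal/mol, relative dielectric
  1.0 (configurable).
* Lennard-Jones 12-6 with Lorentz–Berthelot combination,
  `ε_ij = √(ε_i ε_j)`, `rmin_ij = rmin_half_i + rmin_half_j`.
* Both terms multiplied by the cubic-in-r² switching function (1 below
  10 Å, 0 above 12 Å, C¹-continuous between); pairs beyond the cutoff are
  skipped. Continuity is asserted on a fine radial grid through both
  boundaries.
* No mesh Ewald: long-range electrostatics belong to the simulation
  engine, not to pairwise interaction reporting with a switched cutoff.
* Hydrogens are optional: the bundled united-atom-style table puts formal
  side-chain charges on terminal polar heavy atoms (Lys NZ +1, Asp
  OD1/OD2 −0.5 each, Glu OE1/OE2 −0.5 each, Arg NH1/NH2 +0.5 each), with
  per-element fallbacks (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å vdW radii
  and generic LJ parameters). This table is a documented stand-in users
  can replace with real force-field values via a TSV file; absolute
  energies from it are not comparable to full force-field energies, but
  thresholding and ranking behavior is preserved.

Salt bridges: any acidic side-chain oxygen (Asp OD1/OD2, Glu OE1/OE2)
within ≤ 3.2 Å of a basic side-chain nitrogen (Lys NZ, Arg NH1/NH2/NE; His
ND1/NE2 optional) in at least one frame; distances strictly above the
cutoff never count. Occupancy is the mean of the per-frame formed flags.

## Site calling

Defaults (all configurable through `CallParams` and the CLI): contact
cutoff 7 Å (residue centroid to residue centroid — the most direct reading
of "within 7 Å of any residue of the fragment"; an atom-level minimum
distance variant would be stricter), energy threshold 3 kcal/mol per
paired receptor residue, split gap 5 residues with 50 % contact-frame
persistence, merge adjacency 5 Å over heavy atoms in the trajectory-average
structure, per-residue pruning floor −0.5 kcal/mol, accessibility floor
5 Ų mean ligand-ignored side-chain SASA.

Choices where the procedure was genuinely open:

* **Splitting semantics.** A fragment residue is "attached" when paired in
  ≥ 50 % of the pairing's contact frames; blocks of attached residues
  separated by ≥ 5 unattached residues become independent interactions. A
  pairing with a single attached block is returned unchanged (identity):
  transient stray contacts inside one block are not trimmed at this stage
  because the per-residue pruning floor removes their receptor partners
  later anyway.
* **Re-scoring.** After merging, per-site energy is recomputed against the
  union of contributing fragments; pruning runs before the final screen so
  a site must justify itself with its surviving residues only.
* **Tie-breaking.** Merged candidates are processed and numbered in
  ascending order of their minimum receptor residue, making output order
  deterministic.
* Retained calls always satisfy the per-residue energy threshold after
  final re-scoring (asserted on all outputs).

Superposition RMSD uses the Kabsch least-squares rotation (via
`scipy.spatial.transform.Rotation.align_vectors`) after centroid removal;
it is cross-checked in the tests against an independent implementation.

## Fragmenter

Windows of nominal length 30 tile the chain with stride `30 − overlap`
(overlap 10). "Near fragment ends" means within 3 residues (`end_window`)
of a window boundary, checked both for the current fragment's tail and the
next fragment's head; a dirty boundary extends the window forward up to 44
residues. If no clean boundary exists within the maximum length, the
nominal end is kept and a warning logged. The final fragment is anchored
to the chain end and back-extended to ≥ 30 residues (increasing the last
overlap). Invariants: full coverage, ≥ 10-residue overlaps, exact
reconstruction by overlap deduplication. A proline-free 664-residue chain
yields exactly 33 fragments at the defaults.

## Conservation

Column classes for a chosen reference sequence: `gap_majority` (> 50 %
gaps) is checked first, then `fully_conserved` (all non-gap symbols
identical), then `group_conserved` (all non-gap symbols in one
physicochemical group), else `not_conserved`. The four groups — acidic
{D,E}, basic {K,R,H}, polar uncharged {S,T,N,Q,C,Y,G}, nonpolar
{A,V,L,I,M,F,W,P} — are a documented default membership for the standard
charge/polarity partition; histidine is grouped basic, glycine polar.
Gaps are ignored by the identity/group tests unless the column is
gap-majority.

## Synthetic data: what it emulates and what it does not

The generator scripts **kinematics, not physics**: a rigid coarse receptor
(3 backbone + 1–3 side-chain atoms per residue, 4 Å CA spacing on a gentle
curve, ≥ 2 Å between all atom pairs) with charged surface patches, and
rigid fragments that linearly approach a patch, dwell at a prescribed vdW
surface gap (found by bisection; default −0.1 Å so salt-bridge distances
land near 3 Å), and retreat, with isotropic Gaussian positional noise
(default σ = 0.2 Å) on fragment atoms. Parking keeps idle fragments ≥ 15 Å
away.

The reference scenario uses a 100-residue receptor with three 4-residue
patches ~150 Å apart, three 30-residue fragments with complementary
4-residue charged blocks, 60 frames, and dwell windows covering ≥ 40 % of
the trajectory. The patch spacing is deliberate: a 30-residue fragment in
this coarse geometry is extended (~116 Å), so its 7 Å contact stripe spans
many receptor residues; patches must be farther apart than a fragment
half-length or distinct events would legitimately merge into one site.
Approach/retreat legs are short (≤ 8 frames over a 40 Å path) so that only
dwell frames can come within the 2.8 Å RASAS proximity.

What passing tests therefore show: the analysis correctly recovers known
contact geometry, energetic ranking, splitting/merging topology and
occupancy timing from coordinates. What they do not show: behavior under
receptor flexibility, fragment internal dynamics, solvent effects,
force-field-accurate energies, or crowding — real-trajectory results
depend on those and on the chosen force field.

## Degenerate inputs and numerical edges

* Coincident atoms: handled deterministically in SASA (above); a zero
  interatomic distance in an energy pair raises, naming the atoms.
* A site with no side-chain atoms in side-chain-only mode raises, naming
  its residues (glycine is rescued by the CA pseudo-side-chain).
* Empty fragment/ligand roles give empty pairings and ratio-1 RASAS, not
  errors; empty candidate lists propagate to empty call lists.
* RASAS with a zero denominator (fully buried site) is reported as NaN
  rather than inventing a ratio.
* Multi-model trajectories must match the topology atom count exactly;
  mismatches name the offending model.

## Known limitations

* The bundled parameter table is a reduced set; absolute energies are
  only meaningful relative to its own scale.
* The contact criterion is centroid-based; long side chains can touch at
  centroid distances beyond 7 Å and would need the atom-level variant.
* Conservation classes ignore phylogeny (no tree weighting, no
  similarity scores beyond the group partition).
* The packaged reference site list encodes interfacial-prediction and
  salt-bridge annotations; per-residue conservation flags are not encoded
  and should be derived from an alignment instead.
* Binary trajectory formats (DCD/XTC) are out of scope; multi-model PDB
  is the interchange format.
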