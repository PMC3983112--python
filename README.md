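# peptscan

Detection and characterization of **transient binding sites** for
unstructured peptide fragments on a receptor surface, from molecular
dynamics trajectories.

When a disordered protein tail (for example the acidic C-terminus of the
nuclear-basket protein Tpr interacting with the exportin CRM1) binds a
folded receptor, there is no pocket and no stable complex — only dispersed
attachments and detachments of peptide segments on the receptor surface.
`peptscan` provides the analysis layer for such systems: it scans a
fragment library over a trajectory, scores candidate contact regions by
nonbonded interaction energy, and tracks site occupancy with a
surface-based order parameter.

## The RASAS measure

For a binding site *S* on the receptor, the **ratio of available solvent
accessible surface** in frame *t* is

```
RASAS(t) = SASA(S | ligand present) / SASA(S | ligand ignored)
```

Both SASAs are recomputed per frame with the same receptor/cofactor
context, so conformational self-occlusion cancels and the ratio isolates
occlusion by the ligand: **RASAS = 1 means the site is unoccupied**; lower
values mean the ligand covers the site. With the standard 1.4 Å water
probe, a ligand atom starts to depress RASAS exactly when its van der
Waals surface comes within 2 × 1.4 = **2.8 Å** of a site atom's surface,
so RASAS < 1 is a geometric proximity signature. Evaluated over the whole
receptor with a 2.5 Å probe, `1 − RASAS` gives the fraction of the
receptor surface covered by fragments (≈ 5 Å proximity).

SASA itself is computed by deterministic Fibonacci sphere-point sampling
(default 960 points/atom), so every number is exactly reproducible.

## The site-calling pipeline

1. **Contact pairing** — receptor residues whose centroid lies within 7 Å
   of any residue centroid of a fragment, per frame.
2. **Energy screen** — keep regions whose mean total nonbonded energy
   (Coulomb + Lennard-Jones, 12 Å cutoff / 10 Å switch) drops by at least
   3 kcal/mol per paired receptor residue.
3. **Splitting** — one fragment touching the receptor in two
   sequence-separated stretches is split into independent interactions.
4. **Merging** — residue groups within 5 Å of each other in the average
   structure merge into one site (possibly pooling several fragments).
5. **Re-scoring** — energies are recomputed per merged site; residues
   contributing < 0.5 kcal/mol or with buried side chains are pruned, and
   sites failing the energy screen after re-scoring are dropped.

Each retained site is reported with mean ± sd interaction energy,
mean ± sd RASAS, and salt bridges (acidic O – basic N pairs ≤ 3.2 Å, with
occupancy). Supporting tools: a fragmenter that tiles an unstructured
chain into 30–44-residue windows with 10-residue overlaps (avoiding
proline near window ends), an alignment-column conservation classifier
(fully / group / not conserved, with charge-and-polarity groups), a
superposition RMSD utility, and a packaged reference list of 11 curated
binding sites with per-residue annotations (`peptscan.table1_fixture()`).

## Worked example

Generate a synthetic trajectory with three scripted binding events (a
rigid 100-residue receptor with charged patches, three 30-residue
fragments that approach, dwell and retreat), then call sites on it:

```sh
peptscan --out-dir demo --seed 7 simulate --out-prefix toy
peptscan --out-dir demo call-sites \
    --topology demo/toy_topology.pdb --traj demo/toy_traj.pdb
```

prints

```
site 1: residues [A:11 A:12 A:13 A:14] fragments [1] E -401.6 ± 449.2 kcal/mol RASAS 0.80 ± 0.23
site 2: residues [A:49 A:50 A:51 A:52] fragments [2] E -410.6 ± 457.9 kcal/mol RASAS 0.62 ± 0.43
site 3: residues [A:87 A:88 A:89 A:90] fragments [3] E -453.5 ± 457.5 kcal/mol RASAS 0.77 ± 0.24
3 binding sites called
```

The three called sites are exactly the three planted charged patches
(`demo/toy_truth.json` holds the ground truth). The large standard
deviations are expected: binding is transient, so the per-frame energy
alternates between ~0 (fragment parked far away) and strongly negative
values during the dwell, and RASAS between 1 and its occluded value. The
full per-site report, including per-residue energies and salt-bridge
occupancies, is written to `demo/sites.json`.

Other subcommands: `rasas`, `coverage`, `energy`, `saltbridges`,
`fragment`, `conserve` — see `peptscan --help`.

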