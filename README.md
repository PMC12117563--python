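# fvkit

A curation toolkit for antibody structures. Given antibody or
antibody–antigen entries in PDB/mmCIF format, `fvkit` standardizes them
into one-complex-per-file records containing only the variable regions
(Fv), prepares docking inputs, computes a per-residue molecular-descriptor
table, and scores docked poses against a reference complex with a
DockQ-style metric. It is aimed at people building structure-based
machine-learning datasets for antibody discovery, where consistency of
chain naming, numbering and interface definitions matters more than any
single structure.

## What it does

**Standardization.** Antibody chains are identified and renumbered under
the Martin scheme by a pluggable numbering engine (an adapter for
ANARCI-style tabular output is provided; a deterministic table-driven
engine backs all tests). Heavy and light chains are renamed `H` and `L`
(`h`/`l` for the two halves of an scFv); antigen chains keep their
original identifiers unless they collide with `H`/`L`, in which case they
become `A`. VH/VL pairs are recognized by the distance between the
conserved cysteines — the Cα of Martin H92 and L88 must lie within
22 Å. Multi-chain antigens are kept oligomeric only when their interface
classifies as biological (pluggable classifier; the default heuristic
requires ≥ 800 Å² buried surface and ≥ 10 residue contacts at 5.5 Å).
An antibody–antigen complex is emitted whenever at least one CDR–antigen
Cα pair lies within 7.5 Å and the antigen exceeds 50 residues; each
complex becomes a file named `XXXX_n`. Entries with missing heavy atoms
or uncommon formats (e.g. dual variable domains) are rejected with
logged reasons.

**Docking preparation.** Heavy chains are renumbered sequentially from 1
and light chains from 500 (so numbers never overlap); CDR residues form
the active list on the antibody side; antigen restraints are either every
surface-exposed residue (blind mode, relative SASA ≥ 0.15) or the epitope
defined by the per-residue SASA lost upon complexation (site-directed
mode, ΔSASA > 1 Å²).

**Descriptors.** For every residue: relative solvent-accessible surface
area (Shrake–Rupley, 960 points, 1.4 Å probe, Tien et al. reference
maxima), residue depth, protrusion index (CX), Kyte–Doolittle
hydrophobicity, half-sphere exposure (13 Å), Cα coordinates, φ/ψ
dihedrals, and 3-state secondary structure from Kabsch–Sander hydrogen
bonds — one CSV row per residue.

**Pose scoring.** DockQ combines the fraction of native contacts
(heavy-atom pairs < 5 Å), the interface RMSD (iRMS, native interface at
10 Å) and the ligand RMSD (LRMS, antibody after superposition on the
antigen):

    DockQ = ( Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2) ) / 3

Poses are binned as high (≥ 0.80), medium (≥ 0.49), acceptable (≥ 0.23)
or incorrect, and a 4-pose descriptor subset is selected — one pose per
represented category, back-filled with additional incorrect poses.

## Worked example

Everything is testable offline: the `fixtures` subcommand generates a
synthetic antibody–antigen entry with known ground truth (paired VH/VL
chains with the conserved cysteines 15 Å apart, a 60-residue antigen
posed for exactly 5 CDR contacts) plus the numbering table its engine
needs.

```
$ fvkit fixtures --out fx --seed 3
fixture written to fx
$ fvkit standardize --in fx/9FIX.pdb --out std --numbering numbering.json
standardized 1/1 entries -> std
$ fvkit dockq --ref std/9FIX_1.pdb --model std/9FIX_1.pdb
9FIX_1  fnat=1.000  irms=0.00  lrms=0.00  dockq=1.000  high
$ fvkit describe --in std/9FIX_1.pdb --out desc
$ head -3 desc/9FIX_1.csv
chain_id,res_number,insertion_code,res_name,rel_sasa,depth,protrusion,hydrophobicity,hse_up,hse_down,ca_x,ca_y,ca_z,phi,psi,sec_struct
H,25,,GLY,1.3196,1.6175,13.4509,-0.4000,0,3,0.0000,0.0000,0.0000,,-120.1827,C
H,26,,ALA,0.8179,1.6340,9.9078,1.8000,3,1,3.8000,0.0000,0.0000,-120.1827,-120.1827,C
```

`9FIX_1.pdb` holds the renamed (`H`, `L`, antigen `D`), Martin-renumbered
complex. Scoring the reference against itself returns DockQ = 1.0 in the
`high` category, as it must. The CSV has one row per residue; chain `H`
starts at Martin position 25, and the first row's φ is empty because a
chain-initial φ is undefined. `fvkit profile --in std` summarizes
experimental methods and resolutions of a structure set, and
`fvkit prep-dock` writes the renumbered docking input plus active/passive
restraint lists. Every run writes a `manifest.json` that embeds the exact
configuration (all cutoffs) and records every pairing, contact count and
rejection.

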