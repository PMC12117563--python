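# Methods

This note documents the models, conventions and numerical choices behind
`fvkit`, and what the synthetic test fixtures do and do not demonstrate
about real data.

## Structure model and I/O

A structure is a hierarchy of chains → residues → atoms holding only what
the pipeline needs: names, elements, coordinates, occupancies, B-factors
and experimental metadata (method class and resolution). Reading goes
through gemmi for both PDB and mmCIF. Only the first model of multi-model
(NMR) files is used — each entry is treated as one structure set.
Alternate locations are collapsed to the highest-occupancy conformer
(ties broken by alt-loc letter); waters and non-polymer heteroatoms are
excluded; polymer-linked modified residues are retained but exempted from
completeness checking, to avoid mass rejection of otherwise sound
entries. Writing emits fixed-column PDB text with coordinates at three
decimals; read∘write is the identity on the data model at that precision.

The missing-atom filter compares each standard residue against a fixed
per-residue heavy-atom dictionary (20 amino acids, OXT and hydrogens
ignored). The check is report-only; the pipeline rejects a whole entry on
any violation, reading "remove structures with missing atoms" literally
rather than salvaging per chain. A Cα-only chain is therefore flagged at
every residue.

## Antibody annotation

Numbering is delegated to an engine behind a small contract: sequence in,
zero or more (domain type, per-residue Martin positions) results out,
monotone in sequence order. Production use can plug in an adapter parsing
ANARCI-style tabular text; all tests use a deterministic table-driven
engine carrying the fixtures' pre-computed numbering, so no external
binary is ever required. CDR spans default to Kabat-style intervals on
Martin numbering (L1 24–34, L2 50–56, L3 89–97; H1 31–35, H2 50–65,
H3 95–102) and are configurable, since no single CDR definition is
canonical. Renumbering a chain to Martin positions trims everything
outside the variable region, including constant domains and scFv linkers
— "one complex per file" holds variable regions only. A chain with two
same-type domains (dual-variable-domain constructs) classifies as
`unusual` and is excluded; a curated exclusion list handles non-antibody
false positives that numbering engines occasionally accept.

## Standardization

VH/VL pairing measures the Cα distance between the conserved cysteines at
Martin H92 and L88 with a 22 Å acceptance radius (boundary inclusive —
"within a radius" is read as ≤). When several domains satisfy the cutoff,
matching is greedy nearest-first with ties broken by chain id; on the
synthetic multi-copy fixtures this coincides with the global
minimum-total-distance assignment, which the tests verify by brute force.
Domains lacking the conserved cysteine Cα are unpairable and become
single-chain antibodies.

Antigen oligomeric state is decided by a pluggable pairwise interface
classifier with transitive-closure merging. The default heuristic calls
an interface biological when it buries ≥ 800 Å² of surface area AND has
≥ 10 residue pairs with heavy atoms within 5.5 Å — values in the range
conventionally used to separate biological from crystal-packing
interfaces; an adapter for an external trained classifier can replace it
wholesale. Classifier failures fall back conservatively to monomer
treatment.

Complex construction counts (CDR residue, antigen residue) Cα pairs
strictly below 7.5 Å, pooling the CDRs of all domains of the antibody
unit; one contact suffices. Antigens must exceed 50 residues (strict:
exactly 50 is excluded; oligomer length sums over member chains).
Antibodies with no qualifying antigen are emitted once as free-antibody
records, so every unit appears in exactly one output record. Output files
are named `XXXX_n` with `n` assigned in deterministic order (antibody
chain ids, then antigen ids).

The dataset profiler reports per-method percentages, per-method mean
resolution and the fraction of entries below a resolution cutoff
(default 4.0 Å); entries without a resolution are excluded from
resolution statistics and counted separately.

## Docking preparation

Heavy chains are renumbered sequentially from 1, light chains from 500,
insertion codes dropped; the original↔new mapping is returned as a
bijection so the Martin numbering can be restored. A heavy chain of ≥ 500
residues would collide and raises instead. Antibody active residues are
the pooled CDRs. Antigen restraints come in two modes: blind (all
residues with relative SASA ≥ 0.15 on the isolated antigen are passive —
the common ambiguous-restraint docking convention) and site-directed
(residues losing more than 1.0 Å² of SASA between isolated and complexed
states are active; the 1 Å² floor suppresses estimator noise). Both
thresholds are configurable, as neither has a single published value.
Restraints are written as a two-line active/passive text list plus a JSON
manifest with the per-residue ΔSASA values.

## Descriptors

All estimators are deterministic: sphere points come from a golden-spiral
lattice, never random sampling.

- **SASA** — Shrake–Rupley with a 1.4 Å probe and 960 points per atom by
  default; per-residue areas are sums over heavy atoms. An isolated
  carbon atom reproduces the closed form 4π(1.7+1.4)² to well under
  0.5%. Relative SASA divides by the Tien et al. theoretical maxima
  (terminal residues can legitimately exceed 1).
- **Residue depth** — mean distance of a residue's heavy atoms to the
  nearest solvent-accessible surface dot, where dots sit on the van der
  Waals surface in accessible directions; exposed atoms score about one
  vdW radius, buried atoms more. Single-atom models have depth 0 by
  convention.
- **Protrusion index (CX)** — per atom, occupied volume inside a 10 Å
  sphere is the neighbor count times a 20.1 Å³ mean atom volume;
  CX = V_free/V_occupied, capped at 15; per-residue values are atom
  means.
- **Half-sphere exposure** — Cα neighbors within 13 Å partitioned by the
  plane normal to the Cα→Cβ vector (pseudo-Cβ built from the backbone
  for glycine); up + down always equals the neighbor count.
- **Dihedrals** — standard IUPAC φ/ψ; absent at termini, across chain
  breaks (peptide C–N > 2.5 Å) and wherever backbone atoms are missing.
- **Secondary structure** — 3-state (H/E/C) from Kabsch–Sander hydrogen
  bonds (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
  bond when E < −0.5; amide H rebuilt from the backbone). H comes from
  runs of two consecutive i→i+4 bonds, E from parallel/antiparallel
  bridge patterns, everything else is coil. Three states rather than
  eight keep the assignment minimal and implementable without a DSSP
  binary; no exact numeric agreement with any specific external
  implementation is claimed.
- **Hydrophobicity** — Kyte–Doolittle by default, any table accepted.

Descriptors are computed in the context of the full standardized file by
default (a complexed residue is partially buried by its partner), with an
isolate mode for chain subsets — both contexts are needed for ΔSASA
anyway. The CSV has a fixed column order, one row per residue, empty
fields for absent values.

## Pose scoring

Receptor/ligand assignment is fixed: antigen = receptor, antibody =
ligand. Component definitions follow the established DockQ formulation —
native contacts at 5 Å heavy-atom distance, interface at 10 Å defined on
the reference only, backbone = N/CA/C/O, scaling constants 1.5 Å (iRMS)
and 8.5 Å (LRMS) — with categories at 0.80/0.49/0.23, boundary-inclusive
at each lower bound. Superposition is least-squares with a proper
rotation (SVD with determinant correction); degenerate (collinear) inputs
raise. Residue correspondence between pose and reference is positional,
by (chain, number, insertion code) after standardization — no alignment
fallback, by design: standardized files make the correspondence exact.
The 4-pose descriptor subset takes the best-scoring pose of each
represented category (ties by pose id) and back-fills missing categories
with additional incorrect poses in ascending score order; if incorrect
poses run out, the lowest-scoring remaining poses complete the set.

## Synthetic fixtures: what they show and what they do not

The fixture generator builds antibody-like scenes from geometric
primitives: straight-line chains of Ala/Gly/Cys with full heavy-atom
templates, conserved cysteines placed for an exact H92–L88 separation,
antigens whose "head" residues sit exactly 7.0 Å above chosen CDR Cαs
(one Cα contact pair each at the 7.5 Å cutoff, plus one sub-5-Å
heavy-atom contact via a flipped cysteine side chain, so the same
interface is real under both contact definitions), remote tails, crystal
copies 200 Å apart, and antigen–antigen patches sized either small
(2 residues — crystal-contact scale) or large (the whole tail at 5.2 Å —
biological-dimer scale). Ideal helices and strands come from internal
coordinates (NeRF chain extension with Engh–Huber-style geometry); the
antiparallel strand pair places a 180°-rotated copy by a geometric grid
search targeting 2.9 Å O···N hydrogen bonds. All generators are pure
functions of their specification: same seed, byte-identical files, with
machine-readable ground truth consumed directly by tests.

Passing on these fixtures demonstrates that every rule and threshold is
implemented exactly as stated — it does not demonstrate robustness to the
messiness of real crystallographic data (alternate conformations beyond
simple occupancy ties, chain breaks, non-standard residues in CDRs,
numbering-engine ambiguity), nor does it reproduce dataset-scale
statistics, which would require a dated snapshot of the public archive
and large-scale docking runs. Sequence realism is explicitly out of
scope: fixtures use a three-letter alphabet chosen so that completeness
checks pass by construction.

## Problem sizes and determinism

Default test and acceptance problem sizes are small by choice — 81-residue
domains, 60-residue antigens, 240–960 sphere points — because every
verified property (boundary switches, closed forms, oracle agreement) is
scale-free. The acceptance script recovers thresholds by bisection on
fixture parameters rather than asserting constants, so the reported
values are genuinely measured from pipeline behavior.

## Known limitations

- The numbering engine contract covers Martin-scheme output only; other
  schemes would need new CDR interval tables.
- The default interface classifier is a two-parameter heuristic, not a
  trained model; borderline oligomer calls should be reviewed or routed
  through an external classifier adapter.
- Fnat requires every native-contact residue present in the pose; poses
  with deleted interface residues are rejected rather than partially
  scored.
- Secondary structure omits 3-10/π helices and turn classes (folded into
  coil).
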