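# Methods

This note documents the models, parameters and design choices behind
`ligscreen`, and what the synthetic validation does and does not show.

## Pipeline model

The package implements a ligand-based repurposing screen: similarity of a
query scaffold's tautomer/stereo states to ligands with known target
annotations is used as evidence that the scaffold may bind those targets.
The underlying assumptions are the standard ones of similarity-based
inference — structurally similar ligands tend to share targets, 2D
fingerprints and 3D shape/pharmacophore overlap capture complementary
aspects of that similarity, and requiring both (a consensus) trades recall
for precision.  The ranking produced at the end is a heuristic
prioritisation of targets by evidence volume and direction; no null model
is attached and no significance is claimed.

## State enumeration

A `StateSpace` is a SMILES template plus tautomer sites (each state is a
SMILES fragment spliced into the template) and stereocenters (`@`/`@@`
tags).  Enumeration is the deterministic Cartesian product, site-major then
stereo-minor, and every product must canonicalize to a distinct structure
(collisions and invalid chemistry are hard errors naming the offending site
and state).  Template-fragment rewriting was chosen over reaction-SMARTS
rewrites because tautomer shifts in fused ring systems change bond orders
across several atoms at once; a declarative fragment per state is easier to
audit and cannot fire in unintended places.

The shipped oxindole fixture encodes one consistent chemical reading of the
scaffold's state space: the indole site is either the lactam (C2=O, N1–H)
or the 2-hydroxy-3H-indole imino-ol (C2–OH, C2=N1) — a reading that keeps
C3 sp³ so the stereocenter exists in *every* state — and the pyrazolone
site carries five proton placements (N–NH=O, NH–NH=O, N–NH–OH, N–N–OH,
NH–N–OH).  Which enantiomer is labelled 1 vs 2 is an arbitrary convention
(the compound is a racemate).

## Curation

| parameter | default | rationale |
| --- | --- | --- |
| activity threshold | 1000 nM | community-standard active/inactive cut |
| threshold boundary | inclusive (≤ is active) | documented, configurable |
| assay format | "Single Protein" only | unambiguous target attribution |
| activity types | Ki, IC50, Kd, EC50, Potency | directly potency-like measurements |
| relation | "=" only | censored values (">", "<") would bias labels |
| units | pM/nM/µM/mM/M → nM | anything else dropped with a reason code |
| PDB stoplist | shipped het-code list | solvents/buffers/ions named by code |
| inorganic rule | ≤ 1 heavy atom, or charged and carbon-free | catches ions not on the list |

Duplicate (structure, target) rows are resolved by strict majority vote;
exact ties are dropped rather than guessed, because ambiguous evidence
should not seed repurposing claims.  Deduplication is per (canonical
structure, target) — the same molecule may legitimately be active at one
target and inactive at another.  Potency values are treated identically to
IC50 after nM normalization.  No desalting or charge standardization is
applied before fingerprinting; an optional pre-canonicalization hook exists
but is disabled by default.

## 2D screen

MACCS uses the fixed 166 keys; ECFP/FCFP are hashed circular fingerprints
of 2048 bits (length is unclaimed by any external convention and recorded
in the parameter snapshot), with the numeric suffix read as environment
*diameter*: ECFP4/FCFP4 = Morgan radius 2, ECFP6/FCFP6 = radius 3.  FCFP
variants use pharmacophoric feature invariants.  Thresholds are applied as
≥ (a pair exactly at threshold is a hit).  Tanimoto of two all-zero bitsets
is defined as 1 — the two molecules are indistinguishable to that
fingerprint — and is configurable to 0.

## 3D screen

Shape is modelled as one spherical Gaussian per heavy atom, amplitude
p = 2√2, width α_i = π(3p/(4πr_i³))^(2/3) so each atom Gaussian integrates
to its hard-sphere volume; radii are Bondi by element (C 1.70 Å, N 1.55 Å,
O 1.52 Å, …; a radius-uniform mode is available and recorded in the
snapshot).  Overlap keeps only first-order (pairwise) products — the
standard fast approximation; the systematic overestimate of the true union
volume largely cancels in the Tanimoto ratio.  The analytic double sum is
exact for this model (the unit tests verify it against 3D grid integration
to well below 1%).

Color features are single points (centroid of each SMARTS match; aromatic
rings from ring perception) with a fixed 1.0 Å Gaussian radius and unit
weight; only same-type pairs interact, and the color term enters the
optimization objective with the same weight as shape.  If neither molecule
has any feature the ColorTanimoto is defined as 1 (configurable), matching
the empty-bitset convention; if exactly one has features it is 0.

Overlays start from centroid superposition in the reference inertial frame
over the four proper axis flips; near-collinear queries (second moment
< 10⁻⁶) add four seeded random-rotation starts.  Each start is refined by
Nelder–Mead over (axis-angle, translation) with tolerance 10⁻⁴ and at most
300 iterations.  Scores from this engine are internally consistent and are
validated against its own oracles; they are not expected to equal any other
shape-overlay program's numbers.

Conformers come from ETKDG distance-geometry embedding with MMFF
relaxation, RMSD-deduplicated at 0.5 Å; per-molecule seeds are derived from
the run seed and the record id, so runs are reproducible and insertion
order does not matter.  The full-scale policy (5 query conformers, 50/600
reference conformers for ChEMBL/DrugBank, 50 query conformers against
crystallographic PDB poses) is the default on the policy object; validation
runs and examples use 2 conformers per side, which the planted-recovery
results show is already sufficient for near-duplicate analogs.  Ensemble
scores are the maximum TanimotoCombo over conformer pairs; the 3D hit cut
is TC ≥ 1.2.

By default the pipeline computes 3D scores only for 2D-passing pairs.
Because consensus is a conjunction, this cannot change the consensus hit
set; pairs never scored in 3D simply carry no TanimotoCombo value.
A `--skip-3d` mode reduces consensus to the 2D flag for quick surveys.

## Consensus, join and ranking

Pairs present in only one screen fail consensus (logged, not an error).
Joining across corpora uses the canonical isomeric SMILES as key — stereo
descriptors included, no tautomer normalization, since collapsing tautomers
would conflate the enumerated query states.  A group is a cross-corpus hit
when it has consensus-passing entries in ≥ 3 corpora ("any pass" per
corpus; a strict variant requiring a pass in every corpus the structure
appears in is available behind a flag).

Target association is structural: a hit structure maps to targets through
its ChEMBL activity labels, plus optional externally supplied key→target
links; hits with no association are counted under `UNKNOWN`.  Counts are
distinct structures per target, corpus and label.  Ranking is descending
lexicographic on (corpora spanned, active − inactive, total ligands, active
count) with uniprot-id as the final alphabetical tie-break — a total,
deterministic order encoding the stated precedence: multi-database evidence
first, then the surplus of potent similars, then volume.

## Synthetic data

The generator emulates the *statistical structure* of public extracts:
small-molecule vs biologic DrugBank entries; PDB het groups mixed with
solvents/ions (written as an SD file with one "crystal-like" embedded pose
per ligand); ChEMBL rows spanning assay formats, activity types, qualified
relations, µM/nM units, values log-uniform over [1, 10⁵] nM (straddling the
1000 nM cut), duplicates at rate 0.3 and conflicting duplicates at rate
0.1.  Planted analogs are single substituent swaps (H → F/Cl/CH₃/OCH₃) at
aromatic CH positions of the scaffold — similar by construction — assigned
to one synthetic target with potencies log-uniform in [10, 800] nM
(unambiguously active).  Default scale: 30 decoys per corpus from a shipped
190-molecule combinatorial vocabulary (synthetic, not extracted from any
database), 5 analogs, 5 biologics, 8 contaminants.  A JSON manifest records
every planted fact, including the post-majority-vote expected labels and
expected tie-drops.

What passing these tests shows: every filter, screen, join and count
behaves exactly as specified on data with known answers, end to end, and
the whole chain is byte-deterministic under a fixed seed.  What it does not
show: performance on real database extracts — real corpora are orders of
magnitude larger, chemically far more diverse, and their activity data are
noisier than the clean planted analogs; PDB mock poses are embedded
geometries, not curated crystal structures, so the crystal-mode screen is
exercised mechanically, not crystallographically.

## Known limitations

- First-order Gaussian overlap overestimates absolute volumes; only the
  Tanimoto ratios are meaningful.
- The pharmacophore SMARTS set is deliberately small; exotic feature
  chemistry (tautomer-dependent donors, charged metals) is out of scope.
- Cross-corpus joining is exact on stereochemistry and tautomer state;
  databases that register different tautomers of one compound will not
  join (by design, but worth knowing).
- The target ranking has no statistical calibration; it orders evidence,
  it does not test it.
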