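# Methods

This note documents the models, conventions and design choices behind
`ifpgrow`, in the order a user meets them: fingerprint scoring, interaction
geometry, pose generation, the genetic algorithm, pharmacophore filtering,
shape/electrostatic similarity, cross-docking analytics, and the synthetic
fixtures that make all of it testable offline.

## Interaction fingerprints and the IFP_CS score

A protein–ligand pose is encoded residue-by-residue: residue *i* and
interaction class *c* (eight classes, fixed order: hydrophobic, aromatic
face-to-face, aromatic edge-to-face, H-bond protein-donor, H-bond
protein-acceptor, salt bridge protein-positive, salt bridge
protein-negative, metal coordination) set bit `8*i + c` when the
corresponding geometric predicate is satisfied.  The fingerprint length is
therefore exactly `8*r` for a receptor with `r` polymer residues; residue
order is file order and is treated as immutable, which is why duplicate
residue identity keys `(chain, number, insertion-code)` are a hard error
at parse time.

The score of a query fingerprint B against a reference fingerprint A is
the negative cosine similarity `-(A·B)/(‖A‖‖B‖)`, bounded in [-1, 0].
Conventions:

* the similarity involving an all-zero vector is defined as 0, never an
  exception — a generated molecule with no detected interactions must be
  rankable (at the worst possible score) rather than crash a generation;
* the cosine is computed with a single square root
  (`dot / sqrt(‖A‖²·‖B‖²)`) so that the self-comparison of any nonzero bit
  vector is exactly −1.0 in floating point;
* the reference fingerprint is computed once per run and cached with its
  residue count; scoring against a receptor with a different `r` is an
  error, because cosine similarity requires commensurate vectors;
* a molecule with several poses scores as its best (most negative) pose;
* the fingerprint covers *all* residues of the supplied receptor; users
  who want a binding-site-only fingerprint pre-truncate the receptor.

`InteractionFingerprinter` (fit → transform) and `IFPScorer`
(fit → predict) expose this as scikit-learn-style estimators, so the
fingerprint matrix and the score vector compose with ordinary sklearn
tooling.

## Interaction geometry

The geometric criteria are deliberately simple, fully parameterised
(`ContactParams`) and documented, because different fingerprint dialects
draw these lines differently.  Defaults (distances in Å, angles in
degrees):

| channel | predicate | default |
|---|---|---|
| hydrophobic | apolar C/S to apolar C/S distance | ≤ 4.0 |
| aromatic face-to-face | ring-centroid distance; interplane angle | ≤ 5.0; ≤ 30° |
| aromatic edge-to-face | ring-centroid distance; interplane angle | ≤ 5.0; 60–90° |
| H-bond (both directions) | donor–acceptor heavy distance; D–H…A angle when an explicit H exists | ≤ 3.5; ≥ 120° |
| salt bridge (both signs) | charged-group centroid distance | ≤ 4.0 |
| metal | metal to coordinating O/N distance | ≤ 2.8 |

Interplane angles are folded into [0°, 90°], so the face-to-face and
edge-to-face windows are disjoint by construction and a ring pair can
never satisfy both.  A group that satisfies both H-bond directions sets
both channels.  Per (residue, channel) at most one contact is reported
(the closest realizing pair).

**Hydrophobic = apolar.**  The hydrophobic role is restricted to
non-aromatic carbon/sulfur with no N/O neighbour.  Two reasons: aromatic
carbons already engage through the two dedicated stacking channels, and
counting them as hydrophobic would make every stacked or edge-on ring pair
double-fire the hydrophobic channel (an edge-on ring within the 5 Å
aromatic window necessarily brings ring atoms within ~3.4 Å).  Restricting
to apolar sp3 C/S keeps the eight channels disjoint in what they measure.

Role perception is template-driven for receptor residues (the twenty
standard amino acids plus the fixture templates; unknown residues fall
back to element rules) and topology-driven for ligands (donors: N/O/S with
a hydrogen; acceptors: O with non-positive charge, plus neutral
non-amide, non-pyrrolic N; charged groups: formal charges grouped by
carboxylate/guanidinium/imidazolium templates).  No pKa model is applied —
inputs are assumed protonated for the target pH upstream, as is standard
in structure-preparation pipelines.  Hydrogens are optional: the H-bond
donor-angle criterion applies only when the donor's hydrogen is explicit,
otherwise the check is distance-only.

## Pose providers

Docking engines are out of scope by design.  The `PoseProvider` contract
(`propose(molecule, n, seed) → ≤ n posed molecules`, deterministic under
the seed) has two implementations:

* `ToyAlignProvider` embeds a seeded ETKDG conformer and rigidly superposes
  it on the reference ligand over their maximum common substructure
  (principal-axis alignment as a fallback; deterministic sign conventions).
  A molecule with the reference topology receives the reference conformer
  verbatim, which is what makes the end-to-end self-score of −1 reachable.
  Poses 2..n add seeded Gaussian coordinate noise (default σ = 0.25 Å).
  This provider is a *testing substitute*, not a docking method: it has no
  notion of steric feasibility against the receptor.
* `read_external_poses` ingests SDF/PDB pose files written by a real
  engine, validating atom counts against the docked topology.

## The genetic algorithm

Generation 0 scores the seed molecules.  Each later generation is built
from the previous generation's top `survivors`:

* **mutation** attaches one library fragment to a seeded-random
  hydrogen-bearing C/N atom of a parent through a single bond (growing);
* **crossover** decomposes both parents by BRICS rules and rebuilds a
  child from one fragment of each at a compatible junction (merging);
* **elites** are carried unchanged with their scores, which guarantees the
  per-generation best score is non-increasing;
* duplicate children (by canonical SMILES) within a generation collapse to
  the first occurrence; an operator that finds no legal chemistry returns
  a skip signal and the slot is simply lost for that generation.

Selection keeps the most negative scores, ties broken by lexicographic
canonical SMILES so whole runs are reproducible from `(config, seed)`.
A generation producing only skip signals terminates the run early.  No
drug-likeness filters are imposed by default — only an optional heavy-atom
cap — because silent filters would shape results invisibly.

## Pharmacophore model

From pre-aligned complexes, ligand-side feature points are extracted from
detected contacts: the ligand acceptor atom of each protein-donor H-bond,
the ligand donor atom of each protein-acceptor H-bond, and the ligand ring
centroid (plus unit normal) of each stacking contact.  Points of the same
kind are clustered across complexes by single-linkage with a 1.5 Å merge
radius (order-independent); a cluster present in at least the retention
fraction (default 50%) of complexes becomes a feature, centred at the
cluster centroid with radius = cluster spread floored at 0.5 Å.

Matching is a binary gate with AND semantics: a pose passes only if every
feature has a ligand point of the right role within `radius + tolerance`
(default tolerance 1.0 Å), aromatic features additionally requiring the
ring-normal angle within 30°.  Partial matches are reported per-feature
but never pass.  Donor/acceptor direction vectors (projected points) are
omitted — features are position-only spheres plus aromatic normals.

## Shape and electrostatic similarity

Each heavy atom is a spherical Gaussian `p·exp(-α‖r-R‖²)` with `p = 2.7`
and `α = π (3p/4π)^(2/3) / R_vdw²`, i.e. the Gaussian's volume integral
equals the atom's van der Waals sphere volume.  Only first-order (pairwise)
overlaps are summed.  The shape Tanimoto is `V_ab/(V_aa+V_bb−V_ab)`; the
electrostatic Tanimoto applies the same formula to charge-weighted
overlaps (Gasteiger charges assigned on demand and recorded in
provenance), clamping negative values to 0 and defining the all-zero
charge case as 0.  `et_combo` is the sum, so a self-comparison is exactly
2.0.  Poses are compared in their given frame — no overlay search — which
is the right convention when generated poses and reference ligands already
share the receptor frame.  This is a self-contained implementation on the
familiar 0–2 combo scale; it does not claim numerical agreement with any
commercial shape/electrostatics package.

## Cross-docking analytics

Heavy-atom RMSD is computed without re-superposition and minimised over
the graph automorphisms of the heavy-atom topology (RDKit substructure
self-matches), capped at 10,000 automorphisms with an identity-mapping
fallback and warning.  Symmetry correction matters at a 2 Å gate: a
benzene ring rotated 60° in place is the same pose.  Success is RMSD
*strictly below* the threshold (a cell at exactly 2.0 Å fails); the
per-receptor success fraction ignores missing cells, the consensus is the
arithmetic mean across protocols, and receptors are ranked by consensus
with ties broken by receptor id.  Export heatmaps clip the colour scale at
4 Å.

## Synthetic fixtures

`make_toy_complex` lays the ligand groups of a `FixtureSpec` on a circle
(radius 8 Å) around the origin, one slot per planted interaction, and
places a minimal residue template at ideal geometry outside each group
(ethane hydrophobe at 3.8 Å, stacked ring at 4.5 Å centroid distance,
amide-like donor/acceptor at 2.9 Å, charged groups at 3.78 Å centroid
separation, Zn²⁺ at 2.4 Å).  Margins are engineered so *only* the planted
predicate fires per slot: stacked rings sit beyond the hydrophobic cutoff,
salt-bridge partners keep their donor–acceptor heavy atoms beyond the
H-bond cutoff with N–H vectors pointed sideways, and slots are far enough
apart that channels never fire across slots.  The planted list is
therefore the exact ground truth at σ = 0, and recovery degrades
monotonically (on average over seeds) as Gaussian coordinate noise grows.

`make_kinase_site` builds a connected, drug-like variant: a
methyl-methoxy-phenol embedded in 3D with four templates placed against
its perceived roles (acceptor at the phenol O–H, donor at the methoxy O,
stacked ring on the benzene, hydrophobe at the ring methyl) — an
ATP-site-like arrangement of a hinge donor/acceptor pair plus stacking,
used as the reference complex of the evolution demos.

`make_fragment_library` enumerates single- and double-decorated versions
of a fixed scaffold set and gates them to the fragment-like 100–150 Da
window used for de novo seeding.

What the fixtures do *not* emulate: real protein fold geometry, sterics
(the toy pose provider cannot clash with the receptor), solvation, and
conformational strain.  Passing tests therefore demonstrate the
correctness of the encoding, scoring, selection and analytics machinery —
not docking accuracy on real complexes.

## Problem sizes and defaults

The bundled demonstrations use desk-scale conditions chosen once: a
4-residue synthetic site, 4 aromatic seed fragments, a 20-fragment
library, 5 generations with 8 mutants + 4 crossovers + 2 elites and 6
survivors per generation, 3 poses per molecule at jitter σ = 0.25 Å.
Production runs would raise the generation count (published generational
design campaigns run 5–30 generations), the per-generation counts, and the
pose count (10 is a common docking default), and swap the toy provider for
a real engine through the adapter; nothing in the machinery depends on the
demo sizes.

## Known limitations

* Receptor role perception is template-based; exotic residues fall back to
  crude element rules, and receptor formal charges are not read from PDB
  charge columns.
* The H-bond angle criterion silently weakens to distance-only when
  hydrogens are absent, which can over-detect H-bonds in heavy-atom-only
  structures.
* BRICS crossover returns the first buildable recombinant of a seeded
  fragment-pair order, not a uniform sample over all recombinants.
* Halogen bonds, cation–π and water-mediated contacts are not among the
  eight channels and are not detected.
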