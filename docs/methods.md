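# Methods

This note records the models, conventions and numerical choices behind
each stage of the package, what the synthetic generators do and do not
emulate, and the known limitations.

## Structure model and generic numbering

Structures are read with gemmi (mmCIF preferred, PDB accepted) into an
ordered residue table. Hydrogens are dropped; alternate locations are
resolved per atom name by highest occupancy, ties broken by the
alphabetically first altloc tag; waters are discarded; non-polymer hetero
groups with > 6 heavy atoms are kept in a ligand side table. Non-standard
amino acids become `X`: they participate in contact geometry but are
never matched in conservation counting. Author residue numbering is kept
as found; the only cross-structure key is the generic position
`<segment_code>x<offset>` (codes 1–8 for TM1–TM7/H8, two-digit codes
12…67 for loops; 78, the TM7–H8 elbow, has no segment label of its own
and maps to "other"). Segment labels are a pure function of the segment
code. Heterodimers need no special machinery: each monomer is a chain
selection at load time; the annotation catalog links per-monomer entries
to their parent deposition through a `parent_id` column.

Residues missing side-chain atoms are included in contact analysis with
whatever atoms are modelled (an `adjacent_sidechain_rule` flag governs
only sequence neighbours, below).

## Contact detection

A residue pair is a contact when any criterion holds between heavy
atoms:

| type | criterion | default |
|---|---|---|
| vdw | d ≤ r₁ + r₂ + tolerance | tolerance 0.6 Å |
| hydrophobic | any C–C distance | ≤ 4.5 Å |
| hbond | donor–acceptor heavy atoms | ≤ 3.5 Å |
| ionic | cationic N vs carboxylate O | ≤ 4.5 Å |
| aromatic | ring-centroid distance | ≤ 5.5 Å |

Donor/acceptor and charged-atom sets follow standard residue chemistry
(Pro backbone N excluded as donor; His ring nitrogens count as cationic
behind a flag; hydroxyls and His ring N are both donor and acceptor).
These cutoffs are conventional structural-biology values; they are fully
config-exposed and echoed into every output header, so any result is
reproducible under a stated parameterization. Sequence neighbours
(|Δseqnum| ≤ 2 within a chain) only count when at least one atom of the
pair is a side-chain atom — peptide-bond neighbours always touch via
backbone, yet genuinely side-chain-mediated neighbour contacts (the
Asn–Pro pair at the TM7 kink) must survive. Intra-helical pairs are
counted. Each contact records all satisfied types, the minimum heavy-atom
distance, the closest atom pair, and the amino acids involved (consumed
by the conservation filter).

The indexed detector pre-screens candidate pairs with a k-d tree on atom
coordinates plus a second tree on ring centroids, then classifies each
candidate with the same residue-level routine the exhaustive O(n²)
scanner uses. The brute-force scanner is the correctness contract; the
test suite requires exact set equality on dozens of randomized
structures. Water-mediated and cation-π interactions and explicit
hydrogen placement are out of scope.

## Template selection

Filters (defaults): receptor completeness ≥ 83 % of generic positions,
G-protein completeness ≥ 43 % (active candidates only), sequence
identity to the human receptor strictly > 90 %, resolution ≤ 3.6 Å,
degree-active ≤ 20 % (inactive) or ≥ 90 % (active), ligand modality
inverse agonist/antagonist (inactive) or agonist (active), and a
G-protein complex required for active templates. Degree-active is an
externally supplied annotation column and is never recomputed; a crude
Cα-distance proxy (2x46–6x37) is available but clearly non-canonical. A
published variant of two cut-offs (completeness ≥ 86 %, resolution
≤ 4.0 Å) exists in the literature record this table emulates; both
parameterizations are expressible and the package deliberately does not
reconcile them. "Intermediate" annotations are never representative.

Among passing rows per (receptor, state) the representative is chosen by
best resolution, then highest receptor completeness, then lexicographic
structure id — the tie-break order is a package choice made for
determinism. Selection counts are reported under both conventions where
heterodimer splitting makes them differ: per-monomer entries versus
distinct parent depositions.

## State-specific contact statistics

Frequencies are ratios of integer counts; all threshold comparisons are
performed on exact rationals (`fractions.Fraction`), and 0.1-point
percentages appear only in reports. The denominator per pair and state
is the number of templates in which *both* positions are resolved, so
unmodelled loops do not deflate frequencies; an all-templates denominator
is available as an option. A pair contributes one count per template
regardless of how many interaction types it satisfies. The
frequency-difference thresholds (A 40, B1 67, C 75, F 100 points) are
inclusive at the boundary, as is the 30 % conservation cut-off, which
keeps a pair when the fraction of class receptors carrying any observed
amino-acid pair of that contact reaches the threshold; missing alignment
positions count as non-matching.

Determinant classification uses the partition rule: a position with only
inactivating state-specific contacts is an inactivator, only activating
an activator, both a switch. This reproduces the published roles and
remains well defined when a position has several contacts (a
"most-frequent-contact" rule would need an arbitrary tie-break).
Consensus amino acids and their conservation come from the class
alignment (ties broken alphabetically). Segment networks tally
inactivating/activating edge counts between segments, the inactivating
fraction (overall and excluding intra-segment contacts), and per-segment
switch flags. Chord/snakeplot rendering is out of scope; outputs are
tables and JSON.

## Helix movement and rotation

The membrane frame is either supplied externally (when an external
membrane-placement annotation is available) or estimated from the bundle:
normal = first principal axis of all TM Cα, oriented extracellularly via
helix topology (odd helices run EC→IC, so their low generic offsets are
extracellular), centre = TM Cα centroid.

The structure pair is superposed by Kabsch least squares on shared TM Cα
within ± 6 Å of the mid-plane — the least mobile part of the fold — with
a robust refinement: positions whose residual exceeds
max(2 × median, 0.5 Å) are trimmed (at most twice, never below half the
core), so a helix that rearranges at the membrane mid does not drag the
reference frame. The reference frame convention is a package choice; it
is recorded with every output.

Regions: extracellular end and intracellular end are the terminal 4
shared residues on the corresponding membrane side; mid is the 5 shared
residues nearest the mid-plane (window sizes config-exposed; ≥ 3 residues
required, otherwise "not measurable" — this is how unwound class-B1-like
TM6 ends are handled, never by extrapolation). Translation is the
Euclidean distance between region Cα centroids after superposition.
Rotation fits the local helix axis on a 7-residue window centred on the
region using second differences of consecutive Cα (which lie exactly in
the plane perpendicular to an ideal helix axis, avoiding the tilt bias of
a principal component on short windows); the active-state axis is the
inactive axis carried through the window's rigid fit; after removing
axis tilt by the minimal rotation aligning the axes, the rotation is the
rigid-fit angle of the region's heavy atoms projected onto the plane
perpendicular to the axis. Positive rotation is counterclockwise viewed
from the extracellular side. Degenerate fits (< 1 Å radial spread) are
"not measurable". Class consensus counts receptors whose translation
strictly exceeds 1.0 Å, with consensus when a majority of measured pairs
move. Helix kink/unwinding detection is not implemented.

## Interface mapping

A position is ligand-interacting in a structure when any heavy-atom pair
against a ligand (hetero group or flagged peptide chain) satisfies a
contact criterion; for hetero chemistry the criteria reduce to van der
Waals overlap, C–C proximity and N/O–N/O polar pairs at the hydrogen-bond
distance, since protonation and formal charges of arbitrary ligands are
unknown. Frequencies are over ligand-bearing (resp. G-protein-complex)
structures only. The orthosteric zone is ECL2 plus TM positions whose Cα
projects extracellularly of the membrane mid; allosteric ligand positions
outside it are omitted by default. The determinant overlay counts
positions on ligand sites, on G-protein sites, and on neither (the
transduction path); a position sitting on both interface types is counted
in both percentages, while the transduction count covers exactly the
positions on neither, so interface-or-path counts conserve the total.

## Mutant statistics

Shifts are mutant-level: replicates are averaged per mutant and G protein
before differencing against wild type. The Wilcoxon rank-sum test uses
mid-ranks for ties and exact enumeration of all C(n+m, n) group
assignments for groups of ≤ 10 (a tie-corrected, continuity-corrected
normal approximation beyond). The two-sided p doubles the smaller tail
(including the observed rank-sum) and caps at 1 — a convention that stays
well defined when ties make the permutation distribution asymmetric, and
that is recorded in output. With n = 6 + 6 the support of achievable
p-values is discrete with spacing ~2/924 near the lower tail; reported
p-values should be read at that granularity. Dose–response fitting and
raw BRET processing are out of scope; the module consumes fitted
log EC50/Emax values.

## Synthetic study inputs

The generators define the study conditions and are deterministic under
their seed; seeds permute presentation order only.

* **Ideal bundles**: seven helices (1.5 Å rise, 100° twist, Cα radius
  2.3 Å) on an 11 Å ring, alternating direction as in the native fold,
  generic offset 50 at the mid-plane; backbone N/Cα/C/O plus Cβ, with
  full idealized side chains only where a typed contact is required.
  Imposed motions move the terminal 8 residues of a helix rigidly
  (rotation about the extracellularly oriented helix axis, then
  translation), hold the mid value through the ± 6.5 Å plateau and
  interpolate between — the rigid zones are deliberately wider than the
  measurement windows so recovery tests probe the estimator, not the
  blend. A helper compensates the rotation-induced centroid shift so a
  composed motion yields an exactly programmed measured translation.
* **Contact ensembles**: programmed pair frequencies realized by
  deterministic counting (exactly k of n resolved templates), dropout
  applied to `positions_resolved`; recovered frequencies are exact by
  construction, which is what makes the bookkeeping tests sharp.
* **Annotation catalog**: 510 synthetic rows arranged so the default
  criteria select the published per-class template counts (A 33/14,
  B1 3/10, C 4/2, F 2/2; 42 inactive templates, 27 distinct active
  structures with the GABA_B-like heterodimer contributing two
  per-monomer active entries from one parent deposition, 13 receptors
  with both states, 45 distinct structures at ≤ 3.0 Å), plus rows exactly
  at, just above and just below every filter boundary.
* **Mutant tables**: six state-changing and six nonstate-changing
  mutants per G protein in triplicate, programmed to the published group
  means (1.07 vs 0.22 for Gs, 1.25 vs 0.25 for G15) with rank
  configurations whose exact-test p-values sit on the discrete n = 6,6
  support: 646/924 ≈ 0.6991 and 286/924 ≈ 0.3095 for efficacy exactly,
  and 18/924 ≈ 0.0195 / 4/924 ≈ 0.0043 for potency — the nearest support
  points to the published 0.0193 / 0.0049, which are not expressible as
  exact enumeration values and evidently reflect a convention of the
  original analysis tool that per-mutant raw data would be needed to
  reproduce digit-for-digit.

What the generators do **not** emulate: real side-chain rotamers and
packing, helix kinks and unwinding, crystallographic disorder beyond
simple position dropout, correlated experimental noise, and the actual
PDB corpus. Passing tests therefore demonstrate that the estimators and
bookkeeping are correct under controlled conditions, not that any
particular biological conclusion transfers to a specific receptor;
full-data magnitudes (e.g. the class-A top pair at +80 points, the small
class-C TM6 movement) are exercised as regression targets on stand-ins
constructed to exhibit them, with real-corpus runs requiring the user to
supply downloaded structures.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs: a
510-row catalog, ensembles of ≤ 47 templates, 175-residue bundles, 36–
300-residue random structures for oracle equivalence, and n = 6 + 6
mutant groups — sizes chosen so every check is exact and the whole run
completes in well under a minute. Re-running any stage with the same
inputs and configuration is byte-identical (outputs carry a parameter
hash and no timestamps).

## Known limitations

* Exact contact definitions of the original web tooling are not public;
  results depend on the stated cutoffs (all config-exposed).
* The superposition reference frame and the end/mid window sizes are
  package conventions; region-resolved rotations can differ from
  whole-helix rotation summaries.
* The generic-numbering assignment itself (structure-based alignment) is
  consumed as input, never computed.
* Ligand typing for arbitrary hetero groups is element-based only.
* The exact Wilcoxon implementation enumerates combinations; groups
  larger than 10 per side fall back to the normal approximation.
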