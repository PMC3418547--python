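# Methods

## The discrimination criterion

A column of the two-subfamily alignment is *discriminating* iff every
member of subfamily A carries one identical residue, every member of
subfamily B carries one identical residue, and the two residues differ.
This is deliberately the strictest reading of subfamily specificity — no
entropy weighting, no tolerance for a single deviant sequence. Three
consequences are design decisions, not accidents:

* any gap inside a subfamily disqualifies the column; columns that are
  **all-gap in one subfamily** are a different signal (an insertion) and
  are routed to the insertion detector instead;
* ambiguity codes (X, B, Z, J) disqualify a column, since "perfectly
  conserved" cannot be asserted through an ambiguous character;
* input is case-insensitive and `-`/`.` are both gaps (Clustal/FASTA
  dialect tolerance).

Insertions are maximal runs of columns all-gap in one subfamily and
majority-residue (strictly more than half non-gap per column) in the
other; the consensus is the per-column majority residue of the carrier,
ties broken alphabetically.

Reference mapping follows the structural-biology convention for this
protein family: positions are numbered by the ungapped index of the
bacterial RF1 reference sequence. A column where the reference is gapped
maps to `anchor+offset` (last reference residue before the column, plus
the count of reference-gap columns since it), so insert residues read as
`115+1`, `115+2`.

Pairwise identity is 100 × (identical pairs) / (columns where **both**
sequences are non-gap), rounded to the nearest integer. The denominator
convention matters (alignment length and shorter-sequence length give
different numbers); jointly-non-gap is used because it is symmetric,
alignment-padding-invariant, and the convention most alignment viewers
report. It is stated here because published identity percentages rarely
state theirs.

## Geometry primitives

Hydrogen bonds are detected from heavy atoms only: a donor and an acceptor
within **2.4–3.5 Å** (donor/acceptor roles from an embedded chemistry
table covering the 20 amino acids, backbone N/O, and the standard
nucleotide base/sugar/phosphate atoms). When the donor carries hydrogens,
the best D–H···A angle must additionally be ≥ 120°; crystal structures and
homology models in this domain usually have no hydrogens, so the angular
test is opt-in by construction. Pairs within one residue are never
reported.

Steric clashes use overlap = r_a + r_b − d with embedded van der Waals
radii C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å; an overlap above **0.4 Å**
(configurable) counts as severe. Pairs within one residue and pairs in
sequence-adjacent residues of the same chain are excluded as covalently
bonded neighbours; hydrogens are ignored. Radii and the 0.4 Å threshold are
the widely used clash-screening convention — the literature this package
models reports clashes only qualitatively ("severe").

Superposition is the closed-form least-squares rigid fit (Kabsch, SVD with
reflection correction), returning a proper rotation, translation, and the
post-fit rmsd. Degenerate correspondences (fewer than 3 pairs, collinear
point sets) are rejected. The test suite cross-checks against scipy's
independent quaternion-based `Rotation.align_vectors`.

PDB parsing is delegated to biotite; alternate locations are resolved to
the highest-occupancy conformer (ties toward altloc 'A'), insertion codes
stay part of residue identity, and residue numbering follows the file's
author numbering. Coordinates are carried as float64 alongside the parsed
arrays because file-precision float32 is too coarse for the 10⁻⁶ Å
rigid-motion invariance the geometry layer guarantees.

## Ribosome-context interpretation

**Region table.** Only the switch loop (286–301 in RF1 reference
numbering) is a fixed literature interval. The four domain spans shipped
as defaults (domain1 1–104, domain2 105–203, domain3 204–285, domain4
302–360, with the recognition loop 180–197, helix-α5 tip 110–122, helix α7
297–325, GGQ 231–233, PXT 184–186) are editorial, derived from the domain
architecture of the bacterial RF1 template structures, and are
configuration, not constants. For counting, each position is assigned one
primary region: the switch loop outranks its flanking domains; the other
loops are reported as secondary labels but counted inside their parent
domain, which is what reproduces a 20/2/1/1-style partition over
domain 2 / switch loop / domain 1 / domain 3.

**Decoding-center state.** The A-1492/A-1493 conformation is classified by
nearest template: superpose the local rRNA frame (residues 1491/1494) onto
each labelled template, measure rmsd over the two adenine bases, take the
smallest (ties break stacked < unstacked < recognized). Atoms are matched
by residue number and atom name so template and model chains may differ.

**Compatibility.** A factor pose is compatible with a decoding-center
state iff it makes zero severe clashes against the decoding nucleotides
(A-1492, A-1493, helix-69 A-1914). The verdict is by construction monotone
in the clash threshold. Factor and ribosome must share one coordinate
frame; posing is the caller's responsibility (`superpose` on shared rRNA
atoms), keeping the verdict free of hidden alignment magic.

**Switch-loop inventory.** All hydrogen bonds touching switch-loop
residues, labelled `decoding_center` (partner is one of the three decoding
nucleotides), `insert` (partner is a factor residue with an insertion
code, e.g. the RT-insert arginine numbered 115A), `helix_capping`
(side-chain amine of loop position 298/301 donating to a backbone carbonyl
within helix α7), or `intramolecular`. `interaction_replacement` compares
two inventories position-by-position — the analysis that shows the
RT-insert arginine bonding the loop backbone at exactly the position
(295) where A-1493 stabilizes the bacterial factor.

**Spatial clustering.** The claim "the discriminating positions cluster in
domain 2" is made quantitative as a permutation test: statistic = mean
pairwise Cα distance of the position set; null = same-size uniform residue
subsets of the chain; p = (1 + #{null ≤ observed}) / (1 + N), which is
never zero and exactly 1 when the set is the whole chain.

## Termination classification

Vertebrate mitochondrial code (table 2): UGA is tryptophan, so the
readable stops are UAA/UAG. Decision order per CDS, first match wins:

1. terminal codon UAA/UAG → `standard`;
2. terminal codon AGA/AGG with U immediately 5′ → `frameshift_terminable`
   (the −1-shifted codon is UAG in both cases; only the −1 shift is
   evaluated, matching the hypothesis under test);
3. CDS length mod 3 ∈ {1, 2} with terminus U or UA → `polyA_completed`
   (vertebrate mitochondrial mRNAs ending in incomplete stops are
   completed to UAA by polyadenylation) — on by default, toggleable for a
   strict reading;
4. otherwise `not_terminable`.

The genome verdict is the conjunction over CDS of (class ≠
`not_terminable`). DNA is stored with T and reported with U; GenBank
coordinates are 1-based inclusive on input, 0-based half-open internally.
Sequence extraction (join/complement, circular origin-spanning features)
is delegated to Biopython; pseudogenes are excluded.

## Synthetic data: what it emulates, and what it does not

The generators define the default study conditions:

* **Alignment** (`study_alignment_recipe`): 17 sequences per subfamily
  over a 360-residue reference plus 5 insert columns; 24 planted
  discriminating positions distributed 20/2/1/1 over domain 2, switch
  loop, domain 1 and domain 3, with the named substitutions pinned
  (119 Glu→Ile, 186 Thr→Val, 195 Ser→Gly, 298 Arg→Gln, 301 Lys→Arg); the
  "RT" insert between reference 115/116 and the "GLS" insert directly
  after the PXT motif, both carried by the mtRF1 subfamily. Background
  columns are conserved with probability 0.85 (a realistic level for a
  vertebrate-depth protein alignment); non-conserved columns get one
  deviant member so they can never satisfy the criterion by chance.
* **Structures**: planted hydrogen bonds/clashes realized exactly on a
  40 Å grid of otherwise non-interacting residues; recipes that violate
  detector invariants (bond outside the window, clash below the severe
  threshold, bond and clash on the same pair) are rejected at validation.
* **Complexes** (`gen_complex`): an idealized switch-loop fragment
  (286–301, Cα trace with the relevant side chains) against a synthetic
  decoding center. The recognized-state A-1493 is anchored with one base
  atom exactly 3.7 Å above the Thr-295 backbone carbonyl oxygen — the
  distance reported for the bacterial termination complex — and, in the
  mtRF1 variant, overlapping the RT-insert guanidinium (severe clashes);
  the stacked state parks both bases away from the factor. Planted bonds:
  Thr-295 OG1→A-1914 N7 (2.9 Å), A-1493 N6→Glu-297 OE1 (2.9 Å, bacterial
  variant, recognized state), RT-insert NH1/NH2→backbone O of 295/296
  (2.9 Å, mtRF1 variant), and the 301→298 helix-capping bond.
* **Mitogenome** (`study_genome_recipe`): 13 CDS named after the
  vertebrate mitochondrial gene set, with 8 standard stops, 2 U-preceded
  AGA/AGG, 3 incomplete termini, and ND6 on the minus strand — a
  composition matching the human-like pattern of terminable genes.

The coordinates are **rigid idealized templates**: no bond-length
chemistry, no physically plausible side-chain rotamers, no solvent. What a
passing test shows is that the detectors and classifiers are exact on
geometry they are specified over; it does not show that a real homology
model would present that geometry. Likewise the synthetic alignment
plants the regional architecture of the divergence signal but not deep
phylogenetic structure: between-subfamily identity in the fixture is far
higher than the ~39 % of the real paralogs, so identity values computed on
fixtures characterize the generator, not the biology. Conclusions about
real molecules enter only through the reference-data tests (which require
the documented downloads) — everything else is a correctness statement
about the algorithms.

## Numerical and reproducibility choices

* One `numpy.random.default_rng(seed)` per generator call; the seed is in
  every manifest; identical recipe + seed gives byte-identical files
  (GenBank records carry a fixed date for this reason).
* Detector outputs are deterministically ordered (columns; donor/acceptor
  ids; loop position). Hydrogen-bond deduplication keys on (donor,
  acceptor), so a pair of mutual donor-acceptors (two hydroxyls) yields
  one record per direction.
* The acceptance script sizes everything desk-scale: 35-sequence
  alignments, ~120-atom complexes, a 1000-permutation clustering test,
  one 13-gene genome — a full run takes seconds.
* `pipeline.run_pipeline` stamps every output with a sha256 config hash
  and the root seed; reruns with the same config are byte-identical, and
  stage failures flag the partial report rather than deleting it.

## Known limitations

* No mmCIF input; fixed-column PDB only.
* The hydrogen-bond chemistry table covers standard residues and
  nucleotides; modified residues are skipped with a warning, not modelled.
* Clash exclusion treats sequence-adjacent residues of a chain as bonded —
  correct for polymers, conservative for ligands with gapped numbering.
* Only the −1 frameshift is modelled; +1 shifts and any transcript-level
  evidence (polyadenylation sites, truncated mRNAs) are out of scope.
* The state classifier assumes the three template conformations span the
  relevant space; a genuinely novel decoding-center geometry will still be
  assigned the nearest of the three labels.
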