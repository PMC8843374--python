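# Methods

This note documents the models and procedures implemented in `kac3d`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known limits.

## Structure model and I/O

Structures are parsed with gemmi (PDB and mmCIF) into a plain
chain/residue/atom hierarchy. Residues carry **author numbering** —
the numbers printed in the coordinate file — because modification
sites are cited that way in the literature; insertion codes are
honored and `(author_number, insertion_code)` is unique per chain.
Policy decisions at parse time:

* **Altlocs** — one conformer per atom name is kept: highest
  occupancy, ties broken by the alphabetically first altloc.
* **Modified residues** (MSE, SEP, ALY, …) map to their parent amino
  acid in sequence views; the residue keeps its original name.
* **Multi-model files** collapse to model 1 (crystal structures are
  the intended input).
* The declared (SEQRES/entity) sequence is captured per chain; the
  mapping of declared positions onto resolved residues is computed by
  aligning the resolved sequence into the declared one, so unresolved
  (disordered) positions are identifiable.

The synthetic generator writes minimal fixed-column PDB (SEQRES + ATOM
+ TER); round-tripping through the parser is part of the test suite.

## Pairwise structural alignment

**Rigid route.** The residue correspondence comes from a global
Needleman–Wunsch alignment (BLOSUM62, affine gaps, open 11 / extend 1)
of the two resolved sequences; a single Kabsch superposition is
computed over all corresponding Cα and the RMSD is reported over all
of them, with no outlier rejection. This mirrors superposing two
conformers in a viewer and quoting the all-pair Cα RMSD, and it is
deliberately sensitive to hinge motions.

**Kabsch solver.** Proper rotations only (the reflection branch of the
SVD solution is forbidden); degenerate inputs (< 3 pairs, collinear
points) raise. Verified in the tests against an SVD-free rotation-grid
search.

**Flexible route.** A simplified FATCAT-style aligner:

1. *AFP search* — all gapless fragment pairs (default length **8**)
   whose optimally superposed Cα RMSD is ≤ **3.0 Å**, computed by
   batched Kabsch over all window pairs. Fragments must be contiguous
   in author numbering, so chain breaks and disordered gaps interrupt
   them.
2. *Chaining* — dynamic programming over AFPs, monotone in both
   sequences, with affine gap costs (open **8**, extend **0.5**). A
   **twist** is charged when consecutive chained AFPs cannot share one
   rigid transform — relative rotation > **15°** or translation
   difference > **3 Å** at the fragment midpoint — at a score penalty
   of **12** per twist, with at most **5** twists.
3. *Blocks* — maximal runs of mutually compatible chained AFPs; each
   block gets its own Kabsch transform. `opt_rmsd` is the
   length-weighted mean of per-block RMSDs; `rmsd` is still reported
   from one transform over the full correspondence, so
   `opt_rmsd ≪ rmsd` is the signature of a hinge.

The chaining score is Σ length × (cutoff − fragment_rmsd) − gap costs
− twist penalties: monotone in alignment quality and cheap to verify.
These defaults are configurable; bit-compatibility with any particular
flexible-alignment release is a non-goal, and the published figures
for real conformer pairs are reproduced qualitatively (flexible far
below rigid), not digit-for-digit. For dense AFP pools (highly similar
chains) the pool is capped at 2500 fragments by RMSD, which cannot
remove the winning chain in practice because discarded fragments are
strictly worse copies along the same diagonals.

**Chain selection.** All homolog polymer chains are aligned against
the fixed target chain; the kept chain minimizes `opt_rmsd`, then
maximizes resolved sequence length, then score, then takes the
smallest chain id. The selection records which criterion decided and
is permutation-invariant.

## Structure-anchored MSA

Columns are exactly the target chain's resolved residues, in order.
Each homolog row is its pairwise correspondence projected onto those
columns; homolog residues aligned to nothing in the target are dropped
and **counted** (`dropped_insertions`), so the information loss is
measurable. Anchoring is target-only: adding or removing a homolog
never re-gaps other rows, and reading a row back against the target
row reproduces the pairwise correspondence exactly (a tested
invariant).

## Conservation calls

A site is **conserved in 3D** when a homolog lysine occupies the
target site's position in space after superposition:

1. *Aligned route* — the correspondence maps the site to a homolog
   residue that is lysine **and** spatially consistent: its Cα lies
   within `rescue_cutoff` of the superposed target Cα under the
   containing block's transform. The spatial condition is what makes
   the call a 3D statement rather than a relabelled sequence call —
   under a rigid alignment of a hinged pair, the sequence-derived
   correspondence still names the right residue while the superposed
   geometry puts it far away, which is precisely the failure mode a
   structure-first analysis must expose.
2. *Rescue rule* — if the site is unaligned or the aligned residue is
   not lysine, any **unaligned** homolog lysine whose Cα falls within
   `rescue_cutoff` (default **5.0 Å** Cα–Cα) of the superposed site
   counts as conserved, flagged `rescue`. This codifies the manual
   inspection of structural overlays that catches lysines missing from
   alignment output. An aligned lysine never triggers rescue.
3. *Disorder rule* — if the site maps into a homolog coordinate gap,
   the declared sequence within ±`disorder_window` (default **2**)
   residues of the gap-interpolated position is inspected; an
   unresolved lysine there counts as conserved, flagged `disorder`
   (present in the linear sequence, disordered in the crystal).

**Conserved in 1D** means the homolog row of a sequence MSA has K in
the column holding the target site. The internal sequence MSA is
target-anchored (each homolog globally aligned to the target and
projected onto target columns); an externally produced gapped FASTA
can be imported instead. Conservation requires lysine identity
exactly; an arginine or histidine at the position is reported as a
`positive_substitution` annotation, never as conserved.

Disagreements are classified per call: `open_star` (1D true, 3D
false), `filled_star` (3D true, 1D false), otherwise `agree`. The
three labels partition all calls.

**Domain filter.** A site's call enters taxon summaries only when the
homolog alignment covers ≥ `coverage_threshold` (default **0.7**) of
the target residues of the domain containing the site — otherwise a
missing domain would masquerade as a lost lysine. Summaries report
conserved/total per site × taxon group; the per-homolog matrix orders
rows by percent identity with cells in
{dot, open_circle, open_star, filled_star, blank} (`open_circle` marks
conservation established by rescue or disorder rather than the direct
alignment).

## Structural site annotation

All thresholds codify judgements usually made by eye, and each is a
config key:

* **Secondary structure** — φ/ψ windows (helix −100…−30 / −80…−5;
  strand −170…−70 / 80…180) confirmed by Cα(i)–Cα(i+3) ≈ 5.3 Å for
  helices and Cα(i)–Cα(i+2) ≈ 6.7 Å for strands; runs shorter than 4
  (helix) / 3 (strand) collapse to loop. Dihedral-based assignment
  keeps the package dependency-free and collapses naturally to the
  3-class scheme used in site tables; it is not DSSP and will differ
  from it near termini and in irregular elements. The *end flag* marks
  residues within 2 positions of their segment's terminus.
* **Solvent accessibility** — Shrake–Rupley quadrature (golden-spiral
  points, default **960**/atom, probe **1.4 Å**, element van der Waals
  radii; unknown elements fall back to 1.8 Å with a warning). Relative
  accessibility divides residue SASA by tabulated Gly-X-Gly maxima
  (Tien et al. 2013 theoretical values), clipped to [0, 1.2].
  *Surface exposed* ⇔ relative accessibility ≥ **0.20** in monomer
  context. The total-residue denominator is used rather than a
  side-chain-only one because reduced side chains (see below) leave
  side-chain-only denominators undefined on synthetic chains.
* **Interfaces and contacts** — a residue is at an interface when any
  heavy atom lies within **5.0 Å** of another polymer chain; het
  groups and nucleic-acid chains yield ligand / nucleic-acid contact
  records with per-entity minimum distances.
* **Hydrogen bonds** — N/O donor–acceptor pairs within **3.5 Å**,
  water-mediated when both legs through a water oxygen are within the
  same cutoff. No angle term: crystal structures carry no hydrogens,
  and adding modelled hydrogens was judged out of scope.

## Synthetic families

The generator builds an ideal-geometry target (bond lengths N–CA
1.458, CA–C 1.525, C–N 1.329 Å; ω = 180°; helix φ/ψ −57/−47, strand
−120/+120; loops drawn deterministically from a fixed four-pair set
chosen to fall outside both the helix and strand windows) and derives
homologs by copying its coordinates and mutating its sequence to a
requested identity (realized within 1 percentage point for chains
≥ 100 residues; an unreachable request errors with the achievable
bound). Side chains are reduced to CB plus an idealized NZ for lysines
— sufficient for alignment and conservation geometry without a rotamer
library; feature tests needing richer residues build micro-fixtures by
hand. Lysine is excluded from the random-sequence alphabet so planted
sites are the only lysines and the truth table is unambiguous.

Planted per-homolog outcomes and the truth they imply:

| outcome | 3D | 1D | label | flag |
| --- | --- | --- | --- | --- |
| conserved | ✓ | ✓ | agree | — |
| substituted (to X) | ✗ | ✗ | agree | — |
| sequence_shifted (k) | ✓ | ✗ | filled_star | rescue |
| displaced | ✗ | ✓ | open_star | — |
| disordered | ✓ | ✓ | agree | disorder |

`sequence_shifted` moves the lysine k positions in sequence while
pinning its atoms at the target site's spatial position and scrambling
the surrounding loop so no fragment covers it — the pure 3D-only case.
`displaced` keeps the lysine in sequence but translates its loop ~15 Å
away — the pure 1D-only case; it extends the outcome set because no
combination of the other kinds can produce (1D ✓, 3D ✗) once the
disorder rule exists. Hinges rotate a domain rigidly about an axis
through its first Cα (internal RMSD of the rotated domain is 0 by
construction); Gaussian coordinate noise is optional.

The default study conditions (`demo_family_spec`) are six homologs at
58–92% identity cycling through the outcomes, one 30° hinge conformer
and one mildly noisy structure (σ = 0.15 Å), with taxon labels cycling
through the domain-of-life groups. Identity range and hinge magnitude
mirror what a real homolog cohort above a 30% identity threshold with
open/closed conformers looks like; problem sizes (90-residue chains,
2 sites, 6 homologs) keep every stage exact and the whole suite fast
while exercising all code paths.

**What passing tests do and do not show.** The generator emulates the
geometry of the decision problem — hinges, disorder, sequence shifts,
spatial displacement — under ideal backbone geometry and planted,
unambiguous truth. It does not emulate real side-chain packing,
crystal-packing artifacts, sequence-dependent loop conformations,
alternate conformers, or genuinely ambiguous sites (e.g. two lysines
near one site). Perfect recovery on these families demonstrates the
bookkeeping and the geometric rules are correct, not that the default
cutoffs are optimal for any particular real protein family.

## Numerical choices and degenerate inputs

* Kabsch refuses < 3 pairs and collinear sets rather than returning an
  arbitrary rotation.
* Chaining ties are resolved by the DP's deterministic argmax order;
  chain selection breaks full ties on chain id; representative
  selection breaks resolution ties on PDB id — all runs are
  reproducible and permutation-invariant, and a rerun of the pipeline
  is byte-identical.
* An alignment with no chainable fragments returns an explicitly
  flagged empty result (score 0) instead of failing, and downstream
  calls treat it as "nothing conserved".
* Homolog families with zero members passing the identity filter
  produce a target-only report with a warning, not an error.

## Known limitations

* The flexible aligner is sequential (no non-sequential or circular
  permutation alignment) and aligns one pair at a time (no true
  multiple superposition).
* 3D conservation is judged at the Cα level; side-chain orientation is
  not considered.
* The disorder rule interpolates positions through coordinate gaps
  linearly in author numbering and so can mis-estimate across long or
  heavily inserted gaps.
* Live structure-database and sequence-database queries are out of
  scope; homolog cohorts, taxon labels and wild-type flags are input
  metadata.
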