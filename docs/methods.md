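# Methods

## Scope and model

A rethreading design is specified by (i) a set of excisions — cut pairs
`(left_keep, right_keep)` inside loop regions, removing every residue
strictly between — and (ii) a permutation of the resulting fragments that
keeps the first and last fragments in place (`preserve_termini`, the
default; free-termini permutations are supported for completeness). The
package's combinatorial core enumerates excisions and orders exhaustively
and deterministically (lexicographic by cut positions, then by
permutation), so runs are reproducible without any random state.

Two conventions resolve questions the problem leaves open:

* **Fragment labels** follow the original chain order (`a` is always the
  N-terminal fragment). A rethreaded construct is often described with
  letters assigned along its own reading order instead;
  `topology_string(design, relabel=True)` prints that form.
* **Rescued residues** (`extra_retained`) are residues inside an excised
  window that are kept anyway. They attach as an appended singleton to the
  C-end of the fragment preceding their excision (matching how such rescues
  are reported in practice, e.g. a residue kept "past" the preceding
  strand); attachment to the following fragment's N-end can be requested
  per residue. Junction anchors are always the actual new chain adjacency —
  the last retained residue of the preceding fragment, including rescued
  singletons, to the first retained residue of the following one.

## Junction feasibility

The gap is the Euclidean distance between the donor's backbone carbonyl
carbon and the acceptor's amide nitrogen. Published descriptions of the
same measurement vary between carbonyl C and carbonyl O; the C→N convention
is the default and O→N is a configuration switch (`anchor`). The allowed
span is

    span_per_residue × (flex_donor + flex_acceptor + 1)

with `span_per_residue = 3.5 Å` — deliberately below the 3.8 Å trans Cα–Cα
maximum, so a "feasible" verdict does not require fully extended loops. A
junction additionally requires `min_flank = 1` flexible residue on each
side: the flexible counts are the maximal runs of loop-labelled residues at
the fragment ends, taken from the secondary-structure annotation.
Feasibility is monotone in the flexible-residue budget and antitone in the
gap; infeasible junctions flag the design rather than discard it, so a user
can relax parameters and re-examine.

## Secondary structure

Curated segment tables (TSV of H/E ranges in author numbering; everything
else is loop) are the preferred annotation route and are authoritative in
tests. The built-in assigner is CA-trace-only, in the spirit of P-SEA:
windows of CA(i)–CA(i+2/3/4) distances plus the CA virtual dihedral
(helix ≈ +50°, strand ≈ ±180°, planar arcs ≈ 0°), with a residue labelled
H/E only when two overlapping windows agree. The two-window rule suppresses
the main CA-only failure mode — a smooth loop arc mimicking regular
geometry over a single window at an element boundary — at the cost of
missing helices shorter than ~6 and strands shorter than ~5 residues, and
of letting element ends fall to loop. Both biases are conservative for this
application, where loop labels gate where the chain may be cut.

## Superposition and comparison

Kabsch superposition is the standard SVD construction with the determinant
guard (returned rotations are always proper; near-collinear inputs warn).
The core superposition fits all mapped CA pairs, then alternates refitting
with outlier handling until membership is stable, capped at 20 iterations:
pairs deviating more than `reject_cutoff = 2.0 Å` are dropped *gradually*
(at most the worst 20 % of current members per round) so that a fit skewed
by many genuine outliers — e.g. half the chain being rebuilt loops — can
still recover the consistent core; once no member exceeds the cutoff,
rejected pairs are allowed back in if the refined fit brings them under it.
The procedure is idempotent on its own core.

Displacements are CA–CA distances in the core frame; the census thresholds
default to 1 Å and 4 Å. Per-fragment RMSDs are computed in the same global
frame (no per-fragment refit), which is what makes them a misthreading
diagnostic: a model assembled by sequential threading scores well on
unmoved fragments and fails exactly on the permuted ones. Their
pair-count-weighted pooled RMS equals the all-pairs RMS by construction,
which the tests assert. Ligand RMSD matches atoms by name in the
protein-superposition frame without refitting — it measures ligand movement
relative to the protein, not ligand-internal geometry. B-factor summaries
are plain means over heavy atoms; the junction-site selection is ±2
residues around each junction anchor (configurable), since "at the incision
points" has no canonical window.

## Synthetic fixtures

The toy generator emulates only what the machinery needs: a single chain of
idealised N/CA/C/O backbone (no side chains, no CB) built from helix
(1.5 Å rise, 100°/residue, right-handed), extended-strand (two-residue
zigzag repeat, 3.3 Å axial step) and circular-arc loop elements with 3.8 Å
CA steps; N/C/O are placed by fixed offsets along the CA trace, giving
~1.3 Å peptide C–N links on straight stretches. Loops take a total turning
angle and an out-of-plane tilt, which is how the bundled four-strand
example (`examples.sheet_toy`) places strands next to neighbours that are
distant in sequence — the geometric precondition for a feasible swap.
Coordinate noise is Gaussian, i.i.d. per coordinate, seeded; generation is
byte-deterministic for a fixed spec.

Realised variants keep retained fragments at parent coordinates and rebuild
the flexible flank residues of each junction along a smooth arc between the
flanking rigid CAs (straight interpolation when spacing is comfortable,
bowing outward to keep ≤ 3.8 Å steps otherwise; an unbridgeable junction
raises). Deliberate decoys translate whole fragments, optionally without
loop rebuilding, to emulate rigidly misplaced fragments.

These fixtures validate bookkeeping and geometry exactly — partitions,
renumbering, feasibility algebra, superposition, diagnostics — but they are
not physically realistic backbones: no Ramachandran validity, no packing,
no side chains, and loop rebuilding is purely geometric. Passing tests
therefore demonstrate that the tool measures real structures correctly, not
that a feasible design will fold.

A synthetic 159-residue parent (`examples.dhfr_like_parent`) reproduces the
segment layout of the classic dihydrofolate-reductase rethreading so the
worked example's sequence-level arithmetic (construct length 147, 12
removed, old 25 → new 42, old 121 → new 136, flank counts 6/1, 10/13, 2)
can be checked with no external data. Its coordinates are idealised and
meandering; junction gaps measured on it are not meaningful, and the design
built on it is honestly reported as geometrically infeasible.

## Problem sizes and numerics

The test suite and the acceptance script run on the 35-residue sheet toy
(exhaustive connectivity counts over up to ~1800 cut combinations, 500–1000
random designs for partition conservation) and the 159-residue synthetic
parent; the rotation-grid oracle for Kabsch optimality uses ≤ 6-point sets
on a 36×18×36 Euler grid (resolution bound ~0.15 Å). Structure I/O keeps
the first model only, drops hydrogens and waters, and keeps one alternate
location per atom (highest occupancy, ties to altloc `A`). Degenerate
inputs are errors, not silences: empty structures, empty mappings, core
superpositions retaining fewer than 3 pairs, missing anchor atoms.

## Known limitations

* PDB input/output only (no mmCIF writing), single chain per design,
  crystal-structure use cases; no symmetry expansion.
* No loop sequence optimisation, de-novo linker design, or energetic
  evaluation — feasibility is purely geometric.
* The reference structure for incision-site measurement is the user's
  choice; annotations are structure-dependent and the tool does not
  reconcile segment boundaries across different models of the same protein.
* Circular permutation (fusing the native termini) is out of scope.
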