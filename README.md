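# rethread

Design and validate **protein rethreadings** — redesigns that cut a
single-chain protein inside its loops, discard a few loop residues, and
reconnect the resulting fragments in a new order. The secondary-structure
elements and the original N/C termini stay put; only the connectivity (the
topology) changes. The approach generalises circular permutation and is the
experimental counterpart of *multiple loop permutation* (MLP): residues that
are distant in sequence but close in space offer junctions where the peptide
chain can take an alternative path through the same fold.

The package is for protein engineers and structural bioinformaticians who
want to (i) enumerate where a structure can be rethreaded, (ii) emit the
designed construct (sequence, renumbering map, topology string, alignment),
and (iii) validate a realised design against its parent crystal structure
with mapping-aware superposition metrics.

## The model

Two rules drive the design layer.

**Connectivity.** Introducing one new connection requires breaking two
peptide bonds, which fragments the chain; keeping a single polypeptide with
the original termini therefore requires at least **three** simultaneous
excisions. With *k* excisions the chain is split into *k*+1 fragments, the
two terminal fragments are pinned, and the number of non-identity
reorderings is

    N(k) = (k - 1)! - 1

so N(2) = 0 (two cuts can never rethread), N(3) = 1 (exactly one swap of the
two middle fragments), N(4) = 5, ... The package asserts this by exhaustive
enumeration.

**Loop closure.** A new junction between fragment ends is measured from the
donor's backbone carbonyl carbon to the acceptor's amide nitrogen (carbonyl
oxygen available as an alternative convention). With `f` flexible loop
residues left on the two sides of the junction, the gap `d` is considered
bridgeable when

    d <= s * (f + 1)      (s = 3.5 Å per residue by default)

and each side keeps at least one loop residue. Excisions are only allowed
inside loops, where the remaining residues can adjust their conformation.

Validation follows standard crystallographic practice: the mapped CA pairs
are superposed by least squares (Kabsch) with iterative outlier rejection to
find the undisturbed core and its RMSD, then per-residue CA displacements,
a displacement census (how many residues moved > 1 Å / > 4 Å), per-fragment
RMSDs (a misthreaded model fails exactly on the permuted fragments), ligand
RMSD in the protein frame, and B-factor summaries are reported.

## Worked example

The classic rethreading of *E. coli* dihydrofolate reductase cuts the
159-residue chain at 15|25 (removing 16–24), 118|122 (removing 119–120,
residue 121 is rescued), and 147|149 (removing 148), then swaps the two
middle fragments. On a synthetic 159-residue parent with the same segment
layout (`rethread.examples.dhfr_like_parent` — coordinates are idealised,
so the printed junction gaps are not meaningful, but every sequence-level
quantity is):

```sh
$ rethread design --pdb parent.pdb --chain A --segments segments.tsv \
    --cuts "15:25,118:122,147:149" --order a,c,b,d --retain 121 --out out/
a[1-15]->c[122-147]->b[25-118,121]->d[149-159]
construct 147 aa (12 removed); junction gaps: 173.2 A, 201.3 A, 83.4 A; feasible: False
wrote design.json, design.fasta, topology.txt, alignment.txt in out
```

The topology line reads: fragment a (residues 1–15) is followed by the
fragment that was third in the wild type (122–147), then the old second
fragment (25–118 plus the rescued 121), then the C-terminal fragment
(149–159). The construct is 147 residues — 12 shorter than the parent — and
the design JSON's renumbering map sends old residue 25 to new residue 42
and old 121 to new 136. `feasible: False` is the honest verdict on this
synthetic parent, whose extended geometry leaves the junction anchors far
apart; on the real wild-type structure the three gaps are a few Ångström.

Designs can also be enumerated (`--enumerate --max-removed N`), realised
variants compared (`rethread compare --model variant.pdb:A --ref parent.pdb:A
--design out/design.json`), and toy fixtures generated (`rethread synth`).

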