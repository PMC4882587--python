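"""Per-residue secondary-structure labels and loop-interval extraction.

Incisions for a rethreading design are only allowed inside loops, so the
design layer needs to know, for every residue, whether it belongs to a helix
(H), a strand (E) or a connecting loop (L).  Two routes are provided:

* :func:`assign_sse` — a CA-trace geometric assigner in the spirit of P-SEA:
  helices and strands are recognised from short-range CA(i)-CA(i+k) distances
  and the CA virtual dihedral, so it works on backbones that carry nothing
  but CA atoms.  It is a heuristic; curated boundaries are always preferable.
* :func:`load_segments` — read curated H/E segment boundaries from a small
  TSV table (author numbering, inclusive); everything unlisted is loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import Chain

__all__ = [
    "SSEAnnotation",
    "assign_sse",
    "load_segments",
    "dump_segments",
    "loop_intervals",
]

# CA-geometry acceptance windows (Angstrom / degrees).  Canonical values:
# alpha-helix  d(i,i+3) ~ 5.1, d(i,i+4) ~ 6.2, CA-dihedral ~ +50 deg
# beta-strand  d(i,i+2) ~ 6.7, CA-dihedral ~ +/-180 deg (near-planar zigzag)
_HELIX_D3 = (4.7, 5.6)
_HELIX_D4 = (5.7, 6.9)
_HELIX_DIH = (30.0, 70.0)
_STRAND_D2 = (5.9, 7.1)
_STRAND_DIH_MIN = 120.0


@dataclass
class SSEAnnotation:
    """Per-residue H/E/L labels over a chain's author numbering."""

    numbering: list[int]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.numbering) != len(self.labels):
            raise ValueError("numbering and labels must be parallel")
        bad = set(self.labels) - {"H", "E", "L"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def label_of(self, resnum: int) -> str:
        return self.labels[self.numbering.index(resnum)]

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        """Maximal same-label runs as (type, start_resnum, end_resnum)."""
        segs: list[tuple[str, int, int]] = []
        for i, lab in enumerate(self.labels):
            if segs and segs[-1][0] == lab:
                segs[-1] = (lab, segs[-1][1], self.numbering[i])
            else:
                segs.append((lab, self.numbering[i], self.numbering[i]))
        return segs

    def is_loop(self, resnum: int) -> bool:
        return self.label_of(resnum) == "L"


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def assign_sse(chain: Chain) -> SSEAnnotation:
    """Assign H/E/L labels from CA-trace geometry.

    Residues without a CA atom are labelled L with a warning.  Interior
    residues of regular elements are recovered reliably; the one or two
    residues at element ends may fall to L, and very short elements (helices
    under ~6 residues, strands under ~5) are missed entirely — by
    construction the assigner is conservative, which is the right bias when
    the labels gate where a chain may be cut.
    """
    n = len(chain)
    has_ca = [r.has_atom("CA") for r in chain.residues]
    if sum(has_ca) < 5:
        raise ValueError(f"chain {chain.id}: need at least 5 residues with CA atoms")
    for r, ok in zip(chain.residues, has_ca):
        if not ok:
            warnings.warn(f"residue {r.name}{r.number} has no CA; labelled L")
    ca = np.array([r.atom("CA").xyz if ok else [np.nan] * 3
                   for r, ok in zip(chain.residues, has_ca)])

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(ca[i] - ca[j]))

    labels = ["L"] * n
    # a residue is called H/E only when >= 2 overlapping windows agree, so an
    # isolated helix- or strand-like window at an element boundary (where a
    # smooth loop arc can mimic regular geometry) does not mislabel the loop
    helix_score = np.zeros(n, dtype=int)
    strand_score = np.zeros(n, dtype=int)
    for i in range(n):
        if i + 4 < n and all(has_ca[i:i + 5]):
            d3, d4 = d(i, i + 3), d(i, i + 4)
            dih = _dihedral(ca[i], ca[i + 1], ca[i + 2], ca[i + 3])
            if (_HELIX_D3[0] < d3 < _HELIX_D3[1] and _HELIX_D4[0] < d4 < _HELIX_D4[1]
                    and _HELIX_DIH[0] < dih < _HELIX_DIH[1]):
                helix_score[i:i + 5] += 1
        if i + 3 < n and all(has_ca[i:i + 4]):
            d2 = d(i, i + 2)
            dih = _dihedral(ca[i], ca[i + 1], ca[i + 2], ca[i + 3])
            if _STRAND_D2[0] < d2 < _STRAND_D2[1] and abs(dih) > _STRAND_DIH_MIN:
                strand_score[i:i + 4] += 1
    for i in range(n):
        if helix_score[i] >= 2:
            labels[i] = "H"
        elif strand_score[i] >= 2:
            labels[i] = "E"
    return SSEAnnotation(numbering=chain.numbering, labels=labels)


def load_segments(table: str, chain: Chain) -> SSEAnnotation:
    """Build an annotation from a TSV of curated segments.

    Rows are ``type<TAB>start<TAB>end`` with type H or E and inclusive author
    numbering; ranges must not overlap.  Residues not covered by any row are
    labelled L, so an empty table yields an all-loop annotation.
    """
    ranges: list[tuple[str, int, int]] = []
    for ln, line in enumerate(table.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if len(parts) != 3:
            raise ValueError(f"segment table line {ln}: expected 3 fields, got {len(parts)}")
        typ, start_s, end_s = parts
        if typ not in ("H", "E"):
            raise ValueError(f"segment table line {ln}: unknown type {typ!r}")
        start, end = int(start_s), int(end_s)
        if start > end:
            raise ValueError(f"segment table line {ln}: start {start} > end {end}")
        ranges.append((typ, start, end))
    for a in range(len(ranges)):
        for b in range(a + 1, len(ranges)):
            _, s1, e1 = ranges[a]
            _, s2, e2 = ranges[b]
            if s1 <= e2 and s2 <= e1:
                raise ValueError(f"segment table: ranges {ranges[a]} and {ranges[b]} overlap")
    labels = []
    for num in chain.numbering:
        lab = "L"
        for typ, start, end in ranges:
            if start <= num <= end:
                lab = typ
                break
        labels.append(lab)
    return SSEAnnotation(numbering=chain.numbering, labels=labels)


def dump_segments(annotation: SSEAnnotation) -> str:
    """Serialise H/E segments back to the TSV format read by load_segments."""
    lines = [f"{typ}\t{start}\t{end}"
             for typ, start, end in annotation.segments if typ in ("H", "E")]
    return "\n".join(lines) + ("\n" if lines else "")


def loop_intervals(annotation: SSEAnnotation, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of L of length >= min_len, as (start, end) author numbers.

    Runs at the chain termini count; the default length threshold is 1
    because a single flanking loop residue can suffice at a junction.
    """
    return [(start, end) for typ, start, end in annotation.segments
            if typ == "L" and _run_len(annotation, start, end) >= min_len]


def _run_len(annotation: SSEAnnotation, start: int, end: int) -> int:
    return annotation.numbering.index(end) - annotation.numbering.index(start) + 1
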