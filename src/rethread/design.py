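"""Rethreading design construction and enumeration.

A rethreading redesign cuts a single-chain protein inside loop regions
(excisions), which partitions the retained residues into fragments, and then
reconnects the fragments in a new order.  Two constraints shape the search
space:

* the chain must remain a single polypeptide with the original N and C
  termini in place, which is why no termini-preserving rearrangement exists
  with fewer than three excisions — with k excisions and the two terminal
  fragments fixed there are (k-1)! - 1 non-identity orders;
* every new junction must be bridgeable by the flexible loop residues left on
  both sides of the cut: a junction is feasible when its anchor-atom gap is
  at most ``span_per_residue * (flexible residues + 1)`` and each side keeps
  at least ``min_flank`` loop residues.

Anchor-atom gaps are measured from the donor's backbone carbonyl carbon to
the acceptor's amide nitrogen by default (carbonyl oxygen as an alternative
convention).
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field, replace

from .geometry import atom_distance
from .sse import SSEAnnotation
from .structure import Chain

__all__ = [
    "Excision",
    "Fragment",
    "Junction",
    "RethreadDesign",
    "DEFAULT_ANCHOR",
    "DEFAULT_SPAN_PER_RESIDUE",
    "DEFAULT_MIN_FLANK",
    "enumerate_excisions",
    "make_fragments",
    "enumerate_orders",
    "junction_feasibility",
    "build_design",
    "topology_string",
    "render_alignment",
]

#: Donor/acceptor backbone anchor atoms for junction gap measurement.
DEFAULT_ANCHOR = ("C", "N")
#: Maximum span contributed per bridging residue, Angstrom (conservative vs
#: the 3.8 A trans CA-CA maximum).
DEFAULT_SPAN_PER_RESIDUE = 3.5
#: Minimum flexible loop residues required on each side of a junction.
DEFAULT_MIN_FLANK = 1


@dataclass
class Excision:
    """A pair of cuts inside one loop: keep ``left_keep`` and ``right_keep``,
    remove everything strictly between them."""

    left_keep: int
    right_keep: int
    removed: list[int] = field(default_factory=list)

    @classmethod
    def from_chain(cls, chain: Chain, left_keep: int, right_keep: int) -> "Excision":
        i = chain.index_of(left_keep)
        j = chain.index_of(right_keep)
        if i >= j:
            raise ValueError(
                f"excision ({left_keep}, {right_keep}): left flank must precede right flank"
            )
        return cls(left_keep, right_keep, [r.number for r in chain.residues[i + 1:j]])

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class Fragment:
    """A maximal retained stretch of the parent chain (plus optional appended
    singletons rescued from an excised window)."""

    label: str
    resnums: list[int]
    flex_n: int = 0
    flex_c: int = 0

    def __post_init__(self) -> None:
        if not self.resnums:
            raise ValueError(f"fragment {self.label}: empty")

    def intervals(self, chain: Chain) -> list[tuple[int, int]]:
        """Runs of chain-consecutive residues, as author-number ranges."""
        runs: list[tuple[int, int]] = []
        prev_idx = None
        for num in self.resnums:
            idx = chain.index_of(num)
            if prev_idx is not None and idx == prev_idx + 1:
                runs[-1] = (runs[-1][0], num)
            else:
                runs.append((num, num))
            prev_idx = idx
        return runs

    def __len__(self) -> int:
        return len(self.resnums)


@dataclass
class Junction:
    """A new covalent connection between two fragment ends."""

    donor: int
    acceptor: int
    gap_distance: float
    flex_donor: int
    flex_acceptor: int
    allowed_span: float
    feasible: bool
    slack: float

    @property
    def flex_available(self) -> int:
        return self.flex_donor + self.flex_acceptor


@dataclass
class RethreadDesign:
    parent: str
    chain_id: str
    parent_numbering: list[int]
    excisions: list[Excision]
    fragments: list[Fragment]  # original chain order
    new_order: tuple[str, ...]
    junctions: list[Junction]
    removed_total: int
    renumber: dict[int, int]  # old author number -> new 1-based number
    sequence: str
    preserve_termini: bool = True

    def fragment(self, label: str) -> Fragment:
        for f in self.fragments:
            if f.label == label:
                return f
        raise KeyError(f"no fragment {label!r}")

    def ordered_fragments(self) -> list[Fragment]:
        return [self.fragment(lab) for lab in self.new_order]

    @property
    def feasible(self) -> bool:
        return all(j.feasible for j in self.junctions)

    def mapping_new_to_old(self) -> list[tuple[int, int]]:
        """(new, old) residue-number pairs, in construct order."""
        return sorted(((new, old) for old, new in self.renumber.items()))

    def fragment_membership(self, numbering: str = "old") -> dict[str, list[int]]:
        """Fragment label -> member residue numbers (old or new numbering)."""
        if numbering == "old":
            return {f.label: list(f.resnums) for f in self.fragments}
        return {f.label: [self.renumber[r] for r in f.resnums] for f in self.fragments}

    def to_dict(self) -> dict:
        return {
            "parent": self.parent,
            "chain_id": self.chain_id,
            "parent_numbering": self.parent_numbering,
            "excisions": [
                {"left_keep": e.left_keep, "right_keep": e.right_keep, "removed": e.removed}
                for e in self.excisions
            ],
            "fragments": [
                {"label": f.label, "resnums": f.resnums, "flex_n": f.flex_n, "flex_c": f.flex_c}
                for f in self.fragments
            ],
            "new_order": list(self.new_order),
            "junctions": [vars(j) for j in self.junctions],
            "removed_total": self.removed_total,
            "renumber": {str(k): v for k, v in self.renumber.items()},
            "sequence": self.sequence,
            "preserve_termini": self.preserve_termini,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, data: dict) -> "RethreadDesign":
        return cls(
            parent=data["parent"],
            chain_id=data["chain_id"],
            parent_numbering=list(data["parent_numbering"]),
            excisions=[Excision(**e) for e in data["excisions"]],
            fragments=[Fragment(**f) for f in data["fragments"]],
            new_order=tuple(data["new_order"]),
            junctions=[Junction(**j) for j in data["junctions"]],
            removed_total=data["removed_total"],
            renumber={int(k): v for k, v in data["renumber"].items()},
            sequence=data["sequence"],
            preserve_termini=data.get("preserve_termini", True),
        )

    @classmethod
    def from_json(cls, text: str) -> "RethreadDesign":
        return cls.from_dict(json.loads(text))


def enumerate_excisions(
    chain: Chain,
    loops: list[tuple[int, int]],
    max_removed: int = 0,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[Excision]:
    """All cut pairs whose flanks fall in the same loop interval.

    For each loop, every (left_keep, right_keep) pair removing at most
    ``max_removed`` residues is emitted, provided each side of the cut keeps
    at least ``min_flank`` loop residues (the flanks themselves count).
    Output is sorted by (left_keep, right_keep).
    """
    if max_removed < 0 or min_flank < 0:
        raise ValueError("max_removed and min_flank must be non-negative")
    out: list[Excision] = []
    for start, end in loops:
        i0 = chain.index_of(start)
        i1 = chain.index_of(end)
        for i in range(i0, i1):
            if i - i0 + 1 < min_flank:
                continue
            for j in range(i + 1, min(i1, i + 1 + max_removed) + 1):
                if i1 - j + 1 < min_flank:
                    continue
                out.append(
                    Excision(
                        chain.residues[i].number,
                        chain.residues[j].number,
                        [r.number for r in chain.residues[i + 1:j]],
                    )
                )
    out.sort(key=lambda e: (e.left_keep, e.right_keep))
    return out


def _flex_runs(resnums: list[int], annotation: SSEAnnotation | None) -> tuple[int, int]:
    if annotation is None:
        return 0, 0
    labels = [annotation.label_of(r) for r in resnums]
    flex_n = 0
    for lab in labels:
        if lab != "L":
            break
        flex_n += 1
    flex_c = 0
    for lab in reversed(labels):
        if lab != "L":
            break
        flex_c += 1
    return flex_n, flex_c


def make_fragments(
    chain: Chain,
    excisions: list[Excision],
    annotation: SSEAnnotation | None = None,
) -> list[Fragment]:
    """Partition the chain into k+1 retained fragments around k excisions.

    Fragments are labelled a, b, c, ... in original chain order.  Flexible
    loop-residue counts at each fragment end are derived from the annotation
    (0 if none is given).
    """
    cuts = sorted(excisions, key=lambda e: chain.index_of(e.left_keep))
    prev_end = -1
    for e in cuts:
        i = chain.index_of(e.left_keep)
        j = chain.index_of(e.right_keep)
        if i >= j:
            raise ValueError(f"excision ({e.left_keep}, {e.right_keep}) is inverted")
        if i <= prev_end:
            raise ValueError("excisions overlap")
        prev_end = j - 1
    if len(cuts) + 1 > len(string.ascii_lowercase):
        raise ValueError("too many fragments to label")
    bounds = [0] + [chain.index_of(e.right_keep) for e in cuts]
    ends = [chain.index_of(e.left_keep) for e in cuts] + [len(chain) - 1]
    fragments = []
    for k, (lo, hi) in enumerate(zip(bounds, ends)):
        resnums = [r.number for r in chain.residues[lo:hi + 1]]
        flex_n, flex_c = _flex_runs(resnums, annotation)
        fragments.append(Fragment(string.ascii_lowercase[k], resnums, flex_n, flex_c))
    return fragments


def enumerate_orders(
    fragments: list[Fragment],
    preserve_termini: bool = True,
) -> list[tuple[str, ...]]:
    """All non-identity fragment orderings, lexicographically sorted.

    With ``preserve_termini`` the first and last fragments stay in place, so
    k excisions (k+1 fragments) admit (k-1)! - 1 rearrangements — zero for
    two cuts, exactly one for three: the minimum number of loops that must be
    exchanged in a single step to change topology while keeping one chain.
    """
    labels = [f.label for f in fragments]
    if not labels:
        raise ValueError("no fragments")
    identity = tuple(labels)
    if preserve_termini and len(labels) >= 2:
        first, *middle, last = labels
        perms = (tuple([first, *p, last]) for p in itertools.permutations(middle))
    else:
        perms = itertools.permutations(labels)
    return sorted(p for p in perms if p != identity)


def junction_feasibility(
    chain: Chain,
    donor: int,
    acceptor: int,
    flex_donor: int,
    flex_acceptor: int,
    anchor: tuple[str, str] = DEFAULT_ANCHOR,
    span_per_residue: float = DEFAULT_SPAN_PER_RESIDUE,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> Junction:
    """Measure a junction's anchor-atom gap and judge whether the available
    flexible residues can bridge it.

    The allowed span is ``span_per_residue * (flex_donor + flex_acceptor + 1)``
    and ``slack`` is allowed span minus gap (negative = infeasible).
    """
    donor_res = chain.residue(donor)
    acceptor_res = chain.residue(acceptor)
    for res, name in ((donor_res, anchor[0]), (acceptor_res, anchor[1])):
        if not res.has_atom(name):
            raise ValueError(f"residue {res.name}{res.number} lacks anchor atom {name!r}")
    gap = atom_distance(donor_res.atom(anchor[0]), acceptor_res.atom(anchor[1]))
    allowed = span_per_residue * (flex_donor + flex_acceptor + 1)
    feasible = gap <= allowed and min(flex_donor, flex_acceptor) >= min_flank
    return Junction(
        donor=donor,
        acceptor=acceptor,
        gap_distance=gap,
        flex_donor=flex_donor,
        flex_acceptor=flex_acceptor,
        allowed_span=allowed,
        feasible=feasible,
        slack=allowed - gap,
    )


def _attach_extras(
    chain: Chain,
    excisions: list[Excision],
    fragments: list[Fragment],
    extra_retained: list[int | tuple[int, str]],
    annotation: SSEAnnotation | None,
) -> tuple[list[Excision], list[Fragment]]:
    excisions = [replace(e, removed=list(e.removed)) for e in excisions]
    fragments = [replace(f, resnums=list(f.resnums)) for f in fragments]
    for item in extra_retained:
        resnum, side = item if isinstance(item, tuple) else (item, "left")
        if side not in ("left", "right"):
            raise ValueError(f"extra_retained side must be 'left' or 'right', got {side!r}")
        home = next((k for k, e in enumerate(excisions) if resnum in e.removed), None)
        if home is None:
            raise ValueError(
                f"extra_retained residue {resnum} is not inside any excised window"
            )
        excisions[home].removed.remove(resnum)
        if side == "left":
            # fragment ending at this excision's left flank; appended singleton
            fragments[home].resnums.append(resnum)
        else:
            frag = fragments[home + 1]
            frag.resnums.insert(0, resnum)
    if annotation is not None:
        for k, f in enumerate(fragments):
            f.flex_n, f.flex_c = _flex_runs(f.resnums, annotation)
    return excisions, fragments


def build_design(
    chain: Chain,
    excisions: list[Excision],
    new_order: tuple[str, ...] | list[str],
    annotation: SSEAnnotation | None = None,
    extra_retained: list[int | tuple[int, str]] | None = None,
    preserve_termini: bool = True,
    anchor: tuple[str, str] = DEFAULT_ANCHOR,
    span_per_residue: float = DEFAULT_SPAN_PER_RESIDUE,
    min_flank: int = DEFAULT_MIN_FLANK,
    parent_id: str = "parent",
) -> RethreadDesign:
    """Assemble the designed construct for one fragment reordering.

    Extra retained residues (rescued from inside an excised window) attach to
    the C-end of the fragment preceding their excision by default; pass
    ``(resnum, "right")`` to prepend to the following fragment instead.
    Junctions are measured for every new adjacency; an infeasible junction
    flags the design but does not reject it.
    """
    base_fragments = make_fragments(chain, excisions, annotation)
    excisions_eff, fragments = _attach_extras(
        chain, sorted(excisions, key=lambda e: chain.index_of(e.left_keep)),
        base_fragments, extra_retained or [], annotation,
    )
    new_order = tuple(new_order)
    if sorted(new_order) != sorted(f.label for f in fragments):
        raise ValueError(
            f"new_order {new_order} is not a permutation of fragment labels "
            f"{tuple(f.label for f in fragments)}"
        )
    if preserve_termini and len(fragments) >= 2:
        if new_order[0] != fragments[0].label or new_order[-1] != fragments[-1].label:
            raise ValueError(
                "preserve_termini: first and last fragments must keep their positions"
            )

    ordered = {f.label: f for f in fragments}
    junctions = []
    for lab_a, lab_b in zip(new_order, new_order[1:]):
        fa, fb = ordered[lab_a], ordered[lab_b]
        junctions.append(
            junction_feasibility(
                chain, donor=fa.resnums[-1], acceptor=fb.resnums[0],
                flex_donor=fa.flex_c, flex_acceptor=fb.flex_n,
                anchor=anchor, span_per_residue=span_per_residue, min_flank=min_flank,
            )
        )

    renumber: dict[int, int] = {}
    seq_parts: list[str] = []
    for lab in new_order:
        for resnum in ordered[lab].resnums:
            renumber[resnum] = len(renumber) + 1
            seq_parts.append(chain.residue(resnum).one_letter)
    removed_total = sum(e.n_removed for e in excisions_eff)

    retained = sorted(renumber)
    removed = sorted(r for e in excisions_eff for r in e.removed)
    if sorted(retained + removed) != sorted(chain.numbering):
        raise AssertionError("partition invariant violated: retained + removed != chain")

    return RethreadDesign(
        parent=parent_id,
        chain_id=chain.id,
        parent_numbering=chain.numbering,
        excisions=excisions_eff,
        fragments=fragments,
        new_order=new_order,
        junctions=junctions,
        removed_total=removed_total,
        renumber=renumber,
        sequence="".join(seq_parts),
        preserve_termini=preserve_termini,
    )


def _format_intervals(resnums: list[int], numbering: list[int]) -> str:
    index = {num: i for i, num in enumerate(numbering)}
    runs: list[tuple[int, int]] = []
    prev = None
    for num in resnums:
        if prev is not None and index[num] == index[prev] + 1:
            runs[-1] = (runs[-1][0], num)
        else:
            runs.append((num, num))
        prev = num
    return ",".join(f"{a}-{b}" if a != b else f"{a}" for a, b in runs)


def topology_string(design: RethreadDesign, relabel: bool = False) -> str:
    """Compact connectivity summary, e.g. ``a[1-15]->c[122-147]->b[25-118,121]->d[149-159]``.

    Fragment letters follow original chain order; with ``relabel`` they are
    reassigned along the construct instead (the convention used when a
    rethreaded protein is described as a->b->c->d in its own reading order).
    """
    parts = []
    for pos, lab in enumerate(design.new_order):
        shown = string.ascii_lowercase[pos] if relabel else lab
        parts.append(
            f"{shown}[{_format_intervals(design.fragment(lab).resnums, design.parent_numbering)}]"
        )
    return "->".join(parts)


def render_alignment(design: RethreadDesign, wt_sequence: str, width: int = 60) -> str:
    """Fixed-width text comparing the parent chain and the designed construct.

    Top block: the parent sequence with a fragment-label ruler; removed
    residues are marked ``.`` in the ruler.  Bottom block: the construct
    sequence with fragments at their new positions.
    """
    if len(wt_sequence) != len(design.parent_numbering):
        raise ValueError(
            f"wt sequence length {len(wt_sequence)} != parent chain length "
            f"{len(design.parent_numbering)}"
        )
    frag_of = {}
    for f in design.fragments:
        for r in f.resnums:
            frag_of[r] = f.label
    wt_ruler = "".join(frag_of.get(num, ".") for num in design.parent_numbering)
    new_ruler = "".join(
        lab for lab in design.new_order for _ in design.fragment(lab).resnums
    )

    def _block(title: str, seq: str, ruler: str) -> list[str]:
        lines = [title]
        for i in range(0, len(seq), width):
            lines.append(f"{'':>6} {ruler[i:i + width]}")
            lines.append(f"{i + 1:>6} {seq[i:i + width]}")
        return lines

    lines = _block(f"parent ({len(wt_sequence)} aa; '.' = removed)", wt_sequence, wt_ruler)
    lines.append("")
    lines += _block(
        f"design {'-'.join(design.new_order)} ({len(design.sequence)} aa)",
        design.sequence, new_ruler,
    )
    return "\n".join(lines) + "\n"
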