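"""Ready-made synthetic example systems.

Everything here is generated, not measured: these are stand-ins built with
:mod:`rethread.synthetic` so that designs can be constructed, realised and
validated without any external coordinate files.
"""

from __future__ import annotations

from .design import Excision, RethreadDesign, build_design
from .sse import SSEAnnotation, load_segments
from .structure import Structure
from .synthetic import ToySpec, make_toy_structure

__all__ = [
    "sheet_toy_spec",
    "sheet_toy",
    "sheet_toy_design",
    "DHFR_LIKE_SEGMENTS",
    "dhfr_like_parent",
    "dhfr_design_inputs",
]


def sheet_toy_spec(seed: int = 7, noise_sigma: float = 0.0) -> ToySpec:
    """Four-stranded toy whose strand order in space differs from its order
    in sequence (the middle loops turn out of plane), so that swapping the
    two middle fragments gives feasible junctions — the smallest system on
    which a genuine rethreading can be exercised end to end."""
    return ToySpec(
        elements=[
            ("E", 4),
            ("L", 7),
            ("E", 4),
            ("L", 5, {"turn": 180, "tilt": 90}),
            ("E", 4),
            ("L", 7, {"turn": 180, "tilt": 90}),
            ("E", 4),
        ],
        seed=seed,
        noise_sigma=noise_sigma,
    )


def sheet_toy(seed: int = 7, noise_sigma: float = 0.0):
    return make_toy_structure(sheet_toy_spec(seed, noise_sigma))


def sheet_toy_design(toy: Structure, annotation: SSEAnnotation) -> RethreadDesign:
    """The canonical middle-fragment swap on the sheet toy (cuts at 10|11,
    19|20, 27|28; order a-c-b-d)."""
    chain = toy.chains[0]
    excisions = [
        Excision.from_chain(chain, 10, 11),
        Excision.from_chain(chain, 19, 20),
        Excision.from_chain(chain, 27, 28),
    ]
    return build_design(
        chain, excisions, ("a", "c", "b", "d"), annotation=annotation,
        parent_id=toy.id,
    )


#: Synthetic H/E segment layout for a 159-residue parent emulating the
#: dihydrofolate reductase fold's segment sizes: an N-terminal strand, a long
#: following loop (10-25), a helix, a mixed middle, and the C-terminal
#: strand-loop-strand region whose loops (115-131, 135-150) host the second
#: and third incisions of the classic rethreading worked example.
DHFR_LIKE_SEGMENTS = """\
E\t2\t9
H\t26\t35
E\t40\t47
H\t50\t60
E\t64\t72
H\t78\t86
E\t90\t96
E\t100\t106
E\t109\t114
E\t132\t134
E\t151\t156
"""

_DHFR_LIKE_ELEMENTS = [
    ("L", 1), ("E", 8), ("L", 16), ("H", 10), ("L", 4), ("E", 8), ("L", 2),
    ("H", 11), ("L", 3), ("E", 9), ("L", 5), ("H", 9), ("L", 3), ("E", 7),
    ("L", 3), ("E", 7), ("L", 2), ("E", 6), ("L", 17), ("E", 3), ("L", 16),
    ("E", 6), ("L", 3),
]


def dhfr_like_parent(seed: int = 0):
    """Synthetic 159-residue single-chain parent with the segment layout
    above.  Coordinates are idealised toy geometry (meandering loop turns to
    avoid self-collision); the chain exists so that the classic three-cut
    worked example — excisions (15,25), (118,122), (147,149), middle
    fragments swapped, residue 121 retained — can be built and checked
    without distributing any experimental structure.

    Returns (structure, annotation) where the annotation comes from the
    curated segment table, not from geometric assignment.
    """
    elements = []
    k = 0
    for typ, length in _DHFR_LIKE_ELEMENTS:
        if typ == "L":
            elements.append((typ, length, {"turn": 100.0, "tilt": (67.0 * k) % 360}))
            k += 1
        else:
            elements.append((typ, length))
    structure, _ = make_toy_structure(ToySpec(elements=elements, seed=seed))
    structure.id = "dhfr-like-synthetic"
    annotation = load_segments(DHFR_LIKE_SEGMENTS, structure.chains[0])
    return structure, annotation


def dhfr_design_inputs(structure: Structure):
    """The worked example's design inputs on the synthetic parent: the three
    loop excisions, the middle-fragment swap order (original-order labels),
    and the rescued residue 121."""
    chain = structure.chains[0]
    excisions = [
        Excision.from_chain(chain, 15, 25),
        Excision.from_chain(chain, 118, 122),
        Excision.from_chain(chain, 147, 149),
    ]
    return excisions, ("a", "c", "b", "d"), [121]
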