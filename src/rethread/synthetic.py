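"""Idealised single-chain toy structures with known labels.

The generator builds small backbones (N/CA/C/O, no side chains) from an
ordered element list — helices, strands and connecting loop arcs — with
canonical CA-trace geometry: 3.8 A CA-CA steps, 1.5 A rise / 100 deg twist
helices, extended two-residue-repeat strands, planar circular loop arcs.
Because every element's intended label is known by construction, the toys
provide ground truth for the secondary-structure assigner, for junction
feasibility and for the comparison pipeline, with no external data.

``make_rethreaded_variant`` emulates a realised redesign: retained fragments
keep their parent coordinates while the flexible loop residues at each new
junction are rebuilt along a smooth arc bridging the gap — the same
assumption (loops adjust, cores do not) that underlies the design rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .design import RethreadDesign
from .sse import SSEAnnotation
from .structure import Atom, Chain, Residue, Structure

__all__ = ["ToySpec", "make_toy_structure", "make_rethreaded_variant"]

_CA_STEP = 3.8
_RES_NAME = {"H": "ALA", "E": "VAL", "L": "GLY"}


@dataclass
class ToySpec:
    """Recipe for a toy backbone.

    ``elements`` is an ordered list of (type, length[, params]) tuples where
    type is H/E/L; loop params may carry ``turn`` (total turning angle in
    degrees, default 180 — a hairpin).  ``noise_sigma`` adds seeded Gaussian
    jitter to every coordinate.
    """

    elements: list[tuple]
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        norm = []
        total = 0
        for el in self.elements:
            typ, length = el[0], int(el[1])
            params = dict(el[2]) if len(el) > 2 else {}
            if typ not in ("H", "E", "L"):
                raise ValueError(f"unknown element type {typ!r}")
            if length < 1:
                raise ValueError("element length must be >= 1")
            norm.append((typ, length, params))
            total += length
        if total < 5:
            raise ValueError("toy chain must have at least 5 residues")
        self.elements = norm

    @property
    def labels(self) -> list[str]:
        return [typ for typ, length, _ in self.elements for _ in range(length)]


def _helix_local(n: int) -> np.ndarray:
    # axis +x, 1.5 A rise, 100 deg/residue, 2.3 A radius, right-handed
    t = -np.arange(n) * np.radians(100.0)
    return np.column_stack([1.5 * np.arange(n), 2.3 * np.cos(t), 2.3 * np.sin(t)])


def _strand_local(n: int) -> np.ndarray:
    # extended two-residue repeat: 3.3 A axial step, +/-0.9 A zigzag
    return np.column_stack(
        [3.3 * np.arange(n), np.zeros(n), 0.9 * (-1.0) ** np.arange(n)]
    )


def _loop_local(n: int, turn_deg: float, tilt_deg: float = 0.0) -> np.ndarray:
    # circular arc: direction rotates by turn/(n+1) per step, 3.8 A chords;
    # tilt rotates the arc plane about the incoming direction, letting toys
    # place sequence-distant elements next to each other in space
    step_angle = np.radians(turn_deg) / (n + 1)
    tilt = np.radians(tilt_deg)
    normal = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    pts = [np.zeros(3)]
    ang = 0.0
    for _ in range(n):
        ang += step_angle
        d = np.cos(ang) * np.array([1.0, 0.0, 0.0]) + np.sin(ang) * normal
        pts.append(pts[-1] + _CA_STEP * d)
    return np.array(pts[1:])


def _loop_exit_rotation(turn_deg: float, tilt_deg: float) -> np.ndarray:
    """Rotation applied to the growth frame by a completed loop turn."""
    from scipy.spatial.transform import Rotation

    tilt = np.radians(tilt_deg)
    normal = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    axis = np.cross([1.0, 0.0, 0.0], normal)
    return Rotation.from_rotvec(np.radians(turn_deg) * axis).as_matrix()


def _backbone_from_ca(ca: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Place N, C, O around a CA trace with fixed offsets along the trace.

    Offsets are chosen so that consecutive C(i)-N(i+1) distances come out at
    ~1.33 A when the trace is straight — an idealisation adequate for anchor
    distances and RMSD work, not a Ramachandran-valid backbone.
    """
    n = len(ca)
    out = []
    for i in range(n):
        u_in = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        u_in = u_in / np.linalg.norm(u_in)
        u_out = ca[i + 1] - ca[i] if i + 1 < n else ca[i] - ca[i - 1]
        u_out = u_out / np.linalg.norm(u_out)
        perp = np.cross(u_out, [0.0, 1.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u_out, [0.0, 0.0, 1.0])
        perp = perp / np.linalg.norm(perp)
        c_pos = ca[i] + 1.25 * u_out
        out.append(
            {
                "N": ca[i] - 1.22 * u_in,
                "CA": ca[i],
                "C": c_pos,
                "O": c_pos + 1.23 * perp,
            }
        )
    return out


def _chain_from_ca(ca: np.ndarray, labels: list[str], numbering: list[int],
                   names: list[str] | None = None, bfactor: float = 10.0) -> Chain:
    backbone = _backbone_from_ca(ca)
    residues = []
    for i, atoms in enumerate(backbone):
        name = names[i] if names else _RES_NAME[labels[i]]
        residues.append(
            Residue(
                number=numbering[i],
                name=name,
                atoms=[
                    Atom(nm, "N" if nm == "N" else ("O" if nm == "O" else "C"),
                         pos, bfactor=bfactor)
                    for nm, pos in atoms.items()
                ],
            )
        )
    return Chain(id="A", residues=residues)


def make_toy_structure(spec: ToySpec) -> tuple[Structure, SSEAnnotation]:
    """Build the toy backbone and its intended annotation.

    Deterministic for a fixed seed; with ``noise_sigma`` 0 the seed is
    irrelevant.  Raises if the generated CA trace self-collides (non-bonded
    CA pairs closer than 2.5 A).
    """
    trace: list[np.ndarray] = []
    frame = np.eye(3)  # columns: growth direction, in-plane normal, arc normal
    pos = np.zeros(3)
    for k, (typ, length, params) in enumerate(spec.elements):
        if typ == "H":
            local = _helix_local(length)
        elif typ == "E":
            local = _strand_local(length)
        else:
            local = _loop_local(length, params.get("turn", 180.0), params.get("tilt", 0.0))
        if k == 0:
            placed = local
        elif typ == "L":
            # loop locals already start one chord away from the previous CA
            placed = local @ frame.T + pos
        else:
            placed = (local - local[0]) @ frame.T + pos + _CA_STEP * frame[:, 0]
        trace.extend(placed)
        pos = placed[-1]
        if typ == "L":
            frame = frame @ _loop_exit_rotation(
                params.get("turn", 180.0), params.get("tilt", 0.0)
            )
    ca = np.array(trace)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        ca = ca + rng.normal(0.0, spec.noise_sigma, ca.shape)
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    near = (d < 2.5) & (np.abs(np.subtract.outer(range(len(ca)), range(len(ca)))) > 1)
    if near.any():
        raise ValueError("toy placement self-collides; adjust element parameters")
    labels = spec.labels
    numbering = list(range(1, len(ca) + 1))
    chain = _chain_from_ca(ca, labels, numbering)
    structure = Structure(id=f"toy-{spec.seed}", chains=[chain])
    return structure, SSEAnnotation(numbering=numbering, labels=labels)


def _arc_points(p0: np.ndarray, p1: np.ndarray, n: int, bow: np.ndarray) -> np.ndarray:
    """n intermediate points from p0 to p1 along a circular arc.

    The arc bows in direction ``bow`` just enough to keep per-step spacing
    near the ideal CA step when the straight-line spacing would be cramped;
    a straight line is used when spacing is already comfortable.
    """
    chord = float(np.linalg.norm(p1 - p0))
    straight_step = chord / (n + 1)
    ts = np.arange(1, n + 1) / (n + 1)
    base = p0 + np.outer(ts, p1 - p0)
    if straight_step >= 3.0 or chord < 1e-9:
        return base
    target_len = 3.4 * (n + 1)

    def arc_excess(theta: float) -> float:
        # arc of half-angle theta subtending the chord: length = chord*theta/sin(theta)
        return chord * theta / np.sin(theta) - target_len

    try:
        theta = brentq(arc_excess, 1e-6, np.pi - 1e-6)
    except ValueError:
        theta = np.pi - 1e-3
    radius = chord / (2 * np.sin(theta))
    sagitta = radius * (1 - np.cos(theta))
    bow = bow / np.linalg.norm(bow)
    # quadratic-arc approximation: offset peaks mid-arc
    offsets = sagitta * np.sin(np.pi * ts)
    return base + np.outer(offsets, bow)


def make_rethreaded_variant(
    toy: Structure,
    design: RethreadDesign,
    displace: dict[str, np.ndarray] | None = None,
    rebuild_loops: bool = True,
) -> Structure:
    """Emulate the realised structure of a design built on ``toy``.

    Retained fragments keep parent coordinates; at each new junction the
    flexible flank residues (the fragment-end loop residues counted by the
    design) are rebuilt along a smooth arc between the last and first rigid
    CA positions.  The output chain is renumbered 1..N per the design.
    ``displace`` rigidly translates whole fragments (by original label) —
    useful for constructing known misthreaded decoys; with
    ``rebuild_loops=False`` the flanks keep parent coordinates too, emulating
    a model assembled from rigidly placed fragments (e.g. a sequential
    threading prediction).

    Raises if a junction cannot be bridged (per-step spacing above the CA
    maximum even on a straight path).
    """
    chain = toy.chain(design.chain_id)
    displace = displace or {}

    ca_of = {r.number: r.atom("CA").xyz.copy() for r in chain.residues}
    for lab, shift in displace.items():
        for num in design.fragment(lab).resnums:
            ca_of[num] = ca_of[num] + np.asarray(shift, dtype=float)

    # construct order of old residue numbers
    order = [num for lab in design.new_order for num in design.fragment(lab).resnums]
    ca_new = np.array([ca_of[num] for num in order])
    pos_in_construct = {num: i for i, num in enumerate(order)}

    centroid = ca_new.mean(axis=0)
    junction_iter = zip(
        zip(design.new_order, design.new_order[1:]), design.junctions
    ) if rebuild_loops else ()
    for (lab_a, lab_b), junction in junction_iter:
        fa = design.fragment(lab_a)
        fb = design.fragment(lab_b)
        flex_a = min(fa.flex_c, len(fa) - 1)
        flex_b = min(fb.flex_n, len(fb) - 1)
        n_flex = flex_a + flex_b
        i_last_rigid = pos_in_construct[fa.resnums[-1]] - flex_a
        i_first_rigid = pos_in_construct[fb.resnums[0]] + flex_b
        p0, p1 = ca_new[i_last_rigid], ca_new[i_first_rigid]
        gap = float(np.linalg.norm(p1 - p0))
        if gap / (n_flex + 1) > _CA_STEP:
            raise ValueError(
                f"junction {junction.donor}->{junction.acceptor}: gap {gap:.1f} A cannot "
                f"be bridged by {n_flex} flexible residues"
            )
        if n_flex:
            bow = (p0 + p1) / 2 - centroid
            if np.linalg.norm(bow) < 1e-6:
                bow = np.array([0.0, 1.0, 0.0])
            ca_new[i_last_rigid + 1:i_first_rigid] = _arc_points(p0, p1, n_flex, bow)

    labels = ["L"] * len(order)
    names = [chain.residue(num).name for num in order]
    new_chain = _chain_from_ca(
        ca_new, labels, [design.renumber[num] for num in order], names=names
    )
    return Structure(id=f"{toy.id}-rethreaded", chains=[new_chain])
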