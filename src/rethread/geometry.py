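"""Rigid-body superposition and distance machinery.

Least-squares superposition uses the Kabsch SVD construction with the
reflection guard (the returned rotation always has determinant +1), and the
core superposition mimics standard crystallographic practice: fit all mapped
CA pairs, reject pairs deviating more than a cutoff, refit until the retained
"core" is stable.  All distances are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Atom, Chain, Residue

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "atom_distance",
    "kabsch_superpose",
    "iterative_core_superpose",
    "per_residue_displacement",
    "rmsd_matched_atoms",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    core_members: list[int] = field(default_factory=list)  # indices into the input pairs
    iterations: int = 0


def atom_distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms, Angstrom."""
    return float(np.linalg.norm(a.xyz - b.xyz))


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rotation + translation of moving onto fixed.

    Returns the transform and the post-fit RMSD.  Inputs are (n, 3) arrays of
    paired coordinates, n >= 3.  Near-collinear inputs still yield a proper
    rotation but the in-line component is ill-determined; a warning is issued.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"coordinate sets differ in shape: {moving.shape} vs {fixed.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("need matched (n, 3) coordinates with n >= 3")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1.0):
        warnings.warn("superposition input is nearly collinear; rotation poorly determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, cf - rot @ cm)
    return transform, _rmsd(transform.apply(moving), fixed)


def iterative_core_superpose(
    moving: np.ndarray,
    fixed: np.ndarray,
    reject_cutoff: float = 2.0,
    max_iter: int = 20,
) -> SuperpositionResult:
    """Superpose on the stable core: fit, reject deviant pairs, refit.

    At each round the fit uses the current members, then membership is
    recomputed over *all* pairs (a rejected pair may re-enter if the refit
    brings it back under the cutoff), so the procedure is idempotent on its
    own core.  Raises if fewer than 3 pairs survive.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    n = moving.shape[0]
    members = np.ones(n, dtype=bool)
    transform, _ = kabsch_superpose(moving, fixed)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        transform, _ = kabsch_superpose(moving[members], fixed[members])
        dev = np.linalg.norm(transform.apply(moving) - fixed, axis=1)
        over = members & (dev > reject_cutoff)
        if over.any():
            # drop gradually (worst 20% of members per round) so a fit skewed
            # by many genuine outliers can recover the consistent core
            n_drop = max(1, int(0.2 * members.sum()))
            worst = np.argsort(np.where(over, dev, -np.inf))[::-1][:n_drop]
            new_members = members.copy()
            new_members[worst[over[worst]]] = False
        else:
            # stable against its own members; allow rejected pairs back in
            new_members = dev <= reject_cutoff
        if new_members.sum() < 3:
            raise ValueError(
                f"core superposition collapsed: {int(new_members.sum())} pairs within "
                f"{reject_cutoff} A (need >= 3)"
            )
        if np.array_equal(new_members, members):
            break
        members = new_members
    return SuperpositionResult(
        transform=transform,
        rmsd=_rmsd(transform.apply(moving[members]), fixed[members]),
        n_pairs=int(members.sum()),
        core_members=list(np.flatnonzero(members)),
        iterations=iterations,
    )


def per_residue_displacement(
    chain_a: Chain,
    chain_b: Chain,
    mapping: list[tuple[int, int]],
    transform: RigidTransform,
) -> pd.DataFrame:
    """CA-CA displacement per mapped residue pair, after moving chain A.

    ``mapping`` pairs author numbers (resnum_a, resnum_b); ``transform`` is a
    previously computed core superposition that carries chain A into chain
    B's frame.  Pairs missing a CA are skipped with a warning.  Columns:
    resA, resB, aa, displacement_A; sorted by resA.
    """
    rows = []
    for num_a, num_b in mapping:
        ra = chain_a.residue(num_a)
        rb = chain_b.residue(num_b)
        if not ra.has_atom("CA") or not rb.has_atom("CA"):
            warnings.warn(f"pair ({num_a}, {num_b}): missing CA; skipped")
            continue
        moved = transform.apply(ra.atom("CA").xyz)
        rows.append(
            {
                "resA": num_a,
                "resB": num_b,
                "aa": ra.one_letter,
                "displacement_A": float(np.linalg.norm(moved - rb.atom("CA").xyz)),
            }
        )
    return pd.DataFrame(rows, columns=["resA", "resB", "aa", "displacement_A"]).sort_values(
        "resA", kind="stable", ignore_index=True
    )


def rmsd_matched_atoms(
    res_a: Residue,
    res_b: Residue,
    atom_subset: list[str] | None,
    transform: RigidTransform,
) -> float:
    """RMSD over atoms matched by name, in the frame set by ``transform``.

    No refit is performed: this measures how far residue A's atoms sit from
    residue B's after the (protein) superposition — the right question for a
    bound ligand.  ``atom_subset`` restricts to the named atoms (None = all).
    """
    names_a = {a.name for a in res_a.atoms}
    names_b = {a.name for a in res_b.atoms}
    wanted = names_a & names_b
    if atom_subset is not None:
        wanted &= set(atom_subset)
    if not wanted:
        raise ValueError(
            f"no common atoms between {res_a.name}{res_a.number} and "
            f"{res_b.name}{res_b.number}"
            + (f" within subset {sorted(atom_subset)}" if atom_subset else "")
        )
    expected = set(atom_subset) if atom_subset is not None else names_a | names_b
    if wanted != expected:
        warnings.warn(
            f"partial atom match ({len(wanted)}/{len(expected)}); RMSD over intersection"
        )
    order = sorted(wanted)
    a = np.array([res_a.atom(nm).xyz for nm in order])
    b = np.array([res_b.atom(nm).xyz for nm in order])
    return _rmsd(transform.apply(a), b)
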