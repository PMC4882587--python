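"""One-call structural validation of a realised design against its parent.

Given the model (e.g. the crystal structure of a rethreaded protein), the
reference (its parent), and a residue mapping (the design's renumbering, or
identity for same-protein comparisons), the pipeline:

1. superposes the mapped CA pairs with iterative outlier rejection to find
   the undisturbed core and its RMSD;
2. tabulates per-residue CA displacements in that frame and censuses how
   many residues moved beyond each threshold (defaults 1 A and 4 A);
3. computes per-fragment RMSDs in the same frame — a rethreaded structure
   should score well everywhere, whereas a sequentially-threaded (misplaced)
   model fails exactly on the permuted fragments;
4. optionally measures ligand displacement (all atoms and a named subset
   such as the nicotinamide ring) without refitting, and B-factor means over
   the chain and around the junctions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    RigidTransform,
    iterative_core_superpose,
    per_residue_displacement,
    rmsd_matched_atoms,
)
from .structure import Chain, Structure

__all__ = ["CompareConfig", "ComparisonReport", "compare_structures", "bfactor_summary"]

#: Nicotinamide ring + carboxamide of NADPH (PDB component NDP), 9 atoms.
NICOTINAMIDE_RING_ATOMS = ["N1N", "C2N", "C3N", "C4N", "C5N", "C6N", "C7N", "O7N", "N7N"]


@dataclass
class CompareConfig:
    reject_cutoff: float = 2.0
    max_iter: int = 20
    thresholds: tuple[float, ...] = (1.0, 4.0)
    ligand: str | None = None          # hetero residue name, e.g. "NDP"
    ring_atoms: list[str] | None = None
    fragments: dict[str, list[int]] | None = None  # label -> reference residue numbers
    junction_anchors: list[int] | None = None      # model residue numbers
    flank_window: int = 2


@dataclass
class ComparisonReport:
    core_rmsd: float
    core_n: int
    iterations: int
    transform: RigidTransform
    displacement_table: pd.DataFrame
    n_moved_gt: dict[float, int]
    max_shift: tuple[int, int, float]  # (model resnum, reference resnum, Angstrom)
    per_fragment_rmsd: dict[str, tuple[float, int]] = field(default_factory=dict)
    ligand_rmsd: dict[str, float] = field(default_factory=dict)
    bfactor_mean: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "core_rmsd": self.core_rmsd,
            "core_n": self.core_n,
            "iterations": self.iterations,
            "n_moved_gt": {str(k): v for k, v in self.n_moved_gt.items()},
            "max_shift": {
                "model_residue": self.max_shift[0],
                "reference_residue": self.max_shift[1],
                "displacement_A": self.max_shift[2],
            },
            "per_fragment_rmsd": {
                k: {"rmsd_A": v[0], "n": v[1]} for k, v in self.per_fragment_rmsd.items()
            },
            "ligand_rmsd": dict(self.ligand_rmsd),
            "bfactor_mean": dict(self.bfactor_mean),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [
            f"core superposition: rmsd {self.core_rmsd:.2f} A over {self.core_n} residues "
            f"({self.iterations} iterations)",
        ]
        for thr, count in self.n_moved_gt.items():
            lines.append(f"residues moved > {thr:g} A: {count}")
        m_res, r_res, shift = self.max_shift
        lines.append(f"largest shift: {shift:.1f} A at model residue {m_res} "
                     f"(reference {r_res})")
        if self.per_fragment_rmsd:
            lines.append("per-fragment rmsd (core frame):")
            for lab, (rmsd, n) in sorted(self.per_fragment_rmsd.items()):
                lines.append(f"  [{lab}] {rmsd:.2f} A over {n} residues")
        for key, val in self.ligand_rmsd.items():
            lines.append(f"ligand rmsd ({key}): {val:.2f} A")
        for key, val in self.bfactor_mean.items():
            lines.append(f"mean B-factor ({key}): {val:.2f} A^2")
        return "\n".join(lines) + "\n"


def _resolve_mapping(
    model_chain: Chain,
    ref_chain: Chain,
    mapping: list[tuple[int, int]] | dict[int, int] | None,
) -> list[tuple[int, int]]:
    if mapping is None:
        common = [n for n in model_chain.numbering if ref_chain.has_residue(n)]
        return [(n, n) for n in common]
    if isinstance(mapping, dict):
        mapping = sorted(mapping.items())
    return [(int(a), int(b)) for a, b in mapping]


def compare_structures(
    model: Structure,
    model_chain_id: str,
    reference: Structure,
    ref_chain_id: str,
    mapping: list[tuple[int, int]] | dict[int, int] | None = None,
    config: CompareConfig | None = None,
) -> ComparisonReport:
    """Run the full validation pipeline; see the module docstring.

    ``mapping`` pairs (model residue number, reference residue number); None
    means identity on the residue numbers present in both chains.
    """
    config = config or CompareConfig()
    model_chain = model.chain(model_chain_id)
    ref_chain = reference.chain(ref_chain_id)
    pairs = _resolve_mapping(model_chain, ref_chain, mapping)
    pairs = [
        (a, b) for a, b in pairs
        if model_chain.residue(a).has_atom("CA") and ref_chain.residue(b).has_atom("CA")
    ]
    if not pairs:
        raise ValueError("empty residue mapping between model and reference")

    mov = np.array([model_chain.residue(a).atom("CA").xyz for a, _ in pairs])
    fix = np.array([ref_chain.residue(b).atom("CA").xyz for _, b in pairs])
    sup = iterative_core_superpose(mov, fix, config.reject_cutoff, config.max_iter)

    table = per_residue_displacement(model_chain, ref_chain, pairs, sup.transform)
    n_moved = {
        float(thr): int((table["displacement_A"] > thr).sum()) for thr in config.thresholds
    }
    top = table.loc[table["displacement_A"].idxmax()]
    max_shift = (int(top["resA"]), int(top["resB"]), float(top["displacement_A"]))

    per_fragment: dict[str, tuple[float, int]] = {}
    if config.fragments:
        by_ref = {b: i for i, (_, b) in enumerate(pairs)}
        for lab, members in config.fragments.items():
            idx = [by_ref[m] for m in members if m in by_ref]
            if not idx:
                continue
            dev = sup.transform.apply(mov[idx]) - fix[idx]
            per_fragment[lab] = (
                float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1)))), len(idx)
            )

    ligand_rmsd: dict[str, float] = {}
    if config.ligand:
        try:
            lig_model = model.hetero(config.ligand)
            lig_ref = reference.hetero(config.ligand)
        except KeyError as exc:
            warnings.warn(f"ligand comparison skipped: {exc}")
        else:
            ligand_rmsd["all_atoms"] = rmsd_matched_atoms(
                lig_model, lig_ref, None, sup.transform
            )
            if config.ring_atoms:
                ligand_rmsd["ring"] = rmsd_matched_atoms(
                    lig_model, lig_ref, config.ring_atoms, sup.transform
                )

    bfactor_mean = {"chain": bfactor_summary(model_chain)}
    if config.junction_anchors:
        flank: set[int] = set()
        for anchor in config.junction_anchors:
            idx = model_chain.index_of(anchor)
            lo = max(0, idx - config.flank_window)
            hi = min(len(model_chain), idx + config.flank_window + 1)
            flank.update(r.number for r in model_chain.residues[lo:hi])
        bfactor_mean["junction_flanks"] = bfactor_summary(model_chain, flank)

    return ComparisonReport(
        core_rmsd=sup.rmsd,
        core_n=sup.n_pairs,
        iterations=sup.iterations,
        transform=sup.transform,
        displacement_table=table,
        n_moved_gt=n_moved,
        max_shift=max_shift,
        per_fragment_rmsd=per_fragment,
        ligand_rmsd=ligand_rmsd,
        bfactor_mean=bfactor_mean,
    )


def bfactor_summary(chain: Chain, selection: set[int] | None = None) -> float:
    """Mean B-factor (A^2) over all heavy atoms of the selected residues."""
    residues = (
        chain.residues if selection is None
        else [r for r in chain.residues if r.number in selection]
    )
    values = [a.bfactor for r in residues for a in r.atoms]
    if not values:
        raise ValueError("empty selection for B-factor summary")
    return float(np.mean(values))
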