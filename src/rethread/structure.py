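"""Minimal hierarchical coordinate model and PDB/FASTA I/O.

The model deliberately carries only what the design and comparison machinery
need: author residue numbering (with insertion codes), heavy-atom coordinates,
B-factors and occupancies.  Parsing and serialisation of the PDB format are
delegated to :mod:`gemmi`; this module normalises the result (single model,
highest-occupancy altloc, no hydrogens, no waters, ligands split out).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "StructureParseError",
    "read_structure",
    "write_pdb",
    "chain_sequence",
    "write_fasta",
    "three_to_one",
]

#: Waters are dropped on read; all reported metrics are protein/ligand only.
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "DIS"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues that still read as one polymer position
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


def three_to_one(name: str) -> str:
    """1-letter code for a 3-letter residue name; ``X`` if non-standard."""
    return _THREE_TO_ONE.get(name.upper(), "X")


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Angstrom
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str | None = None
    chain_id: str | None = None  # set for hetero residues detached from a chain

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    @property
    def key(self) -> tuple[int, str | None]:
        return (self.number, self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.id}: duplicate residue numbers")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def numbering(self) -> list[int]:
        return [r.number for r in self.residues]

    def residue(self, number: int, insertion_code: str | None = None) -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.id}: no residue {number}{insertion_code or ''}")

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    def index_of(self, number: int) -> int:
        for i, r in enumerate(self.residues):
            if r.number == number:
                return i
        raise KeyError(f"chain {self.id}: no residue {number}")

    def ca_coords(self) -> np.ndarray:
        """(n, 3) CA coordinates; raises if any residue lacks a CA."""
        return np.array([r.atom("CA").xyz for r in self.residues])


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    heteros: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(
            f"structure {self.id}: no chain {chain_id!r} "
            f"(available: {', '.join(c.id for c in self.chains) or 'none'})"
        )

    def hetero(self, name: str, chain_id: str | None = None) -> Residue:
        for h in self.heteros:
            if h.name == name and (chain_id is None or h.chain_id == chain_id):
                return h
        raise KeyError(f"structure {self.id}: no hetero residue {name!r}")


def _pick_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    # highest occupancy wins; ties broken alphabetically ('A' first)
    by_name: dict[str, Atom] = {}
    for a in raw_atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, -ord(a.altloc or "~")) > (prev.occupancy, -ord(prev.altloc or "~")):
            by_name[a.name] = a
    return list(by_name.values())


def _is_amino_acid(name: str) -> bool:
    if name.upper() in _THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def read_structure(source: str | os.PathLike, fmt: str = "pdb") -> Structure:
    """Parse a PDB file (path or literal text) into a :class:`Structure`.

    Only the first model is read.  Hydrogens and waters are dropped, one
    alternate location is kept per atom (highest occupancy, then altloc
    ``A``), and non-polymer residues (ligands such as NDP) are collected in
    ``Structure.heteros`` rather than in the chains.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported format {fmt!r}")
    text: str
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            text = fh.read()
        name = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    else:
        text = str(source)
        name = "structure"
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureParseError(f"cannot parse PDB input: {exc}") from exc
    header_name = (st.name or "").strip()
    if header_name and header_name.lower() != "string":
        name = header_name
    if len(st) == 0:
        raise StructureParseError("no models found in input")
    model = st[0]

    chains: list[Chain] = []
    heteros: list[Residue] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name.upper() in _WATER_NAMES:
                continue
            atoms: list[Atom] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=ga.b_iso,
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=ga.altloc if ga.altloc != "\0" else None,
                    )
                )
            atoms = _pick_altlocs(atoms)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip() or None
            res = Residue(number=gres.seqid.num, name=gres.name, atoms=atoms,
                          insertion_code=icode)
            # ATOM records are polymer by assertion of the depositor; HETATM
            # residues join the chain only if they are amino acids (e.g. MSE)
            if gres.het_flag == "A" or _is_amino_acid(gres.name):
                residues.append(res)
            else:
                res.chain_id = gchain.name
                heteros.append(res)
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains and not heteros:
        raise StructureParseError("empty structure: no polymer or hetero residues")
    return Structure(id=name, chains=chains, heteros=heteros)


def write_pdb(structure: Structure) -> str:
    """Serialise to PDB text (ATOM/HETATM/TER records, single model)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")

    def _add(gchain: gemmi.Chain, res: Residue, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or a.name[0])
            ga.pos = gemmi.Position(*a.xyz)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        gchain.add_residue(gres)

    gchains: dict[str, gemmi.Chain] = {}
    for chain in structure.chains:
        gchains[chain.id] = gemmi.Chain(chain.id)
        for res in chain.residues:
            _add(gchains[chain.id], res, het=False)
    for het in structure.heteros:
        cid = het.chain_id or "X"
        if cid not in gchains:
            gchains[cid] = gemmi.Chain(cid)
        _add(gchains[cid], het, het=True)
    for gchain in gchains.values():
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))


def chain_sequence(structure: Structure, chain_id: str) -> tuple[str, list[int]]:
    """1-letter sequence and parallel author numbering for one chain.

    Non-standard residues become ``X`` with a warning; author numbering is
    passed through untouched (gaps and all).
    """
    chain = structure.chain(chain_id)
    letters = []
    for r in chain.residues:
        code = r.one_letter
        if code == "X":
            warnings.warn(f"non-standard residue {r.name}{r.number} encoded as 'X'")
        letters.append(code)
    return "".join(letters), chain.numbering


def write_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    """Standard FASTA text, sequences wrapped at 60 columns."""
    if not records:
        raise ValueError("no records to write")
    out = []
    for header, seq in records:
        if not seq:
            raise ValueError(f"record {header!r}: empty sequence")
        out.append(f">{header}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"
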