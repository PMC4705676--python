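"""Structure containers and PDB input/output.

The morph engine works on a lightweight hierarchical model
(:class:`StructureModel` -> :class:`ChainModel` -> :class:`Residue` ->
:class:`Atom`) holding all-atom coordinates in angstroms.  Reading and
writing of the PDB format is delegated to :mod:`gemmi`; multi-model PDB
files are the trajectory format (one MODEL block per frame).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = [
    "PolymerClass",
    "Atom",
    "Residue",
    "ChainModel",
    "StructureModel",
    "Trajectory",
    "ParsePolicy",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "extract_sequence",
    "translate_chain",
]


class PolymerClass(str, Enum):
    PROTEIN = "protein"
    RNA = "rna"
    DNA = "dna"
    OTHER = "other"


#: Standard residue names used to infer the polymer class of a chain.
PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}
RNA_RESIDUES = {"A", "C", "G", "U"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT"}
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


def classify_residue(name: str) -> PolymerClass:
    name = name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return PolymerClass.PROTEIN
    if name in RNA_RESIDUES:
        return PolymerClass.RNA
    if name in DNA_RESIDUES:
        return PolymerClass.DNA
    return PolymerClass.OTHER


@dataclass
class Atom:
    """A single atom: PDB name, element and position in angstroms."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    """A residue with author numbering and an ordered atom list."""

    name: str
    number: int
    insertion_code: str = ""
    atoms: List[Atom] = field(default_factory=list)
    polymer_class: PolymerClass = PolymerClass.OTHER

    @property
    def key(self) -> Tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None


@dataclass
class ChainModel:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def polymer_class(self) -> PolymerClass:
        """Majority polymer class over the chain's residues."""
        counts: Dict[PolymerClass, int] = {}
        for r in self.residues:
            counts[r.polymer_class] = counts.get(r.polymer_class, 0) + 1
        if not counts:
            return PolymerClass.OTHER
        return max(counts, key=lambda k: counts[k])

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class StructureModel:
    """An ordered collection of chains; the unit the morph acts on."""

    chains: List[ChainModel] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain_id in StructureModel")

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.label!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)

    def iter_atoms(self) -> Iterator[Tuple[ChainModel, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coords_array(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) array in iteration order."""
        out = np.empty((self.n_atoms, 3))
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            out[i] = a.coords
        return out

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            a.coords = coords[i].copy()

    def atom_index_map(self) -> Dict[Tuple[str, int, str, str], int]:
        """Map (chain_id, resnum, icode, atom_name) -> flat atom index."""
        out: Dict[Tuple[str, int, str, str], int] = {}
        for i, (c, r, a) in enumerate(self.iter_atoms()):
            out[(c.chain_id, r.number, r.insertion_code, a.name)] = i
        return out

    def copy(self, label: Optional[str] = None) -> "StructureModel":
        dup = _copy.deepcopy(self)
        if label is not None:
            dup.label = label
        return dup


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing the topology of one model.

    ``frames[k]`` is an (n_atoms, 3) array in the atom iteration order of
    ``topology``; ``frame_metadata[k]`` carries per-frame energy totals.
    """

    topology: StructureModel
    frames: List[np.ndarray] = field(default_factory=list)
    frame_metadata: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for f in self.frames:
            if f.shape != (n, 3):
                raise ValueError("every frame must match the topology atom count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_model(self, index: int) -> StructureModel:
        m = self.topology.copy()
        m.set_coords(self.frames[index])
        return m


@dataclass
class ParsePolicy:
    """Rules applied while reading a PDB file.

    altloc: 'highest-occupancy' keeps one conformer per atom (ties broken
    by altloc letter), 'all' keeps every record.
    hydrogens: 'strip' or 'keep'.
    waters: 'drop' or 'keep'.
    hetatm: 'keep' (ligands/ions become polymer_class=other) or 'drop'.
    """

    altloc: str = "highest-occupancy"
    hydrogens: str = "strip"
    waters: str = "drop"
    hetatm: str = "keep"


def _resolve_altlocs(atoms: List[Atom], policy: ParsePolicy) -> List[Atom]:
    if policy.altloc == "all":
        return atoms
    by_name: Dict[str, List[Atom]] = {}
    order: List[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        best = group[0]
        best.altloc = ""
        kept.append(best)
    return kept


def read_pdb(path, policy: Optional[ParsePolicy] = None, label: str = "") -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Only the first MODEL block is read (use :func:`read_trajectory` for
    multi-model trajectory files).  The parse policy controls altloc
    resolution, hydrogen stripping and HETATM handling.
    """
    policy = policy or ParsePolicy()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"empty structure in {path}")
    model = _convert_gemmi_model(st[0], policy, label=label or path.stem)
    if model.n_atoms == 0:
        raise ValueError(f"no atoms retained from {path} under the parse policy")
    return model


def _convert_gemmi_model(gmodel: "gemmi.Model", policy: ParsePolicy, label: str) -> StructureModel:
    chains: List[ChainModel] = []
    for gchain in gmodel:
        residues: List[Residue] = []
        for gres in gchain:
            name = gres.name.strip()
            if name in WATER_RESIDUES:
                if policy.waters == "drop":
                    continue
            pclass = classify_residue(name)
            if pclass is PolymerClass.OTHER and gres.het_flag == "H" and policy.hetatm == "drop":
                continue
            atoms: List[Atom] = []
            for ga in gres:
                if policy.hydrogens == "strip" and ga.is_hydrogen():
                    continue
                altloc = "" if ga.altloc in ("\0", "") else ga.altloc
                atoms.append(Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=altloc,
                ))
            atoms = _resolve_altlocs(atoms, policy)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(Residue(
                name=name,
                number=gres.seqid.num,
                insertion_code=icode,
                atoms=atoms,
                polymer_class=pclass,
            ))
        if residues:
            chains.append(ChainModel(chain_id=gchain.name, residues=residues))
    return StructureModel(chains=chains, label=label)


_PDB_COORD_MIN = -999.999
_PDB_COORD_MAX = 9999.999


def _check_coord_width(model: StructureModel) -> None:
    for _, _, a in model.iter_atoms():
        if np.any(a.coords < _PDB_COORD_MIN) or np.any(a.coords > _PDB_COORD_MAX):
            raise ValueError(
                f"coordinate {a.coords} of atom {a.name} exceeds the PDB "
                "fixed-width field (-999.999 .. 9999.999)"
            )


def _to_gemmi_model(model: StructureModel, num: int) -> "gemmi.Model":
    gm = gemmi.Model(num)
    serial = 0
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "A" if res.polymer_class is not PolymerClass.OTHER else "H"
            for atom in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or "X")
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.serial = serial
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    return gm


def write_pdb(model: StructureModel, path) -> None:
    """Write a single-model PDB file (standard ATOM/HETATM records)."""
    _check_coord_width(model)
    st = gemmi.Structure()
    st.name = model.label or "model"
    st.add_model(_to_gemmi_model(model, 1))
    st.setup_entities()
    st.write_pdb(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL blocks from 1)."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    st = gemmi.Structure()
    st.name = traj.topology.label or "trajectory"
    work = traj.topology.copy()
    for k, frame in enumerate(traj.frames):
        work.set_coords(frame)
        _check_coord_width(work)
        st.add_model(_to_gemmi_model(work, k + 1))
    st.setup_entities()
    st.write_pdb(str(path))


def read_trajectory(path, policy: Optional[ParsePolicy] = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`."""
    policy = policy or ParsePolicy()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"empty structure in {path}")
    topology = _convert_gemmi_model(st[0], policy, label=path.stem)
    frames = []
    for gm in st:
        m = _convert_gemmi_model(gm, policy, label=path.stem)
        if m.n_atoms != topology.n_atoms:
            raise ValueError("trajectory frames differ in atom count")
        frames.append(m.coords_array())
    return Trajectory(topology=topology, frames=frames,
                      frame_metadata=[{} for _ in frames])


def extract_sequence(chain: ChainModel) -> str:
    """One-letter sequence of a polymer chain; unknown residues map to X."""
    pclass = chain.polymer_class
    if pclass is PolymerClass.OTHER:
        raise ValueError(f"chain {chain.chain_id!r} is not a biopolymer")
    letters = []
    for r in chain.residues:
        name = r.name.strip().upper()
        if pclass is PolymerClass.PROTEIN:
            letters.append(THREE_TO_ONE.get(name, "X"))
        elif pclass is PolymerClass.RNA:
            letters.append(name if name in RNA_RESIDUES else "X")
        else:  # DNA
            letters.append(name[1] if name in DNA_RESIDUES else "X")
    return "".join(letters)


def translate_chain(model: StructureModel, chain_id: str, offset: Sequence[float]) -> StructureModel:
    """Return a copy with one chain rigidly displaced by ``offset`` (angstroms)."""
    offset = np.asarray(offset, dtype=float).reshape(3)
    if not model.has_chain(chain_id):
        raise KeyError(f"no chain {chain_id!r}")
    out = model.copy()
    for r in out.chain(chain_id).residues:
        for a in r.atoms:
            a.coords = a.coords + offset
    return out


def representative_atom_name(polymer_class: PolymerClass, residue: Residue) -> Optional[str]:
    """The atom used for residue-level correspondence and RMSD.

    CA for protein; P for nucleic acids, falling back to C1' for the 5'
    residue where P is absent.  Returns None for non-polymer residues.
    """
    if polymer_class is PolymerClass.PROTEIN:
        return "CA" if residue.has_atom("CA") else None
    if polymer_class in (PolymerClass.RNA, PolymerClass.DNA):
        if residue.has_atom("P"):
            return "P"
        if residue.has_atom("C1'"):
            return "C1'"
        return None
    return None
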