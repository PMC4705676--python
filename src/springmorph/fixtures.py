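"""Synthetic toy structures with known kinematic ground truth.

Everything here is generated, idealized geometry: extended or helical
polypeptide backbones built from ideal bond lengths and angles, and a
simplified nucleotide template carrying the backbone, glycosidic and
Watson-Crick edge atoms.  The central object is the two-domain hinge
case: two rigid domains joined by a short flexible hinge, with a final
structure produced by rotating the distal domain about one hinge
torsion through a known angle, and a constructed half-way intermediate
on the same hinge path.  Because the final structure lies exactly in
the reachable torsion subspace of the declared flexibility, a morph
must be able to drive the spring energy to zero, which makes every
stage of the pipeline testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .flexibility import (
    CollisionSphere,
    FlexibleSelection,
    MobilitySpec,
    compile_mobility,
)
from .model_io import Atom, ChainModel, PolymerClass, Residue, StructureModel
from .morph_engine import GeneralizedCoordinates, forward_kinematics

__all__ = [
    "ToyMorphCase",
    "make_polymer",
    "make_two_domain_case",
    "make_indel_variant",
    "make_off_path_intermediate",
    "place_atom",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c given internal coordinates (NeRF).

    ``bond`` = |c-d|, ``angle_deg`` = angle b-c-d, ``torsion_deg`` =
    dihedral a-b-c-d.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_AA_FROM_ONE = {
    "A": "ALA", "G": "GLY", "S": "SER", "T": "THR", "V": "VAL", "L": "LEU",
    "I": "ILE", "D": "ASP", "E": "GLU", "N": "ASN", "Q": "GLN", "K": "LYS",
    "R": "ARG", "F": "PHE", "Y": "TYR", "W": "TRP", "H": "HIS", "M": "MET",
    "C": "CYS", "P": "PRO",
}

# phi/psi per geometry preset (omega always trans)
_BACKBONE_TORSIONS = {"extended": (180.0, 180.0), "helical": (-57.0, -47.0)}


def _build_protein(sequence: str, geometry: str, chain_id: str) -> ChainModel:
    phi, psi = _BACKBONE_TORSIONS[geometry]
    residues: List[Residue] = []
    serial = 0
    prev: Dict[str, np.ndarray] = {}
    for i, letter in enumerate(sequence):
        name = _AA_FROM_ONE.get(letter.upper(), "ALA")
        pos: Dict[str, np.ndarray] = {}
        if i == 0:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([1.458, 0.0, 0.0])
            # arbitrary but fixed plane for the first residue
            pos["C"] = place_atom(np.array([0.0, 1.0, 0.0]), pos["N"],
                                  pos["CA"], 1.525, 111.0, 60.0)
        else:
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  1.329, 116.2, psi)
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   1.458, 121.7, 180.0)  # omega trans
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  1.525, 111.0, phi)
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                              1.231, 120.5, psi + 180.0)
        if name != "GLY":
            pos["CB"] = place_atom(pos["N"], pos["C"], pos["CA"],
                                   1.530, 110.1, 122.5)
        atoms = []
        for aname in ("N", "CA", "C", "O", "CB"):
            if aname not in pos:
                continue
            serial += 1
            atoms.append(Atom(serial=serial, name=aname,
                              element=aname[0], coords=pos[aname]))
        residues.append(Residue(name=name, number=i + 1, atoms=atoms,
                                polymer_class=PolymerClass.PROTEIN))
        prev = pos
    return ChainModel(chain_id=chain_id, residues=residues)


def _nucleotide_template(base: str) -> List[Tuple[str, str, np.ndarray]]:
    """(atom_name, element, coords) for one idealized nucleotide.

    A planar ribose pentagon with backbone substituents and a reduced
    planar base carrying the glycosidic nitrogen and the Watson-Crick
    edge atoms; toy geometry, not a crystallographic nucleotide.
    """
    ring_names = ["O4'", "C1'", "C2'", "C3'", "C4'"]
    R = 1.31
    ring = {}
    for k, nm in enumerate(ring_names):
        ang = np.deg2rad(90.0 - 72.0 * k)
        ring[nm] = np.array([R * np.cos(ang), R * np.sin(ang), 0.0])
    out = {}

    def away(p: np.ndarray) -> np.ndarray:
        v = p.copy()
        v[2] = 0.0
        return v / np.linalg.norm(v)

    out.update(ring)
    u4 = away(ring["C4'"])
    out["C5'"] = ring["C4'"] + 1.51 * (0.8 * u4 + np.array([0, 0, 0.6]))
    u5 = np.array([0, 0, 1.0])
    out["O5'"] = out["C5'"] + 1.42 * (0.3 * u4 + 0.95 * u5) / np.linalg.norm(0.3 * u4 + 0.95 * u5)
    out["P"] = out["O5'"] + 1.59 * (0.55 * u4 + 0.83 * u5) / np.linalg.norm(0.55 * u4 + 0.83 * u5)
    u3 = away(ring["C3'"])
    out["O3'"] = ring["C3'"] + 1.42 * (0.8 * u3 - np.array([0, 0, 0.6]))
    # reduced planar base hanging off C1'
    u1 = away(ring["C1'"])
    perp = np.cross(u1, np.array([0, 0, 1.0]))
    gly = "N9" if base in ("A", "G") else "N1"
    chain_spec = {
        # name: (parent, distance, lateral-step sign)
        "A": [("N9", None), ("C4", "N9"), ("C5", "C4"), ("C6", "C5"),
              ("N1", "C6"), ("N6", "C6")],
        "G": [("N9", None), ("C4", "N9"), ("C5", "C4"), ("C6", "C5"),
              ("N1", "C6"), ("O6", "C6"), ("C2", "N1"), ("N2", "C2")],
        "C": [("N1", None), ("C2", "N1"), ("O2", "C2"), ("N3", "C2"),
              ("C4", "N3"), ("N4", "C4")],
        "U": [("N1", None), ("C2", "N1"), ("O2", "C2"), ("N3", "C2"),
              ("C4", "N3"), ("O4", "C4")],
        "T": [("N1", None), ("C2", "N1"), ("O2", "C2"), ("N3", "C2"),
              ("C4", "N3"), ("O4", "C4")],
    }[base]
    base_pos: Dict[str, np.ndarray] = {}
    zig = 1.0
    for name, parent in chain_spec:
        if parent is None:
            base_pos[name] = ring["C1'"] + 1.47 * u1
        else:
            step = 1.36 * (0.80 * u1 + 0.60 * zig * perp)
            base_pos[name] = base_pos[parent] + step
            zig = -zig
    out.update(base_pos)
    return [(nm, nm[0], xyz) for nm, xyz in out.items()]


def _build_nucleic(sequence: str, polymer_class: PolymerClass,
                   chain_id: str) -> ChainModel:
    residues: List[Residue] = []
    serial = 0
    offset = np.zeros(3)
    step: Optional[np.ndarray] = None
    for i, letter in enumerate(sequence):
        base = letter.upper()
        template = _nucleotide_template(base if base in "ACGUT" else "A")
        pos = {nm: xyz.copy() for nm, el, xyz in template}
        if step is None:
            # chain along the P -> O3' direction with a 1.6 A O3'-P link
            v = pos["O3'"] - pos["P"]
            step = v + 1.6 * v / np.linalg.norm(v)
        coords = {nm: xyz + offset for nm, xyz in pos.items()}
        atoms = []
        order = ["P", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
        extra = [nm for nm, _, _ in template if nm not in order]
        for aname in order + sorted(extra):
            if aname not in coords:
                continue
            if i == 0 and aname in ("P", "O5'"):
                continue  # 5' residue starts at C5'
            serial += 1
            atoms.append(Atom(serial=serial, name=aname, element=aname[0],
                              coords=coords[aname]))
        resname = base if polymer_class is PolymerClass.RNA else f"D{base}"
        residues.append(Residue(name=resname, number=i + 1, atoms=atoms,
                                polymer_class=polymer_class))
        offset = offset + step
    return ChainModel(chain_id=chain_id, residues=residues)


def make_polymer(n_residues: int, polymer_class="protein",
                 geometry: str = "extended", sequence: Optional[str] = None,
                 chain_id: str = "A", label: str = "toy") -> StructureModel:
    """Build an idealized polymer chain with representative + backbone atoms.

    Protein chains carry N/CA/C/O (+CB); nucleic chains carry the
    backbone, sugar, glycosidic and Watson-Crick edge atoms.  Geometry
    is 'extended' or 'helical' (protein only).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    pclass = PolymerClass(polymer_class) if not isinstance(polymer_class, PolymerClass) else polymer_class
    if sequence is None:
        sequence = ("A" * n_residues if pclass is PolymerClass.PROTEIN
                    else ("ACGU" * n_residues)[:n_residues])
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    if pclass is PolymerClass.PROTEIN:
        if geometry not in _BACKBONE_TORSIONS:
            raise ValueError(f"unknown geometry {geometry!r}")
        chain = _build_protein(sequence, geometry, chain_id)
    elif pclass in (PolymerClass.RNA, PolymerClass.DNA):
        chain = _build_nucleic(sequence, pclass, chain_id)
    else:
        raise ValueError("polymer_class must be protein, rna or dna")
    return StructureModel(chains=[chain], label=label)


ResidueKey = Tuple[str, int, str]


@dataclass
class ToyMorphCase:
    """A two-domain hinge morph problem with known ground truth.

    ``final`` is exactly ``initial`` with the distal domain rotated by
    ``true_hinge_angle`` degrees about the phi bond of the first hinge
    residue; ``intermediate`` sits on the same hinge path at half the
    angle (optionally with a small seeded coordinate jitter).
    """

    initial: StructureModel
    intermediate: StructureModel
    final: StructureModel
    hinge_residues: List[ResidueKey]
    true_hinge_angle: float
    seed: int
    mobility: MobilitySpec
    axis_point: np.ndarray
    axis_dir: np.ndarray
    domain1: List[ResidueKey]
    domain2: List[ResidueKey]
    interface_sphere: CollisionSphere


def _rotated_copy(model: StructureModel, topology, joint_index: int,
                  angle_rad: float, label: str) -> StructureModel:
    q = GeneralizedCoordinates.identity(topology)
    q.torsions[joint_index] = angle_rad
    coords = forward_kinematics(topology, q, model.coords_array())
    out = model.copy(label=label)
    out.set_coords(coords)
    return out


def make_two_domain_case(domain_size: int = 8, hinge_length: int = 2,
                         theta_degrees: float = 60.0, seed: int = 0,
                         jitter: float = 0.0) -> ToyMorphCase:
    """Two rigid domains joined by a flexible hinge, rotated by theta.

    The interface collision sphere is constructed geometrically: it is
    centered on the chord midpoint of the most distal Calpha and sized
    to half that point's clearance from the true rotational sweep, so
    the straight-line interpolation between the endpoints passes
    through the sphere while the hinge-path trajectory never enters it.
    """
    if not (0.0 < theta_degrees < 180.0):
        raise ValueError("theta must be in (0, 180) degrees")
    n = 2 * domain_size + hinge_length
    initial = make_polymer(n, "protein", "extended", label="toy_initial")
    chain_id = initial.chains[0].chain_id
    h_first = domain_size + 1
    h_last = domain_size + hinge_length
    mobility = MobilitySpec(flexible_selections=[
        FlexibleSelection(chain_id, h_first, h_last)])
    topology = compile_mobility(initial, mobility)
    drive_label = f"{chain_id}:{h_first}:N-CA"
    joint_index = next(i for i, j in enumerate(topology.joints)
                       if j.label == drive_label)
    theta = np.deg2rad(theta_degrees)
    final = _rotated_copy(initial, topology, joint_index, theta, "toy_final")
    intermediate = _rotated_copy(initial, topology, joint_index, theta / 2.0,
                                 "toy_intermediate")
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        c = intermediate.coords_array()
        intermediate.set_coords(c + rng.normal(0.0, jitter, c.shape))

    joint = topology.joints[joint_index]
    ref = initial.coords_array()
    axis_point = ref[joint.axis_a].copy()
    axis_dir = ref[joint.axis_b] - ref[joint.axis_a]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)

    hinge = [(chain_id, num, "") for num in range(h_first, h_last + 1)]
    domain1 = [(chain_id, num, "") for num in range(1, domain_size + 1)]
    domain2 = [(chain_id, num, "") for num in range(h_last + 1, n + 1)]

    sphere = _interface_sphere(initial, final, topology, joint_index,
                               axis_point, axis_dir, theta, chain_id, n)
    return ToyMorphCase(
        initial=initial, intermediate=intermediate, final=final,
        hinge_residues=hinge, true_hinge_angle=theta_degrees, seed=seed,
        mobility=mobility, axis_point=axis_point, axis_dir=axis_dir,
        domain1=domain1, domain2=domain2, interface_sphere=sphere)


def _interface_sphere(initial: StructureModel, final: StructureModel,
                      topology, joint_index: int, axis_point: np.ndarray,
                      axis_dir: np.ndarray, theta: float, chain_id: str,
                      last_residue: int) -> CollisionSphere:
    index_map = initial.atom_index_map()
    probe = index_map[(chain_id, last_residue, "", "CA")]
    ref = initial.coords_array()
    fin = final.coords_array()
    center = 0.5 * (ref[probe] + fin[probe])
    # clearance of the chord midpoint from the true rotational sweep
    joint = topology.joints[joint_index]
    angles = np.linspace(0.0, theta, 181)
    dmin = np.inf
    from scipy.spatial.transform import Rotation as _R
    moving = joint.rotating_atoms
    for ang in angles:
        rot = _R.from_rotvec(axis_dir * ang)
        pts = rot.apply(ref[moving] - axis_point) + axis_point
        dmin = min(dmin, float(np.min(np.linalg.norm(pts - center, axis=1))))
    radius = max(0.5 * dmin, 0.2)
    return CollisionSphere(radius=radius, center_point=center, stiffness=100.0)


def make_off_path_intermediate(case: ToyMorphCase,
                               tilt_degrees: float = 8.0) -> StructureModel:
    """A harder reference intermediate lying off the hinge path.

    The half-way structure is additionally rotated about an axis
    perpendicular to the hinge axis, emulating an experimental
    intermediate that deviates from the direct interpolation pathway;
    a morph is then expected to approach it more closely than either
    endpoint rather than to recapitulate it exactly.
    """
    perp = np.cross(case.axis_dir, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(case.axis_dir, np.array([0.0, 1.0, 0.0]))
    perp /= np.linalg.norm(perp)
    from scipy.spatial.transform import Rotation as _R
    rot = _R.from_rotvec(perp * np.deg2rad(tilt_degrees))
    out = case.intermediate.copy(label="toy_intermediate_offpath")
    index_map = out.atom_index_map()
    coords = out.coords_array()
    moving = [index_map[k + (a.name,)]
              for k in case.domain2
              for a in out.chain(k[0]).residue(k[1], k[2]).atoms]
    coords[moving] = rot.apply(coords[moving] - case.axis_point) + case.axis_point
    out.set_coords(coords)
    return out


def make_indel_variant(model: StructureModel,
                       delete_ranges: Sequence[Tuple[str, int, int]],
                       seed: Optional[int] = None) -> StructureModel:
    """Copy of ``model`` minus the given residue ranges (author numbering kept)."""
    out = model.copy(label=(model.label or "model") + "_indel")
    for chain_id, first, last in delete_ranges:
        chain = out.chain(chain_id)
        kept = [r for r in chain.residues if not (first <= r.number <= last)]
        if not kept:
            raise ValueError(f"deletion removes every residue of chain {chain_id}")
        chain.residues = kept
    return out
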