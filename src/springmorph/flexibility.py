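"""Mobility declarations and their compiled kinematic topology.

A :class:`MobilitySpec` says which residues are flexible, which segments
are welded together, where collision spheres sit, and how wide the
physics zone is.  :func:`compile_mobility` turns it into a
:class:`KinematicTopology`: a partition of all atoms into rigid bodies
connected by rotatable-bond torsion joints, forming a forest (one free
6-DOF root body per connected component).

Flexibility is torsional only: a flexible protein residue contributes
its phi and psi backbone torsions (omega stays planar); a flexible
nucleotide contributes the backbone torsions alpha, beta, gamma,
epsilon, zeta and the glycosidic chi, with the sugar ring kept rigid.
Side chains ride rigidly with their residue unless an explicit
single-bond selection names a side-chain bond.  Because motion is
restricted to rotations about existing covalent bonds, bond lengths and
angles are preserved by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model_io import PolymerClass, StructureModel

__all__ = [
    "FlexibleSelection",
    "Segment",
    "CollisionSphere",
    "MobilitySpec",
    "Joint",
    "KinematicTopology",
    "compile_mobility",
    "physics_zone_atoms",
    "build_bond_graph",
]

# Single-bond covalent radii (angstrom) used to infer the bond graph.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "MG": 1.41, "ZN": 1.22, "FE": 1.32, "K": 2.03, "NA": 1.66, "CA": 1.76,
}
_BOND_TOLERANCE = 1.25  # bonded if d < (r_i + r_j) * tolerance

PROTEIN_TORSION_BONDS = [("N", "CA"), ("CA", "C")]  # phi, psi
NUCLEIC_TORSION_BONDS = [
    ("P", "O5'"),    # alpha
    ("O5'", "C5'"),  # beta
    ("C5'", "C4'"),  # gamma
    ("C3'", "O3'"),  # epsilon
]
GLYCOSIDIC_ATOMS = ("N9", "N1")  # purine, pyrimidine


@dataclass
class FlexibleSelection:
    """A residue range granted torsional freedom.

    level 'residue-torsions' frees the standard backbone torsions of
    every residue in [first, last]; level 'single-bond' frees only the
    named bonds (list of (residue_number, atom_a, atom_b)).
    """

    chain_id: str
    first: int
    last: int
    level: str = "residue-torsions"
    bonds: List[Tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in ("residue-torsions", "single-bond"):
            raise ValueError(f"unknown flexibility level {self.level!r}")
        if self.first > self.last:
            raise ValueError("selection first > last")


@dataclass
class Segment:
    """A residue range (whole chain when first/last are None)."""

    chain_id: str
    first: Optional[int] = None
    last: Optional[int] = None

    def contains(self, chain_id: str, number: int) -> bool:
        if chain_id != self.chain_id:
            return False
        if self.first is not None and number < self.first:
            return False
        if self.last is not None and number > self.last:
            return False
        return True


@dataclass
class CollisionSphere:
    """A repulsive sphere placed at a hinge or interface.

    The center is either an atom reference (chain, residue number, atom
    name) that moves with its body, or a fixed laboratory-frame point.
    Atoms outside the sphere's own body are pushed out harmonically.
    """

    radius: float
    stiffness: float = 100.0  # kJ/mol/A^2
    center_atom: Optional[Tuple[str, int, str]] = None  # (chain, resnum, atom)
    center_point: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("collision sphere radius must be > 0")
        if self.stiffness < 0:
            raise ValueError("collision sphere stiffness must be >= 0")
        if (self.center_atom is None) == (self.center_point is None):
            raise ValueError("specify exactly one of center_atom / center_point")
        if self.center_point is not None:
            self.center_point = np.asarray(self.center_point, dtype=float).reshape(3)


@dataclass
class MobilitySpec:
    """User flexibility declaration; everything not selected is rigid."""

    flexible_selections: List[FlexibleSelection] = field(default_factory=list)
    welds: List[Tuple[Segment, Segment]] = field(default_factory=list)
    collision_spheres: List[CollisionSphere] = field(default_factory=list)
    physics_zone_radius: float = 10.0  # angstrom

    def flexible_residue_keys(self, model: StructureModel) -> List[Tuple[str, int, str]]:
        """All (chain, number, icode) covered by residue-level selections."""
        keys = []
        seen = set()
        for sel in self.flexible_selections:
            chain = model.chain(sel.chain_id)
            found_any = False
            for r in chain.residues:
                if sel.first <= r.number <= sel.last:
                    found_any = True
                    k = (chain.chain_id, r.number, r.insertion_code)
                    if k not in seen:
                        seen.add(k)
                        keys.append(k)
            if not found_any:
                raise ValueError(
                    f"flexible selection {sel.chain_id}:{sel.first}-{sel.last} "
                    "matches no residues"
                )
        return keys


@dataclass
class Joint:
    """A torsion joint about the covalent bond axis_a -> axis_b.

    ``rotating_atoms`` is exactly the atom set distal to the bond within
    the joint's connected component; ``parent_body``/``child_body`` are
    body indices on either side of the bond.
    """

    axis_a: int
    axis_b: int
    rotating_atoms: np.ndarray
    parent_body: int
    child_body: int
    label: str = ""


@dataclass
class KinematicTopology:
    n_atoms: int
    bodies: List[np.ndarray]                 # atom indices per body
    atom_body: np.ndarray                    # atom index -> body index
    joints: List[Joint]                      # in root-outward application order
    root_bodies: List[int]                   # one free 6-DOF body per component
    component_atoms: List[np.ndarray]        # atom indices per component
    atom_component: np.ndarray
    flexible_atoms: np.ndarray               # atoms of flexible residues
    bond_graph: "coo_matrix"

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)

    @property
    def n_joints(self) -> int:
        return len(self.joints)


def _flatten(model: StructureModel):
    """Flat atom table: coords, element, and (chain, resnum, icode, name) keys."""
    coords, elements, keys, res_of_atom = [], [], [], []
    residues = []  # (chain_id, resnum, icode, pclass, [atom indices])
    idx = 0
    for chain in model.chains:
        pclass = chain.polymer_class
        for res in chain.residues:
            atom_idx = []
            for a in res.atoms:
                coords.append(a.coords)
                elements.append((a.element or "C").upper())
                keys.append((chain.chain_id, res.number, res.insertion_code, a.name))
                res_of_atom.append(len(residues))
                atom_idx.append(idx)
                idx += 1
            residues.append((chain.chain_id, res.number, res.insertion_code,
                             res.polymer_class, atom_idx, res))
    return (np.asarray(coords, dtype=float), elements, keys,
            np.asarray(res_of_atom), residues)


def build_bond_graph(model: StructureModel) -> coo_matrix:
    """Covalent bond graph inferred from interatomic distances.

    Two heavy atoms are bonded when their distance is below the sum of
    covalent radii times 1.25.  A KD-tree keeps this O(n log n).
    """
    coords, elements, _, _, _ = _flatten(model)
    n = len(coords)
    if n == 0:
        raise ValueError("empty model")
    radii = np.array([COVALENT_RADII.get(e, 0.77) for e in elements])
    max_cut = 2.0 * radii.max() * _BOND_TOLERANCE
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    rows, cols = [], []
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        cut = (radii[pairs[:, 0]] + radii[pairs[:, 1]]) * _BOND_TOLERANCE
        bonded = pairs[d < cut]
        rows = bonded[:, 0].tolist() + bonded[:, 1].tolist()
        cols = bonded[:, 1].tolist() + bonded[:, 0].tolist()
    data = np.ones(len(rows), dtype=np.int8)
    return coo_matrix((data, (rows, cols)), shape=(n, n))


def _rotatable_bonds(model: StructureModel, spec: MobilitySpec,
                     key_to_idx: Dict[Tuple[str, int, str, str], int]) -> List[Tuple[int, int, str]]:
    """Global-index rotatable bonds implied by the flexibility selections."""
    bonds: List[Tuple[int, int, str]] = []
    seen: Set[Tuple[int, int]] = set()

    def add(i: Optional[int], j: Optional[int], label: str) -> None:
        if i is None or j is None:
            return
        pair = (min(i, j), max(i, j))
        if pair in seen:
            return
        seen.add(pair)
        bonds.append((i, j, label))

    for sel in spec.flexible_selections:
        chain = model.chain(sel.chain_id)
        pclass = chain.polymer_class
        if sel.level == "single-bond":
            for resnum, a_name, b_name in sel.bonds:
                i = key_to_idx.get((sel.chain_id, resnum, "", a_name))
                j = key_to_idx.get((sel.chain_id, resnum, "", b_name))
                if i is None or j is None:
                    raise ValueError(
                        f"single-bond selection {sel.chain_id}:{resnum} "
                        f"{a_name}-{b_name}: atom not found"
                    )
                add(i, j, f"{sel.chain_id}:{resnum}:{a_name}-{b_name}")
            continue
        for pos, res in enumerate(chain.residues):
            if not (sel.first <= res.number <= sel.last):
                continue
            ckey = (sel.chain_id, res.number, res.insertion_code)
            if pclass is PolymerClass.PROTEIN:
                for a_name, b_name in PROTEIN_TORSION_BONDS:
                    i = key_to_idx.get(ckey + (a_name,))
                    j = key_to_idx.get(ckey + (b_name,))
                    add(i, j, f"{sel.chain_id}:{res.number}:{a_name}-{b_name}")
            elif pclass in (PolymerClass.RNA, PolymerClass.DNA):
                for a_name, b_name in NUCLEIC_TORSION_BONDS:
                    i = key_to_idx.get(ckey + (a_name,))
                    j = key_to_idx.get(ckey + (b_name,))
                    add(i, j, f"{sel.chain_id}:{res.number}:{a_name}-{b_name}")
                # zeta: O3'(i) - P(i+1)
                if pos + 1 < len(chain.residues):
                    nxt = chain.residues[pos + 1]
                    i = key_to_idx.get(ckey + ("O3'",))
                    j = key_to_idx.get((sel.chain_id, nxt.number, nxt.insertion_code, "P"))
                    add(i, j, f"{sel.chain_id}:{res.number}:zeta")
                # chi: C1' - N9/N1
                i = key_to_idx.get(ckey + ("C1'",))
                for nname in GLYCOSIDIC_ATOMS:
                    j = key_to_idx.get(ckey + (nname,))
                    if j is not None:
                        add(i, j, f"{sel.chain_id}:{res.number}:chi")
                        break
    return bonds


def compile_mobility(model: StructureModel, spec: MobilitySpec) -> KinematicTopology:
    """Compile a mobility declaration into a rigid-body/torsion tree.

    Rigid stretches collapse into single bodies; each rotatable bond
    becomes a torsion joint; welded segments merge into one body; every
    disconnected component gets one free root body.  Deterministic:
    identical inputs give identical topologies.
    """
    coords, elements, keys, res_of_atom, residues = _flatten(model)
    n = len(coords)
    key_to_idx = {k: i for i, k in enumerate(keys)}
    bond_graph = build_bond_graph(model)

    # validate flexible selections and collect flexible residue atoms
    flex_keys = set(spec.flexible_residue_keys(model))
    flex_atoms = np.array(sorted(
        i for i, k in enumerate(keys) if (k[0], k[1], k[2]) in flex_keys
    ), dtype=int)

    rot_bonds = _rotatable_bonds(model, spec, key_to_idx)

    # remove rotatable bond edges -> rigid bodies are the remaining components
    rot_set = {(min(i, j), max(i, j)) for i, j, _ in rot_bonds}
    rows, cols = bond_graph.row, bond_graph.col
    keep = np.array([
        (min(a, b), max(a, b)) not in rot_set for a, b in zip(rows, cols)
    ], dtype=bool) if len(rows) else np.zeros(0, dtype=bool)
    stripped = coo_matrix(
        (np.ones(int(keep.sum()), dtype=np.int8), (rows[keep], cols[keep])),
        shape=(n, n))
    n_bodies, atom_body = connected_components(stripped, directed=False)

    # welds: union bodies
    parent = list(range(n_bodies))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    def segment_body(seg: Segment) -> int:
        for i, k in enumerate(keys):
            if seg.contains(k[0], k[1]):
                return int(atom_body[i])
        raise ValueError(f"weld segment {seg} matches no atoms")

    weld_edges = []
    for seg_a, seg_b in spec.welds:
        ba, bb = segment_body(seg_a), segment_body(seg_b)
        weld_edges.append((ba, bb))

    # joints between (pre-weld) bodies; drop degenerate in-ring bonds
    joint_entries = []
    for i, j, label in rot_bonds:
        if atom_body[i] == atom_body[j]:
            warnings.warn(
                f"rotatable bond {label} lies in a ring; joint dropped")
            continue
        joint_entries.append((i, j, label))

    for ba, bb in weld_edges:
        # a weld must not close a kinematic loop through existing joints
        union(ba, bb)
    # check welds against joint graph below (cycle detection on merged bodies)

    # relabel merged bodies compactly, deterministic by smallest atom index
    merged_of = np.array([find(int(b)) for b in atom_body])
    uniq = []
    seen: Dict[int, int] = {}
    for a in range(n):
        m = int(merged_of[a])
        if m not in seen:
            seen[m] = len(uniq)
            uniq.append(m)
    atom_body = np.array([seen[int(m)] for m in merged_of])
    n_bodies = len(uniq)
    bodies = [np.flatnonzero(atom_body == b) for b in range(n_bodies)]

    # body-level joint graph; must be a forest
    adj: Dict[int, List[Tuple[int, int]]] = {b: [] for b in range(n_bodies)}
    for jidx, (i, j, label) in enumerate(joint_entries):
        ba, bb = int(atom_body[i]), int(atom_body[j])
        if ba == bb:
            raise ValueError(
                f"weld merges both sides of rotatable bond {label} "
                "(kinematic loop)")
        adj[ba].append((bb, jidx))
        adj[bb].append((ba, jidx))

    visited = np.zeros(n_bodies, dtype=bool)
    joints: List[Joint] = []
    root_bodies: List[int] = []
    component_atoms: List[np.ndarray] = []
    atom_component = np.full(n, -1, dtype=int)
    body_order = np.argsort([b[0] for b in bodies])  # roots by first atom

    for root in body_order:
        root = int(root)
        if visited[root]:
            continue
        root_bodies.append(root)
        comp_bodies = [root]
        visited[root] = True
        # BFS over joints, recording parent->child orientation
        frontier = [root]
        comp_joint_idx: List[Tuple[int, int, int]] = []  # (jidx, parent, child)
        used_edges: Set[Tuple[int, int]] = set()
        while frontier:
            nxt = []
            for b in frontier:
                for nb, jidx in sorted(adj[b]):
                    if visited[nb]:
                        if (min(b, nb), max(b, nb), jidx) in used_edges:
                            continue
                        raise ValueError(
                            "kinematic loop detected (weld or duplicate "
                            "rotatable bond creates a cycle)")
                    visited[nb] = True
                    used_edges.add((min(b, nb), max(b, nb), jidx))
                    comp_bodies.append(nb)
                    comp_joint_idx.append((jidx, b, nb))
                    nxt.append(nb)
            frontier = nxt
        comp_atoms = np.sort(np.concatenate([bodies[b] for b in comp_bodies]))
        component_atoms.append(comp_atoms)
        atom_component[comp_atoms] = len(component_atoms) - 1

        # rotating set of each joint = atoms of the child-side subtree
        children: Dict[int, List[Tuple[int, int]]] = {}
        for jidx, pb, cb in comp_joint_idx:
            children.setdefault(pb, []).append((cb, jidx))

        def subtree_atoms(body: int) -> np.ndarray:
            stack, acc = [body], []
            while stack:
                b = stack.pop()
                acc.append(bodies[b])
                for cb, _ in children.get(b, ()):  # noqa: B023
                    stack.append(cb)
            return np.sort(np.concatenate(acc))

        for jidx, pb, cb in comp_joint_idx:
            i, j, label = joint_entries[jidx]
            # orient axis from parent-side atom to child-side atom
            if int(atom_body[i]) == pb:
                a_atom, b_atom = i, j
            else:
                a_atom, b_atom = j, i
            joints.append(Joint(
                axis_a=a_atom, axis_b=b_atom,
                rotating_atoms=subtree_atoms(cb),
                parent_body=pb, child_body=cb, label=label,
            ))

    # partition sanity
    assert sum(len(b) for b in bodies) == n

    return KinematicTopology(
        n_atoms=n,
        bodies=bodies,
        atom_body=atom_body,
        joints=joints,
        root_bodies=root_bodies,
        component_atoms=component_atoms,
        atom_component=atom_component,
        flexible_atoms=flex_atoms,
        bond_graph=bond_graph,
    )


def physics_zone_atoms(model: StructureModel, spec: MobilitySpec,
                       radius: Optional[float] = None) -> np.ndarray:
    """Atoms within ``radius`` of any flexible-residue atom (inclusive).

    This is the neighborhood in which the nonbonded term is evaluated;
    the default radius is 10 angstroms around all flexible residues.
    """
    r = spec.physics_zone_radius if radius is None else radius
    if r < 0:
        raise ValueError("physics zone radius must be >= 0")
    coords, _, keys, _, _ = _flatten(model)
    flex_keys = set(spec.flexible_residue_keys(model))
    flex_idx = np.array([i for i, k in enumerate(keys)
                         if (k[0], k[1], k[2]) in flex_keys], dtype=int)
    if len(flex_idx) == 0:
        return flex_idx
    if r == 0:
        return np.sort(flex_idx)
    tree = cKDTree(coords)
    hits = tree.query_ball_point(coords[flex_idx], r)
    zone: Set[int] = set(flex_idx.tolist())
    for h in hits:
        zone.update(h)
    return np.array(sorted(zone), dtype=int)
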