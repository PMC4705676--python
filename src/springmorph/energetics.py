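"""The morph potential and its exact Cartesian gradient.

Four terms, all harmonic or soft-repulsive, all in kJ/mol with
coordinates in angstroms:

* threading springs pulling mobile atoms to their target points,
  E = sum (1/2) F w |x - t|^2;
* collision spheres repelling foreign atoms that penetrate,
  E = sum (1/2) k (R - r)^2 for r < R;
* a soft-sphere nonbonded repulsion evaluated only inside the physics
  zone, E = sum eps (1 - r/sigma_ij)^2 for r < sigma_ij, with sigma
  from per-element radius sums; pairs within the same rigid body or
  closer than four bonds are excluded;
* explicit distance restraints (e.g. Watson-Crick pairs),
  E = sum (1/2) k (r - d0)^2.

Covalent geometry needs no energy term: torsion-only kinematics
preserves bond lengths and angles exactly, so the potential only has to
drive the alignment and keep moving parts from interpenetrating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .correspondence import DistanceRestraint, SpringSet
from .flexibility import KinematicTopology, MobilitySpec
from .model_io import StructureModel

__all__ = [
    "EnergyReport",
    "CompiledSprings",
    "CompiledSpheres",
    "NonbondedParams",
    "CompiledNonbonded",
    "CompiledRestraints",
    "MorphPotential",
    "compile_potential",
    "spring_energy",
    "collision_energy",
    "nonbonded_energy",
    "restraint_energy",
    "total_energy",
]

# Nonbonded contact radii per element (angstrom); sigma_ij = R_i + R_j.
CONTACT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
                 "H": 1.20, "MG": 1.73, "ZN": 1.39, "K": 2.75, "NA": 2.27}
_DEFAULT_CONTACT_RADIUS = 1.70


@dataclass
class EnergyReport:
    spring: float = 0.0
    collision: float = 0.0
    nonbonded: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return self.spring + self.collision + self.nonbonded + self.restraint

    def as_dict(self) -> Dict[str, float]:
        return {"spring": self.spring, "collision": self.collision,
                "nonbonded": self.nonbonded, "restraint": self.restraint,
                "total": self.total}


@dataclass
class CompiledSprings:
    atom_idx: np.ndarray        # (n_springs,)
    targets: np.ndarray         # (n_springs, 3)
    force_constant: float
    weights: np.ndarray


@dataclass
class CompiledSpheres:
    center_atom: List[Optional[int]]      # flat atom index or None
    center_point: List[Optional[np.ndarray]]
    radius: np.ndarray
    stiffness: np.ndarray
    own_body: np.ndarray                  # -1 for fixed-point spheres


@dataclass
class NonbondedParams:
    epsilon: float = 10.0       # kJ/mol
    bonded_exclusion: int = 3   # exclude pairs <= this many bonds apart


@dataclass
class CompiledNonbonded:
    zone: np.ndarray            # flat atom indices inside the physics zone
    sigma: np.ndarray           # per-zone-atom contact radius
    epsilon: float
    excluded: Set[Tuple[int, int]]   # sorted flat-index pairs to skip
    max_cutoff: float


@dataclass
class CompiledRestraints:
    idx_i: np.ndarray
    idx_j: np.ndarray
    target: np.ndarray
    stiffness: np.ndarray


@dataclass
class MorphPotential:
    """All compiled energy terms for one morph stage."""

    n_atoms: int
    atom_body: np.ndarray
    springs: Optional[CompiledSprings] = None
    spheres: Optional[CompiledSpheres] = None
    nonbonded: Optional[CompiledNonbonded] = None
    restraints: Optional[CompiledRestraints] = None


def compile_potential(model: StructureModel, topology: KinematicTopology,
                      spring_set: Optional[SpringSet],
                      spec: MobilitySpec,
                      zone_atoms: Optional[np.ndarray] = None,
                      restraints: Sequence[DistanceRestraint] = (),
                      nonbonded_params: Optional[NonbondedParams] = None,
                      ) -> MorphPotential:
    """Resolve symbolic atom references into flat-index energy terms."""
    index_map = model.atom_index_map()
    n = model.n_atoms

    springs = None
    if spring_set is not None and len(spring_set):
        idx = np.array([index_map[ref] for ref in spring_set.atom_refs])
        springs = CompiledSprings(
            atom_idx=idx, targets=spring_set.targets.copy(),
            force_constant=spring_set.force_constant,
            weights=np.asarray(spring_set.weights, dtype=float))

    spheres = None
    if spec.collision_spheres:
        c_atom, c_point, rad, stiff, own = [], [], [], [], []
        for s in spec.collision_spheres:
            if s.center_atom is not None:
                chain, num, name = s.center_atom
                ai = index_map[(chain, num, "", name)]
                c_atom.append(ai)
                c_point.append(None)
                own.append(int(topology.atom_body[ai]))
            else:
                c_atom.append(None)
                c_point.append(np.asarray(s.center_point, dtype=float))
                own.append(-1)
            rad.append(s.radius)
            stiff.append(s.stiffness)
        spheres = CompiledSpheres(center_atom=c_atom, center_point=c_point,
                                  radius=np.array(rad), stiffness=np.array(stiff),
                                  own_body=np.array(own))

    nb = None
    params = nonbonded_params or NonbondedParams()
    if zone_atoms is not None and len(zone_atoms) > 1:
        elements = [(a.element or "C").upper() for _, _, a in model.iter_atoms()]
        sigma = np.array([CONTACT_RADII.get(elements[i], _DEFAULT_CONTACT_RADIUS)
                          for i in zone_atoms])
        excluded = _bonded_exclusions(topology, zone_atoms,
                                      params.bonded_exclusion)
        nb = CompiledNonbonded(zone=np.asarray(zone_atoms, dtype=int),
                               sigma=sigma, epsilon=params.epsilon,
                               excluded=excluded,
                               max_cutoff=float(2 * sigma.max()))

    rest = None
    if restraints:
        rest = CompiledRestraints(
            idx_i=np.array([index_map[r.atom_i] for r in restraints]),
            idx_j=np.array([index_map[r.atom_j] for r in restraints]),
            target=np.array([r.target for r in restraints]),
            stiffness=np.array([r.stiffness for r in restraints]))

    return MorphPotential(n_atoms=n, atom_body=topology.atom_body,
                          springs=springs, spheres=spheres, nonbonded=nb,
                          restraints=rest)


def _bonded_exclusions(topology: KinematicTopology, zone: np.ndarray,
                       max_bonds: int) -> Set[Tuple[int, int]]:
    """Pairs of zone atoms within ``max_bonds`` covalent bonds."""
    graph = topology.bond_graph.tocsr()
    zone_set = set(int(i) for i in zone)
    excluded: Set[Tuple[int, int]] = set()
    for start in zone:
        start = int(start)
        frontier = {start}
        seen = {start}
        for _ in range(max_bonds):
            nxt = set()
            for a in frontier:
                nxt.update(graph.indices[graph.indptr[a]:graph.indptr[a + 1]].tolist())
            nxt -= seen
            seen |= nxt
            frontier = nxt
        for other in seen:
            if other != start and other in zone_set:
                excluded.add((min(start, other), max(start, other)))
    return excluded


def spring_energy(coords: np.ndarray, springs: CompiledSprings
                  ) -> Tuple[float, np.ndarray]:
    """E = sum (1/2) F w |x - t|^2 with its exact gradient."""
    grad = np.zeros_like(coords)
    d = coords[springs.atom_idx] - springs.targets
    kw = springs.force_constant * springs.weights
    energy = 0.5 * float(np.sum(kw * np.sum(d * d, axis=1)))
    np.add.at(grad, springs.atom_idx, kw[:, None] * d)
    return energy, grad


def collision_energy(coords: np.ndarray, spheres: CompiledSpheres,
                     atom_body: np.ndarray) -> Tuple[float, np.ndarray]:
    """Harmonic repulsion of foreign atoms penetrating each sphere.

    An atom belonging to the sphere's own body (or serving as its
    center) feels nothing; the gradient includes the reaction on a
    moving center atom.
    """
    energy = 0.0
    grad = np.zeros_like(coords)
    n = len(coords)
    for k in range(len(spheres.radius)):
        R = spheres.radius[k]
        stiff = spheres.stiffness[k]
        ci = spheres.center_atom[k]
        center = coords[ci] if ci is not None else spheres.center_point[k]
        mask = np.ones(n, dtype=bool)
        if spheres.own_body[k] >= 0:
            mask &= atom_body != spheres.own_body[k]
        if ci is not None:
            mask[ci] = False
        dx = coords[mask] - center
        r = np.linalg.norm(dx, axis=1)
        inside = r < R
        if not inside.any():
            continue
        r_in = np.maximum(r[inside], 1e-12)
        pen = R - r_in
        energy += 0.5 * stiff * float(np.sum(pen * pen))
        # dE/dx = -k (R - r) * (x - c)/r  (pushes the atom outward)
        f = (-stiff * pen / r_in)[:, None] * dx[inside]
        idx = np.flatnonzero(mask)[inside]
        np.add.at(grad, idx, f)
        if ci is not None:
            grad[ci] -= f.sum(axis=0)
    return energy, grad


def nonbonded_energy(coords: np.ndarray, nb: CompiledNonbonded,
                     atom_body: np.ndarray) -> Tuple[float, np.ndarray]:
    """Soft-sphere repulsion over physics-zone atom pairs.

    E = eps (1 - r/sigma_ij)^2 for r < sigma_ij; pairs in the same
    rigid body or within the bonded-exclusion distance are skipped.
    Pair search uses a KD-tree at the current coordinates.
    """
    energy = 0.0
    grad = np.zeros_like(coords)
    zc = coords[nb.zone]
    tree = cKDTree(zc)
    pairs = tree.query_pairs(nb.max_cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return energy, grad
    gi = nb.zone[pairs[:, 0]]
    gj = nb.zone[pairs[:, 1]]
    keep = atom_body[gi] != atom_body[gj]
    if nb.excluded:
        lo = np.minimum(gi, gj)
        hi = np.maximum(gi, gj)
        keep &= np.array([(int(a), int(b)) not in nb.excluded
                          for a, b in zip(lo, hi)])
    pairs = pairs[keep]
    gi, gj = gi[keep], gj[keep]
    if len(pairs) == 0:
        return energy, grad
    sigma = nb.sigma[pairs[:, 0]] + nb.sigma[pairs[:, 1]]
    dx = coords[gi] - coords[gj]
    r = np.linalg.norm(dx, axis=1)
    inside = r < sigma
    if not inside.any():
        return energy, grad
    r_in = np.maximum(r[inside], 1e-12)
    s_in = sigma[inside]
    u = 1.0 - r_in / s_in
    energy = nb.epsilon * float(np.sum(u * u))
    dEdr = -2.0 * nb.epsilon * u / s_in
    f = (dEdr / r_in)[:, None] * dx[inside]
    np.add.at(grad, gi[inside], f)
    np.add.at(grad, gj[inside], -f)
    return energy, grad


def restraint_energy(coords: np.ndarray, rest: CompiledRestraints
                     ) -> Tuple[float, np.ndarray]:
    """E = sum (1/2) k (r - d0)^2 over explicit distance restraints."""
    grad = np.zeros_like(coords)
    dx = coords[rest.idx_i] - coords[rest.idx_j]
    r = np.maximum(np.linalg.norm(dx, axis=1), 1e-12)
    dev = r - rest.target
    energy = 0.5 * float(np.sum(rest.stiffness * dev * dev))
    f = (rest.stiffness * dev / r)[:, None] * dx
    np.add.at(grad, rest.idx_i, f)
    np.add.at(grad, rest.idx_j, -f)
    return energy, grad


def total_energy(coords: np.ndarray, potential: MorphPotential
                 ) -> Tuple[EnergyReport, np.ndarray]:
    """Term-wise energy report and the summed Cartesian gradient."""
    report = EnergyReport()
    grad = np.zeros_like(coords)
    if potential.springs is not None:
        e, g = spring_energy(coords, potential.springs)
        report.spring = e
        grad += g
    if potential.spheres is not None:
        e, g = collision_energy(coords, potential.spheres, potential.atom_body)
        report.collision = e
        grad += g
    if potential.nonbonded is not None:
        e, g = nonbonded_energy(coords, potential.nonbonded, potential.atom_body)
        report.nonbonded = e
        grad += g
    if potential.restraints is not None:
        e, g = restraint_energy(coords, potential.restraints)
        report.restraint = e
        grad += g
    return report, grad
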