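"""Spring-driven morphing by energy descent in internal coordinates.

The state of the system is a set of generalized coordinates: one free
6-DOF pose (translation + quaternion) per kinematically disconnected
component, plus one angle per torsion joint.  Forward kinematics maps
this state to Cartesian coordinates while preserving every rigid body's
internal geometry bit-for-bit, so covalent geometry cannot degrade no
matter how far the morph travels.

The driver is monotone energy descent on the total morph potential,
projected to generalized coordinates by the exact chain rule:
conjugate-gradient directions preconditioned by the spring term's
diagonal curvature, an Armijo backtracking line search, and a trust cap
on the per-step atomic displacement so the trajectory is a smooth
quasi-static path.  Accepted-step energies never increase (noise off),
which makes the frame-wise energy-plateau stop rule well defined: the
run converges at the first frame ending a window of consecutive
frame-to-frame energy differences all below the threshold (defaults:
50 kJ/mol over 5 frames).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .correspondence import DistanceRestraint, build_springs
from .energetics import (
    EnergyReport,
    MorphPotential,
    NonbondedParams,
    compile_potential,
    total_energy,
)
from .flexibility import KinematicTopology, MobilitySpec, compile_mobility, physics_zone_atoms
from .geometry_metrics import apply_transform, kabsch_superpose, residue_correspondence, representative_coords
from .model_io import StructureModel, Trajectory

__all__ = [
    "GeneralizedCoordinates",
    "MorphConfig",
    "MorphResult",
    "StageSpec",
    "forward_kinematics",
    "generalized_gradient",
    "run_morph",
    "check_convergence",
    "chain_morphs",
    "linear_morph",
    "prealign_final",
]


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(theta + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


@dataclass
class GeneralizedCoordinates:
    """Reduced-coordinate state: root poses plus joint torsions.

    Torsions are offsets (radians) from the reference geometry; root
    rotations act about each component's reference centroid.
    """

    translations: np.ndarray          # (n_components, 3)
    rotations: List[Rotation]         # one per component
    torsions: np.ndarray              # (n_joints,), wrapped to (-pi, pi]

    @classmethod
    def identity(cls, topology: KinematicTopology) -> "GeneralizedCoordinates":
        n_comp = len(topology.component_atoms)
        return cls(translations=np.zeros((n_comp, 3)),
                   rotations=[Rotation.identity() for _ in range(n_comp)],
                   torsions=np.zeros(topology.n_joints))

    def stepped(self, direction: "GeneralizedGradient", alpha: float
                ) -> "GeneralizedCoordinates":
        """Move along ``direction`` by step ``alpha`` (exp-map for roots)."""
        rots = []
        for k, r in enumerate(self.rotations):
            dw = alpha * direction.rotations[k]
            rots.append(Rotation.from_rotvec(dw) * r)
        return GeneralizedCoordinates(
            translations=self.translations + alpha * direction.translations,
            rotations=rots,
            torsions=_wrap_angle(self.torsions + alpha * direction.torsions),
        )


@dataclass
class GeneralizedGradient:
    translations: np.ndarray   # (n_components, 3)
    rotations: np.ndarray      # (n_components, 3) rotation-vector components
    torsions: np.ndarray       # (n_joints,)

    def norm_sq(self) -> float:
        return (float(np.sum(self.translations ** 2))
                + float(np.sum(self.rotations ** 2))
                + float(np.sum(self.torsions ** 2)))

    def negated(self) -> "GeneralizedGradient":
        return GeneralizedGradient(-self.translations, -self.rotations,
                                   -self.torsions)

    def preconditioned(self, diag: "GeneralizedGradient") -> "GeneralizedGradient":
        return GeneralizedGradient(self.translations / diag.translations,
                                   self.rotations / diag.rotations,
                                   self.torsions / diag.torsions)

    def dot(self, other: "GeneralizedGradient") -> float:
        return (float(np.sum(self.translations * other.translations))
                + float(np.sum(self.rotations * other.rotations))
                + float(np.sum(self.torsions * other.torsions)))

    def combine(self, other: "GeneralizedGradient", beta: float
                ) -> "GeneralizedGradient":
        """self + beta * other."""
        return GeneralizedGradient(
            self.translations + beta * other.translations,
            self.rotations + beta * other.rotations,
            self.torsions + beta * other.torsions)

    def minus(self, other: "GeneralizedGradient") -> "GeneralizedGradient":
        return self.combine(other, -1.0)


def _component_centroids(topology: KinematicTopology,
                         reference: np.ndarray) -> np.ndarray:
    return np.array([reference[atoms].mean(axis=0)
                     for atoms in topology.component_atoms])


def _rotate_about_axis(coords: np.ndarray, atom_idx: np.ndarray,
                       point: np.ndarray, axis: np.ndarray, angle: float) -> None:
    rot = Rotation.from_rotvec(axis * angle)
    coords[atom_idx] = rot.apply(coords[atom_idx] - point) + point


def forward_kinematics(topology: KinematicTopology,
                       q: GeneralizedCoordinates,
                       reference: np.ndarray) -> np.ndarray:
    """Cartesian coordinates for generalized state ``q``.

    Joint rotations are applied root-outward about the current bond
    axes, then each component's free pose is applied about its
    reference centroid.  ``q`` identical to the reference state returns
    the reference coordinates bit-identically.
    """
    if len(q.torsions) != topology.n_joints:
        raise ValueError("torsion vector does not match joint count")
    if len(q.rotations) != len(topology.component_atoms):
        raise ValueError("root pose count does not match component count")
    coords = reference.copy()
    for j, joint in enumerate(topology.joints):
        theta = q.torsions[j]
        if theta == 0.0:
            continue
        a = coords[joint.axis_a]
        b = coords[joint.axis_b]
        axis = b - a
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValueError(f"degenerate joint axis at joint {j}")
        _rotate_about_axis(coords, joint.rotating_atoms, a, axis / norm, theta)
    centroids = _component_centroids(topology, reference)
    for c, atoms in enumerate(topology.component_atoms):
        rot = q.rotations[c]
        t = q.translations[c]
        if np.all(t == 0.0) and rot.magnitude() == 0.0:
            continue
        coords[atoms] = rot.apply(coords[atoms] - centroids[c]) + centroids[c] + t
    return coords


def generalized_gradient(cartesian_gradient: np.ndarray,
                         topology: KinematicTopology,
                         q: GeneralizedCoordinates,
                         coords: np.ndarray,
                         reference: np.ndarray) -> GeneralizedGradient:
    """Exact chain-rule projection of a Cartesian gradient onto ``q``.

    Torsion component: sum over rotating atoms of
    (axis x (x - axis_point)) . dE/dx.  Root components: net force and
    net torque about the component's (displaced) reference centroid.
    """
    g = np.asarray(cartesian_gradient)
    n_comp = len(topology.component_atoms)
    gt = np.zeros((n_comp, 3))
    gw = np.zeros((n_comp, 3))
    centroids = _component_centroids(topology, reference)
    for c, atoms in enumerate(topology.component_atoms):
        gc = g[atoms]
        gt[c] = gc.sum(axis=0)
        center = centroids[c] + q.translations[c]
        gw[c] = np.sum(np.cross(coords[atoms] - center, gc), axis=0)
    gtheta = np.zeros(topology.n_joints)
    for j, joint in enumerate(topology.joints):
        a = coords[joint.axis_a]
        axis = coords[joint.axis_b] - a
        axis = axis / np.linalg.norm(axis)
        arms = coords[joint.rotating_atoms] - a
        gtheta[j] = float(np.sum(np.cross(axis, arms) * g[joint.rotating_atoms]))
    return GeneralizedGradient(translations=gt, rotations=gw, torsions=gtheta)


def _spring_curvature_diag(potential: MorphPotential,
                           topology: KinematicTopology,
                           q: GeneralizedCoordinates,
                           coords: np.ndarray,
                           reference: np.ndarray) -> GeneralizedGradient:
    """Gauss-Newton diagonal of the spring term in generalized coordinates.

    Used as a preconditioner: it equalizes the wildly different
    curvature scales of translations (kJ/mol/A^2) and torsions
    (kJ/mol/rad^2, which grow with the moment sum F * sum r^2 of the
    sprung atoms in the rotating set).  Coordinates without any sprung
    atom get the largest scale so they take conservative steps.
    """
    n_comp = len(topology.component_atoms)
    ht = np.zeros((n_comp, 3))
    hw = np.zeros((n_comp, 3))
    htheta = np.zeros(topology.n_joints)
    if potential.springs is not None:
        s = potential.springs
        kw = s.force_constant * s.weights
        sprung = np.zeros(len(coords))
        sprung[s.atom_idx] = kw
        centroids = _component_centroids(topology, reference)
        for c, atoms in enumerate(topology.component_atoms):
            k_here = sprung[atoms]
            ht[c] = k_here.sum()
            arms = coords[atoms] - (centroids[c] + q.translations[c])
            # per-axis torque curvature ~ sum k * |r_perp|^2
            r2 = np.sum(arms * arms, axis=1)
            for ax in range(3):
                hw[c, ax] = float(np.sum(k_here * (r2 - arms[:, ax] ** 2)))
        for j, joint in enumerate(topology.joints):
            a = coords[joint.axis_a]
            axis = coords[joint.axis_b] - a
            axis = axis / np.linalg.norm(axis)
            arms = coords[joint.rotating_atoms] - a
            lever = np.cross(axis, arms)
            htheta[j] = float(np.sum(sprung[joint.rotating_atoms]
                                     * np.sum(lever * lever, axis=1)))
    scale = max(float(ht.max(initial=0.0)), float(hw.max(initial=0.0)),
                float(htheta.max(initial=0.0)), 1.0)
    floor = max(1e-3 * scale, 1.0)
    return GeneralizedGradient(np.maximum(ht, floor),
                               np.maximum(hw, floor),
                               np.maximum(htheta, floor))


@dataclass
class MorphConfig:
    """Run parameters for one morph stage.

    The convergence rule stops the run at the first frame ending
    ``convergence_window`` consecutive frame-to-frame total-energy
    differences below ``convergence_threshold`` (kJ/mol).  Setting
    ``thermal_noise`` > 0 enables seeded overdamped exploration noise
    (off by default; descent is then no longer monotone).
    """

    report_interval: int = 5           # accepted steps per emitted frame
    max_step_displacement: float = 0.5  # A; per-step atomic motion cap
    convergence_threshold: float = 50.0  # kJ/mol
    convergence_window: int = 5        # frames
    max_steps: int = 20000
    max_wall_time: Optional[float] = None  # seconds
    initial_step_size: float = 1.0
    force_constant: float = 30.0       # threading spring F, kJ/mol/A^2
    atom_policy: str = "representative"
    nonbonded: NonbondedParams = field(default_factory=NonbondedParams)
    thermal_noise: float = 0.0         # rms noise per generalized coordinate
    seed: int = 0
    stop_check: Optional[object] = None  # callable; polled between steps

    def __post_init__(self) -> None:
        if self.convergence_threshold <= 0:
            raise ValueError("convergence threshold must be > 0")
        if self.convergence_window < 1:
            raise ValueError("convergence window must be >= 1")


@dataclass
class MorphResult:
    trajectory: Trajectory
    energy_series: List[EnergyReport]
    converged: bool
    frames_to_convergence: Optional[int]
    stalled: bool = False
    diagnostic: str = ""

    def final_model(self) -> StructureModel:
        return self.trajectory.frame_model(self.trajectory.n_frames - 1)


def check_convergence(energy_series: Sequence[float], threshold: float = 50.0,
                      window: int = 5) -> Tuple[bool, Optional[int]]:
    """Apply the frame-wise energy-plateau stop rule.

    Converged at the first frame index (0-based) ending a run of
    ``window`` consecutive absolute frame-to-frame differences all
    below ``threshold``.
    """
    if len(energy_series) == 0:
        raise ValueError("energy series must be non-empty")
    e = np.asarray(energy_series, dtype=float)
    diffs = np.abs(np.diff(e))
    run = 0
    for k, d in enumerate(diffs):
        run = run + 1 if d < threshold else 0
        if run >= window:
            return True, k + 1
    return False, None


def prealign_final(initial: StructureModel, final: StructureModel,
                   alignment_chain_pairs: Sequence[Tuple[str, str]],
                   ) -> StructureModel:
    """Rigidly superpose the final structure onto the initial frame.

    Alignment uses representative atoms of the residues matched by
    gapped alignment over the designated chain pairs, so all emitted
    frames live in the initial structure's coordinate frame.
    """
    corr = residue_correspondence(initial, final,
                                  chain_pairs=alignment_chain_pairs)
    if not corr:
        raise ValueError("no alignable residues between initial and final")
    keys_i = [p[0] for p in corr]
    keys_f = [p[1] for p in corr]
    ci, pi = representative_coords(initial, keys_i)
    cf, pf = representative_coords(final, keys_f)
    mask = np.array(pi) & np.array(pf)
    R, t, _ = kabsch_superpose(ci[mask], cf[mask])
    aligned = final.copy()
    aligned.set_coords(apply_transform(aligned.coords_array(), R, t))
    return aligned


def run_morph(initial: StructureModel, final: StructureModel,
              spec: MobilitySpec,
              chain_pairs: Sequence[Tuple[str, str]],
              config: Optional[MorphConfig] = None,
              alignment_chain_pairs: Optional[Sequence[Tuple[str, str]]] = None,
              alignment_mode="gapped",
              restraints: Sequence[DistanceRestraint] = (),
              prealigned: bool = False) -> MorphResult:
    """Morph the semiflexible initial structure onto the rigid final one.

    Pipeline: (1) rigid pre-alignment of the final structure onto the
    initial frame over ``alignment_chain_pairs`` (default: all chain
    pairs); (2) threading-spring construction per chain pair; (3)
    steepest descent with backtracking line search on the total morph
    potential in generalized coordinates, emitting a frame every
    ``report_interval`` accepted steps until the energy-plateau rule,
    ``max_steps`` or ``max_wall_time`` stops it.  Frame 0 is the
    unmodified initial structure.
    """
    config = config or MorphConfig()
    if prealigned:
        final_aligned = final
    else:
        final_aligned = prealign_final(
            initial, final, alignment_chain_pairs or chain_pairs)

    springs = build_springs(initial, final_aligned, chain_pairs,
                            alignment_mode=alignment_mode,
                            atom_policy=config.atom_policy,
                            force_constant=config.force_constant)
    topology = compile_mobility(initial, spec)
    zone = physics_zone_atoms(initial, spec) if spec.flexible_selections else None
    potential = compile_potential(initial, topology, springs, spec,
                                  zone_atoms=zone, restraints=restraints,
                                  nonbonded_params=config.nonbonded)
    return _descend(initial, topology, potential, config)


def _descend(model: StructureModel, topology: KinematicTopology,
             potential: MorphPotential, config: MorphConfig) -> MorphResult:
    reference = model.coords_array()
    q = GeneralizedCoordinates.identity(topology)
    coords = reference.copy()
    report, cart_grad = total_energy(coords, potential)
    grad = generalized_gradient(cart_grad, topology, q, coords, reference)

    rng = np.random.default_rng(config.seed)
    frames: List[np.ndarray] = [coords.copy()]
    energies: List[EnergyReport] = [report]
    t_start = time.monotonic()
    alpha = config.initial_step_size
    armijo_c = 1e-4
    accepted = 0
    steps = 0
    stalled = False
    diagnostic = ""
    converged = False
    conv_frame: Optional[int] = None

    def emit_frame() -> None:
        frames.append(coords.copy())
        energies.append(report)

    prev_pgrad: Optional[GeneralizedGradient] = None
    prev_direction: Optional[GeneralizedGradient] = None
    while steps < config.max_steps:
        if (config.max_wall_time is not None
                and time.monotonic() - t_start > config.max_wall_time):
            diagnostic = "wall-time limit reached"
            break
        if config.stop_check is not None and config.stop_check():
            diagnostic = "stopped by user"
            break
        # preconditioned nonlinear conjugate gradient (Polak-Ribiere with
        # restart): the preconditioner equalizes translation/torsion scales
        # and the conjugate term resolves the coupling between near-parallel
        # hinge torsions that plain steepest descent crawls through
        diag = _spring_curvature_diag(potential, topology, q, coords, reference)
        pgrad = grad.preconditioned(diag)
        direction = pgrad.negated()
        if prev_pgrad is not None and prev_direction is not None:
            beta = (grad.dot(pgrad.minus(prev_pgrad))
                    / max(prev_pgrad_dot, 1e-300))
            if beta > 0.0:
                candidate = direction.combine(prev_direction, beta)
                if -grad.dot(candidate) > 0.0:  # keep only descent directions
                    direction = candidate
        prev_pgrad = pgrad
        prev_pgrad_dot = grad.dot(pgrad)
        if config.thermal_noise > 0.0:
            direction = GeneralizedGradient(
                direction.translations + config.thermal_noise
                * rng.standard_normal(direction.translations.shape),
                direction.rotations + config.thermal_noise
                * rng.standard_normal(direction.rotations.shape),
                direction.torsions + config.thermal_noise
                * rng.standard_normal(direction.torsions.shape))
        descent_rate = -grad.dot(direction)  # positive along a descent direction
        if not stalled:
            if descent_rate <= 0.0:
                stalled = config.thermal_noise == 0.0
            else:
                # trust region: cap the largest atomic displacement per step
                # so the trajectory is a smooth quasi-static interpolation
                trial_alpha = alpha
                for _ in range(4):
                    q_try = q.stepped(direction, trial_alpha)
                    coords_try = forward_kinematics(topology, q_try, reference)
                    disp = float(np.max(np.linalg.norm(coords_try - coords,
                                                       axis=1)))
                    if disp <= config.max_step_displacement or disp == 0.0:
                        break
                    trial_alpha *= config.max_step_displacement / disp
                # backtracking (Armijo) line search along the descent direction
                accepted_step = False
                while trial_alpha > 1e-15:
                    q_try = q.stepped(direction, trial_alpha)
                    coords_try = forward_kinematics(topology, q_try, reference)
                    report_try, cart_grad_try = total_energy(coords_try, potential)
                    if report_try.total <= report.total - armijo_c * trial_alpha * descent_rate:
                        q, coords, report = q_try, coords_try, report_try
                        grad = generalized_gradient(cart_grad_try, topology, q,
                                                    coords, reference)
                        alpha = min(trial_alpha * 1.5, 1.0)
                        accepted_step = True
                        prev_direction = direction
                        break
                    trial_alpha *= 0.5
                if not accepted_step:
                    stalled = config.thermal_noise == 0.0
                    prev_pgrad = prev_direction = None  # CG restart
        steps += 1
        accepted += 1  # stalled iterations still advance the frame clock
        if accepted % config.report_interval == 0:
            emit_frame()
            converged, conv_frame = check_convergence(
                [e.total for e in energies],
                config.convergence_threshold, config.convergence_window)
            if converged:
                break

    if not converged and accepted % config.report_interval != 0:
        # record the last reached state even when stopping on limits
        emit_frame()
        converged, conv_frame = check_convergence(
            [e.total for e in energies],
            config.convergence_threshold, config.convergence_window)
    if stalled and not converged:
        diagnostic = diagnostic or "line search stalled at machine precision"

    traj = Trajectory(topology=model.copy(), frames=frames,
                      frame_metadata=[e.as_dict() for e in energies])
    return MorphResult(trajectory=traj, energy_series=energies,
                       converged=converged, frames_to_convergence=conv_frame,
                       stalled=stalled, diagnostic=diagnostic)


@dataclass
class StageSpec:
    """Per-stage settings for a chained multi-state morph.

    ``drop_chains`` removes chains from the working model before the
    stage (e.g. factor release); ``translate`` rigidly displaces chains
    (e.g. placing a factor at distance before binding).
    """

    mobility: MobilitySpec
    chain_pairs: Sequence[Tuple[str, str]]
    alignment_chain_pairs: Optional[Sequence[Tuple[str, str]]] = None
    restraints: Sequence[DistanceRestraint] = ()
    alignment_mode: str | dict = "gapped"
    drop_chains: Sequence[str] = ()
    translate: Dict[str, Sequence[float]] = field(default_factory=dict)
    config: Optional[MorphConfig] = None


def chain_morphs(states: Sequence[StructureModel],
                 per_stage_specs: Sequence[StageSpec],
                 config: Optional[MorphConfig] = None) -> List[MorphResult]:
    """Chain morphs through an ordered list of states.

    Stage k morphs the result of stage k-1 (the initial state for k=0)
    onto ``states[k+1]``.  A stage failure aborts the chain and the
    partial results are returned.
    """
    if len(states) < 2:
        raise ValueError("need at least two states to chain morphs")
    if len(per_stage_specs) != len(states) - 1:
        raise ValueError("need one stage spec per transition")
    from .model_io import translate_chain

    results: List[MorphResult] = []
    current = states[0]
    for k, stage in enumerate(per_stage_specs):
        work = current.copy()
        for cid in stage.drop_chains:
            work.chains = [c for c in work.chains if c.chain_id != cid]
        for cid, offset in stage.translate.items():
            work = translate_chain(work, cid, offset)
        try:
            res = run_morph(work, states[k + 1], stage.mobility,
                            stage.chain_pairs,
                            config=stage.config or config,
                            alignment_chain_pairs=stage.alignment_chain_pairs,
                            alignment_mode=stage.alignment_mode,
                            restraints=stage.restraints)
        except Exception as exc:
            warnings.warn(f"stage {k} failed: {exc}; returning partial chain")
            break
        results.append(res)
        current = res.final_model()
    return results


def linear_morph(initial: StructureModel, final: StructureModel,
                 n_frames: int = 21, prealigned: bool = True) -> Trajectory:
    """Straight-line Cartesian interpolation between identical topologies.

    The zero-physics baseline: every atom travels the chord between its
    endpoint positions, which is what lets linear morphs drive moving
    parts through each other.  Requires the two models to share atom
    count and ordering.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if not prealigned:
        final = prealign_final(initial, final,
                               [(c.chain_id, c.chain_id) for c in initial.chains
                                if final.has_chain(c.chain_id)])
    a = initial.coords_array()
    b = final.coords_array()
    if a.shape != b.shape:
        raise ValueError("linear interpolation requires identical topologies")
    frames = [(1 - s) * a + s * b for s in np.linspace(0.0, 1.0, n_frames)]
    return Trajectory(topology=initial.copy(), frames=frames,
                      frame_metadata=[{} for _ in range(n_frames)])
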