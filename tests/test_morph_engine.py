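import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import springmorph as sm
from springmorph.correspondence import build_springs
from springmorph.energetics import compile_potential, total_energy
from springmorph.flexibility import compile_mobility, physics_zone_atoms
from springmorph.morph_engine import (
    GeneralizedCoordinates,
    check_convergence,
    forward_kinematics,
    generalized_gradient,
    linear_morph,
    prealign_final,
)


@pytest.fixture(scope="module")
def toy_topology(toy_case):
    return compile_mobility(toy_case.initial, toy_case.mobility)


def test_fk_identity_is_bit_exact(toy_case, toy_topology):
    ref = toy_case.initial.coords_array()
    q = GeneralizedCoordinates.identity(toy_topology)
    out = forward_kinematics(toy_topology, q, ref)
    assert (out == ref).all()


def test_fk_full_turn_returns_to_reference(toy_case, toy_topology):
    ref = toy_case.initial.coords_array()
    q = GeneralizedCoordinates.identity(toy_topology)
    # angles wrap to (-pi, pi], so 2*pi wraps to zero exactly; apply two
    # half turns instead to exercise the rotation path itself
    q.torsions[0] = np.pi
    half = forward_kinematics(toy_topology, q, ref)
    q2 = GeneralizedCoordinates.identity(toy_topology)
    q2.torsions[0] = -np.pi
    back = forward_kinematics(toy_topology, q2, half)
    assert np.abs(back - ref).max() < 1e-9


def test_fk_hinge_rotation_matches_explicit_axis_angle(toy_case, toy_topology):
    ref = toy_case.initial.coords_array()
    j = next(i for i, joint in enumerate(toy_topology.joints)
             if joint.label == "A:9:N-CA")
    joint = toy_topology.joints[j]
    theta = 0.8
    q = GeneralizedCoordinates.identity(toy_topology)
    q.torsions[j] = theta
    got = forward_kinematics(toy_topology, q, ref)
    axis = ref[joint.axis_b] - ref[joint.axis_a]
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * theta)
    want = ref.copy()
    want[joint.rotating_atoms] = (
        rot.apply(ref[joint.rotating_atoms] - ref[joint.axis_a])
        + ref[joint.axis_a])
    assert np.abs(got - want).max() < 1e-9


def test_fk_dimension_mismatch_errors(toy_case, toy_topology):
    q = GeneralizedCoordinates(translations=np.zeros((1, 3)),
                               rotations=[Rotation.identity()],
                               torsions=np.zeros(99))
    with pytest.raises(ValueError):
        forward_kinematics(toy_topology, q, toy_case.initial.coords_array())


def _toy_potential(toy_case):
    spec = sm.MobilitySpec(
        flexible_selections=list(toy_case.mobility.flexible_selections),
        collision_spheres=[toy_case.interface_sphere])
    springs = build_springs(toy_case.initial, toy_case.final, [("A", "A")])
    topo = compile_mobility(toy_case.initial, spec)
    zone = physics_zone_atoms(toy_case.initial, spec)
    return topo, compile_potential(toy_case.initial, topo, springs, spec,
                                   zone_atoms=zone)


def test_generalized_gradient_zero_for_zero_cartesian(toy_case, toy_topology):
    ref = toy_case.initial.coords_array()
    q = GeneralizedCoordinates.identity(toy_topology)
    g = generalized_gradient(np.zeros_like(ref), toy_topology, q, ref, ref)
    assert g.norm_sq() == 0.0


def test_generalized_gradient_pure_translation_force(toy_case):
    topo = compile_mobility(toy_case.initial, sm.MobilitySpec())  # one body
    ref = toy_case.initial.coords_array()
    q = GeneralizedCoordinates.identity(topo)
    cart = np.tile(np.array([1.0, -2.0, 0.5]), (len(ref), 1))
    g = generalized_gradient(cart, topo, q, ref, ref)
    np.testing.assert_allclose(g.translations[0],
                               cart.sum(axis=0), rtol=1e-12)
    assert len(g.torsions) == 0


def test_generalized_gradient_matches_finite_differences(toy_case, rng):
    """Chain-rule projection vs finite differences in q (1e-6 rad/A)."""
    topo, pot = _toy_potential(toy_case)
    ref = toy_case.initial.coords_array()
    q = GeneralizedCoordinates.identity(topo)
    q.torsions[:] = rng.normal(0, 0.3, topo.n_joints)
    q.translations[:] = rng.normal(0, 1.0, q.translations.shape)
    q.rotations = [Rotation.random(random_state=5)]
    coords = forward_kinematics(topo, q, ref)
    _, cart = total_energy(coords, pot)
    g = generalized_gradient(cart, topo, q, coords, ref)
    h = 1e-6

    def energy_of(qq):
        rep, _ = total_energy(forward_kinematics(topo, qq, ref), pot)
        return rep.total

    for j in range(topo.n_joints):
        qp = GeneralizedCoordinates(q.translations.copy(), list(q.rotations),
                                    q.torsions.copy())
        qp.torsions[j] += h
        qm = GeneralizedCoordinates(q.translations.copy(), list(q.rotations),
                                    q.torsions.copy())
        qm.torsions[j] -= h
        fd = (energy_of(qp) - energy_of(qm)) / (2 * h)
        assert g.torsions[j] == pytest.approx(fd, rel=1e-4)
    for k in range(3):
        dt = np.zeros(3)
        dt[k] = h
        qp = GeneralizedCoordinates(q.translations + dt, list(q.rotations),
                                    q.torsions.copy())
        qm = GeneralizedCoordinates(q.translations - dt, list(q.rotations),
                                    q.torsions.copy())
        fd = (energy_of(qp) - energy_of(qm)) / (2 * h)
        assert g.translations[0, k] == pytest.approx(fd, rel=1e-4)
        dw = np.zeros(3)
        dw[k] = h
        qp = GeneralizedCoordinates(q.translations.copy(),
                                    [Rotation.from_rotvec(dw) * q.rotations[0]],
                                    q.torsions.copy())
        qm = GeneralizedCoordinates(q.translations.copy(),
                                    [Rotation.from_rotvec(-dw) * q.rotations[0]],
                                    q.torsions.copy())
        fd = (energy_of(qp) - energy_of(qm)) / (2 * h)
        assert g.rotations[0, k] == pytest.approx(fd, rel=1e-4)


@pytest.mark.parametrize("series,threshold,window,expected", [
    ([10.0] * 6, 50.0, 5, (True, 5)),
    ([1000 - 100 * i for i in range(8)], 50.0, 5, (False, None)),
    ([1000, 940, 900, 870, 850, 840, 835], 50.0, 5, (True, 6)),
])
def test_convergence_rule(series, threshold, window, expected):
    assert check_convergence(series, threshold, window) == expected


def test_convergence_rule_rejects_empty_series():
    with pytest.raises(ValueError):
        check_convergence([])


def test_identity_morph_converges_immediately(toy_case):
    res = sm.run_morph(toy_case.initial, toy_case.initial, sm.MobilitySpec(),
                       [("A", "A")])
    assert res.converged
    window = sm.MorphConfig().convergence_window
    assert res.frames_to_convergence == window
    assert sm.calpha_rmsd(res.final_model(), toy_case.initial) == pytest.approx(0.0, abs=1e-9)


def test_morph_frame0_is_the_initial_structure(toy_morph_result, toy_case):
    np.testing.assert_array_equal(toy_morph_result.trajectory.frames[0],
                                  toy_case.initial.coords_array())


def test_morph_reaches_target_in_torsion_subspace(toy_morph_result, toy_case):
    assert toy_morph_result.converged
    rmsd = sm.calpha_rmsd(toy_morph_result.final_model(), toy_case.final)
    assert rmsd < 0.5


def test_rigid_hinge_morph_stalls_but_plateau_fires(toy_case):
    res = sm.run_morph(toy_case.initial, toy_case.final, sm.MobilitySpec(),
                       [("A", "A")])
    assert res.converged  # plateau rule still fires on the flat series
    rmsd = sm.calpha_rmsd(res.final_model(), toy_case.final)
    assert rmsd > 1.0  # cannot reach the target without the hinge DOF


def test_descent_energy_is_monotone(toy_morph_result):
    e = [r.total for r in toy_morph_result.energy_series]
    assert all(b <= a + 1e-9 for a, b in zip(e, e[1:]))


def test_morph_is_deterministic(toy_case):
    spec = sm.MobilitySpec(
        flexible_selections=list(toy_case.mobility.flexible_selections))
    r1 = sm.run_morph(toy_case.initial, toy_case.final, spec, [("A", "A")])
    r2 = sm.run_morph(toy_case.initial, toy_case.final, spec, [("A", "A")])
    assert r1.trajectory.n_frames == r2.trajectory.n_frames
    for f1, f2 in zip(r1.trajectory.frames, r2.trajectory.frames):
        np.testing.assert_array_equal(f1, f2)


def test_cooperative_user_stop(toy_case):
    spec = sm.MobilitySpec(
        flexible_selections=list(toy_case.mobility.flexible_selections))
    calls = []

    def stop():
        calls.append(1)
        return len(calls) > 3

    cfg = sm.MorphConfig(stop_check=stop)
    res = sm.run_morph(toy_case.initial, toy_case.final, spec, [("A", "A")],
                       config=cfg)
    assert res.diagnostic == "stopped by user"
    assert not res.converged
    assert res.trajectory.n_frames >= 1


def test_no_springs_errors(toy_case):
    rna = sm.make_polymer(4, "rna")
    with pytest.raises(ValueError):
        sm.run_morph(toy_case.initial, rna, sm.MobilitySpec(), [("A", "A")])


def test_chain_morphs_monotone_hinge_opening():
    mid = sm.make_two_domain_case(theta_degrees=30.0)
    end = sm.make_two_domain_case(theta_degrees=60.0)
    stage = lambda: sm.StageSpec(mobility=sm.MobilitySpec(
        flexible_selections=list(mid.mobility.flexible_selections)),
        chain_pairs=[("A", "A")])
    results = sm.chain_morphs([mid.initial, mid.final, end.final],
                              [stage(), stage()])
    assert len(results) == 2 and all(r.converged for r in results)
    # concatenated trajectory approaches 30 deg then 60 deg states
    assert sm.calpha_rmsd(results[0].final_model(), mid.final) < 0.5
    assert sm.calpha_rmsd(results[1].final_model(), end.final) < 0.5
    # hinge angle proxy: srmsd to the initial grows monotonically per stage end
    s1 = sm.srmsd(mid.initial, results[0].final_model(), mid.domain1, mid.domain2)
    s2 = sm.srmsd(mid.initial, results[1].final_model(), mid.domain1, mid.domain2)
    assert 0 < s1 < s2


def test_chain_morphs_stage_spec_can_drop_chains():
    a = sm.make_polymer(6, chain_id="A")
    b = sm.translate_chain(sm.make_polymer(6, chain_id="B"), "B", (30, 0, 0))
    both = sm.StructureModel(chains=[a.chains[0], b.chains[0]])
    only_a = sm.StructureModel(chains=[a.chains[0]])
    stage = sm.StageSpec(mobility=sm.MobilitySpec(), chain_pairs=[("A", "A")],
                         drop_chains=["B"])
    results = sm.chain_morphs([both, only_a], [stage])
    assert len(results) == 1
    assert [c.chain_id for c in results[0].trajectory.topology.chains] == ["A"]


def test_linear_morph_endpoints_and_validation(toy_case):
    traj = linear_morph(toy_case.initial, toy_case.final, n_frames=11)
    np.testing.assert_allclose(traj.frames[0], toy_case.initial.coords_array())
    np.testing.assert_allclose(traj.frames[-1], toy_case.final.coords_array())
    with pytest.raises(ValueError):
        linear_morph(toy_case.initial, toy_case.final, n_frames=1)


def test_prealignment_puts_final_in_initial_frame(toy_case):
    moved = toy_case.final.copy()
    rot = Rotation.from_euler("y", 45, degrees=True)
    moved.set_coords(rot.apply(moved.coords_array()) + np.array([10.0, 0, 0]))
    aligned_moved = prealign_final(toy_case.initial, moved, [("A", "A")])
    aligned_plain = prealign_final(toy_case.initial, toy_case.final, [("A", "A")])
    np.testing.assert_allclose(aligned_moved.coords_array(),
                               aligned_plain.coords_array(), atol=1e-6)
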