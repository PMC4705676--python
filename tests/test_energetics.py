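import numpy as np
import pytest

import springmorph as sm
from springmorph.energetics import (
    CompiledSpheres,
    CompiledSprings,
    NonbondedParams,
    collision_energy,
    compile_potential,
    nonbonded_energy,
    restraint_energy,
    spring_energy,
    total_energy,
)
from springmorph.flexibility import compile_mobility, physics_zone_atoms


@pytest.fixture(scope="module")
def toy_potential(toy_case):
    """Fully populated potential: springs, interface sphere, physics zone."""
    from springmorph.correspondence import build_springs, wc_restraints
    spec = sm.MobilitySpec(
        flexible_selections=list(toy_case.mobility.flexible_selections),
        collision_spheres=[toy_case.interface_sphere],
        physics_zone_radius=10.0)
    springs = build_springs(toy_case.initial, toy_case.final, [("A", "A")],
                            force_constant=30.0)
    topo = compile_mobility(toy_case.initial, spec)
    zone = physics_zone_atoms(toy_case.initial, spec)
    restraints = [sm.DistanceRestraint(("A", 1, "", "CA"), ("A", 18, "", "CA"),
                                       20.0, 5.0)]
    return compile_potential(toy_case.initial, topo, springs, spec,
                             zone_atoms=zone, restraints=restraints)


def test_spring_energy_closed_forms():
    coords = np.array([[0.0, 0.0, 0.0]])
    springs = CompiledSprings(atom_idx=np.array([0]),
                              targets=np.array([[0.0, 0.0, 0.0]]),
                              force_constant=30.0, weights=np.ones(1))
    assert spring_energy(coords, springs)[0] == 0.0
    springs.targets = np.array([[1.0, 0.0, 0.0]])  # 1 A displacement
    e30, g = spring_energy(coords, springs)
    assert e30 == pytest.approx(15.0)           # (1/2) * 30 * 1^2
    np.testing.assert_allclose(g[0], [-30.0, 0.0, 0.0])
    springs.force_constant = 60.0
    e60, _ = spring_energy(coords, springs)
    assert e60 == pytest.approx(30.0) and e60 == pytest.approx(2 * e30)


def test_collision_energy_closed_forms():
    spheres = CompiledSpheres(center_atom=[None],
                              center_point=[np.zeros(3)],
                              radius=np.array([5.0]),
                              stiffness=np.array([100.0]),
                              own_body=np.array([-1]))
    body = np.array([0, 1])
    far = np.array([[10.0, 0, 0], [0, 12.0, 0]])
    assert collision_energy(far, spheres, body)[0] == 0.0
    at_center = np.array([[0.0, 0.0, 0.0], [20.0, 0, 0]])
    e, _ = collision_energy(at_center, spheres, body)
    assert e == pytest.approx(0.5 * 100.0 * 25.0)  # 1250 kJ/mol
    boundary = np.array([[5.0, 0.0, 0.0], [20.0, 0, 0]])
    e, g = collision_energy(boundary, spheres, body)
    assert e == 0.0
    np.testing.assert_allclose(g, 0.0, atol=1e-12)  # gradient continuous


def test_collision_sphere_ignores_its_own_body(toy_case):
    spec = sm.MobilitySpec(
        flexible_selections=list(toy_case.mobility.flexible_selections),
        collision_spheres=[sm.CollisionSphere(
            radius=8.0, center_atom=("A", 4, "CA"))])
    topo = compile_mobility(toy_case.initial, spec)
    pot = compile_potential(toy_case.initial, topo, None, spec)
    # every atom near residue 4 belongs to the proximal body -> no energy
    e, _ = collision_energy(toy_case.initial.coords_array(), pot.spheres,
                            pot.atom_body)
    assert e == 0.0


def test_nonbonded_closed_form_and_brute_force_oracle(rng, toy_case):
    # two isolated atoms at r = sigma/2 -> eps/4
    from springmorph.energetics import CompiledNonbonded
    sigma = np.array([1.7, 1.7])
    nb = CompiledNonbonded(zone=np.array([0, 1]), sigma=sigma, epsilon=10.0,
                           excluded=set(), max_cutoff=6.8)
    coords = np.array([[0.0, 0, 0], [1.7, 0, 0]])  # r = sigma_ij / 2 = 1.7
    e, _ = nonbonded_energy(coords, nb, np.array([0, 1]))
    assert e == pytest.approx(10.0 / 4.0)

    # KD-tree implementation equals a brute-force double loop on the toy
    spec = toy_case.mobility
    topo = compile_mobility(toy_case.initial, spec)
    zone = physics_zone_atoms(toy_case.initial, spec)
    pot = compile_potential(toy_case.initial, topo, None, spec,
                            zone_atoms=zone)
    coords = toy_case.initial.coords_array() + rng.normal(0, 0.4, (toy_case.initial.n_atoms, 3))
    e_impl, g_impl = nonbonded_energy(coords, pot.nonbonded, pot.atom_body)
    nbz = pot.nonbonded
    e_brute = 0.0
    for a in range(len(nbz.zone)):
        for b in range(a + 1, len(nbz.zone)):
            gi, gj = int(nbz.zone[a]), int(nbz.zone[b])
            if pot.atom_body[gi] == pot.atom_body[gj]:
                continue
            if (min(gi, gj), max(gi, gj)) in nbz.excluded:
                continue
            r = np.linalg.norm(coords[gi] - coords[gj])
            s = nbz.sigma[a] + nbz.sigma[b]
            if r < s:
                e_brute += nbz.epsilon * (1.0 - r / s) ** 2
    assert e_impl == pytest.approx(e_brute, rel=1e-12)


def test_all_pair_distances_beyond_sigma_give_zero():
    from springmorph.energetics import CompiledNonbonded
    nb = CompiledNonbonded(zone=np.arange(3), sigma=np.full(3, 1.5),
                           epsilon=10.0, excluded=set(), max_cutoff=6.0)
    coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
    e, g = nonbonded_energy(coords, nb, np.arange(3))
    assert e == 0.0
    np.testing.assert_allclose(g, 0.0)


def test_total_energy_is_sum_of_terms(toy_potential, toy_case, rng):
    coords = toy_case.initial.coords_array() + rng.normal(0, 0.3, (toy_case.initial.n_atoms, 3))
    report, _ = total_energy(coords, toy_potential)
    assert report.total == pytest.approx(
        report.spring + report.collision + report.nonbonded + report.restraint)
    for term in (report.spring, report.collision, report.nonbonded,
                 report.restraint):
        assert term >= 0.0


def test_empty_potential_reports_zero(toy_case):
    spec = sm.MobilitySpec()
    topo = compile_mobility(toy_case.initial, spec)
    pot = compile_potential(toy_case.initial, topo, None, spec)
    report, grad = total_energy(toy_case.initial.coords_array(), pot)
    assert report.total == 0.0
    np.testing.assert_allclose(grad, 0.0)


def test_analytic_gradient_matches_finite_differences(toy_potential, toy_case, rng):
    """Central finite differences (1e-5 A) vs the analytic Cartesian
    gradient of the full potential, relative error < 1e-5."""
    coords = toy_case.initial.coords_array() + rng.normal(0, 0.3, (toy_case.initial.n_atoms, 3))
    _, grad = total_energy(coords, toy_potential)
    h = 1e-5
    idx = rng.choice(len(coords), 12, replace=False)
    for i in idx:
        for k in range(3):
            cp = coords.copy()
            cp[i, k] += h
            ep, _ = total_energy(cp, toy_potential)
            cm = coords.copy()
            cm[i, k] -= h
            em, _ = total_energy(cm, toy_potential)
            fd = (ep.total - em.total) / (2 * h)
            if abs(fd) > 1e-6:
                assert grad[i, k] == pytest.approx(fd, rel=1e-5)
            else:
                assert grad[i, k] == pytest.approx(fd, abs=1e-5)


def test_restraint_energy_zero_at_target_distance():
    from springmorph.energetics import CompiledRestraints
    rest = CompiledRestraints(idx_i=np.array([0]), idx_j=np.array([1]),
                              target=np.array([3.0]),
                              stiffness=np.array([30.0]))
    coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    e, g = restraint_energy(coords, rest)
    assert e == pytest.approx(0.0)
    np.testing.assert_allclose(g, 0.0, atol=1e-12)
    coords[1, 0] = 4.0  # stretched by 1 A
    e, _ = restraint_energy(coords, rest)
    assert e == pytest.approx(15.0)
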