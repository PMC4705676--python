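import numpy as np
import pytest

import springmorph as sm


@pytest.fixture(scope="session")
def toy_case():
    """Two-domain hinge case at 60 degrees: the standard benchmark toy."""
    return sm.make_two_domain_case(domain_size=8, hinge_length=2,
                                   theta_degrees=60.0, seed=1)


@pytest.fixture(scope="session")
def toy_morph_result(toy_case):
    """One converged morph of the 60-degree toy under default conditions:
    hinge flexible, physics zone 10 A, F = 30, convergence 50 kJ/mol over
    5 frames, interface collision sphere active."""
    spec = sm.MobilitySpec(
        flexible_selections=toy_case.mobility.flexible_selections,
        collision_spheres=[toy_case.interface_sphere],
        physics_zone_radius=10.0)
    config = sm.MorphConfig(force_constant=30.0, convergence_threshold=50.0,
                            convergence_window=5)
    return sm.run_morph(toy_case.initial, toy_case.final, spec,
                        [("A", "A")], config=config)


@pytest.fixture(scope="session")
def clash_case():
    """Wide-swing (150 degree) hinge case whose straight-line interpolation
    drives the distal domain through the interface collision sphere."""
    return sm.make_two_domain_case(domain_size=8, hinge_length=2,
                                   theta_degrees=150.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
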