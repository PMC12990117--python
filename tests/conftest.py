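import pytest

from cgmem.core_io import SimulationBox
from cgmem.synthetic import (
    BilayerSpec,
    IonPlacement,
    default_role_map,
    generate_two_bilayer_system,
    place_ions,
)


@pytest.fixture(scope="session")
def role_map():
    return default_role_map()


@pytest.fixture(scope="session")
def flat_system():
    """Two flat bilayers (thickness 4, centers 5 and 15) in a 10x10x20 box:
    phosphate sheets at z = 3, 7, 13, 17 exactly."""
    box = SimulationBox(10.0, 10.0, 20.0)
    spec1 = BilayerSpec(156, 0.64, 4.0, 0.0, (1, 0), 5.0)
    spec2 = BilayerSpec(156, 0.64, 4.0, 0.0, (1, 0), 15.0)
    return generate_two_bilayer_system(spec1, spec2, box, seed=11)


@pytest.fixture(scope="session")
def droplet_system(flat_system):
    """Flat two-bilayer system plus a 50-cation nanodroplet lodged at the
    center of bilayer 1."""
    return place_ions(
        flat_system, IonPlacement(50, "core_droplet", cluster_radius=2.0), seed=12
    )


def make_undulated_system(seed, amplitude=0.6, periods=(1, 0), n=156):
    box = SimulationBox(10.0, 10.0, 20.0)
    spec1 = BilayerSpec(n, 0.64, 4.0, amplitude, periods, 5.0)
    spec2 = BilayerSpec(n, 0.64, 4.0, amplitude, periods, 15.0)
    return generate_two_bilayer_system(spec1, spec2, box, seed=seed)
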