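import math

import numpy as np
import pytest

from coaflow import (
    AortaNetwork,
    CohortConfig,
    FluidProperties,
    Junction,
    Outlet,
    RunConfig,
    VesselSegment,
    generate_cohort,
    run_pipeline,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


def make_chain_network(
    radii=(0.8, 0.7, 0.6, 0.5, 0.5),
    lengths=(2.0, 1.0, 1.0, 2.0, 5.0),
    lesion_index=3,
    lesion_throat_radius=0.25,
    outlet_diameters=(1.2, 0.8, 0.9, 1.0),
):
    """Hand-built five-segment arch chain with three branch outlets and a
    terminal outlet; the lesion segment narrows to ``lesion_throat_radius``
    in its middle third."""
    segs = []
    for i, (r, L) in enumerate(zip(radii, lengths)):
        if i == lesion_index:
            a, b = L / 3.0, 2.0 * L / 3.0
            prof = [(0.0, r), (a, r), ((a + b) / 2, lesion_throat_radius), (b, r), (L, r)]
            segs.append(VesselSegment(f"seg{i}", L, prof, is_lesion=True,
                                      lesion_start=a, lesion_end=b))
        else:
            segs.append(VesselSegment(f"seg{i}", L, [(0.0, r), (L, r)]))
    outlets = [Outlet(f"out{i}", d) for i, d in enumerate(outlet_diameters)]
    junctions = [
        Junction("seg0", "seg1", "out0"),
        Junction("seg1", "seg2", "out1"),
        Junction("seg2", "seg3", "out2"),
        Junction("seg3", "seg4", None),
        Junction("seg4", None, "out3"),
    ]
    return AortaNetwork(segments=segs, junctions=junctions, outlets=outlets,
                        inlet_segment="seg0", diaphragm_diameter=2 * radii[-1])


@pytest.fixture()
def chain_network():
    return make_chain_network()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort (n=65, seed 42)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_pipeline_result():
    return run_pipeline(RunConfig(seed=42))


def random_chain_network(rng):
    """A random valid arch chain for solver stress tests."""
    n_seg = 5
    radii = rng.uniform(0.3, 1.0, n_seg)
    lengths = rng.uniform(0.5, 5.0, n_seg)
    lesion_index = int(rng.integers(0, n_seg))
    throat = float(radii[lesion_index] * rng.uniform(0.2, 0.95))
    diams = rng.uniform(0.3, 1.5, 4)
    return make_chain_network(
        radii=tuple(radii), lengths=tuple(lengths),
        lesion_index=lesion_index, lesion_throat_radius=throat,
        outlet_diameters=tuple(diams),
    )
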