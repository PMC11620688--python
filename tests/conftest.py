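import pytest

from icrsim.geometry import CorneaGeometry
from icrsim.implantation import CorneaSimulator
from icrsim.material import YeohParams
from icrsim.mesh import build_cornea_mesh
from icrsim.rings import default_registry, enumerate_campaign

#: element target used for simulation-backed tests; coarse enough to keep a
#: full protocol run around half a minute while still resolving the slit
SIM_ELEMENTS = 1200


@pytest.fixture(scope="session")
def geom():
    return CorneaGeometry()


@pytest.fixture(scope="session")
def material():
    return YeohParams()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def sections(registry):
    return {(c.family_id, c.size_index): c for c in registry.cross_sections()}


@pytest.fixture(scope="session")
def coarse_mesh(geom):
    """Uniform, unrefined mesh (no slit band)."""
    return build_cornea_mesh(geom, target_elements=500)


@pytest.fixture(scope="session")
def refined_mesh(geom):
    """Mesh with slit-band refinement at the 5.5 mm implantation annulus."""
    return build_cornea_mesh(geom, target_elements=SIM_ELEMENTS,
                             refinement_zone=(2.75, 0.9))


@pytest.fixture(scope="session")
def simulator():
    return CorneaSimulator(target_elements=SIM_ELEMENTS)


@pytest.fixture(scope="session")
def keraring_run(simulator, sections):
    """One full implantation: the Keraring-like wedge, largest size, 5.5 mm."""
    cs = sections[("horizontal-trapezoid", 1)]
    run = simulator.run(enumerate_campaign([cs], diameters=(5.5,))[0])
    assert run.converged, f"reference run failed at {run.failure_stage}"
    return run


@pytest.fixture(scope="session")
def mini_campaign(simulator):
    """Reduced design sweep for campaign-level checks.  The full 300-run
    sweep is a many-hour batch job; this subsample keeps the category and
    size structure of the full design."""
    from icrsim.campaign import run_reduced_sweep

    return run_reduced_sweep(simulator=simulator)
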