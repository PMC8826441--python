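import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_surrogate():
    from latticeimplant.surrogate import SurrogateModel

    return SurrogateModel.with_reference_coefficients()


@pytest.fixture(scope="session")
def small_cantilever():
    from latticeimplant import fixtures

    return fixtures.make_cantilever(8, 4, 2)


@pytest.fixture(scope="session")
def octet_cell_05():
    from latticeimplant.unit_cell import UnitCellSpec, build_cell

    spec = UnitCellSpec(cell_type="octet", l=1.35, rho=0.5)
    return spec, build_cell(spec)


@pytest.fixture(scope="session")
def mbb_beam():
    """Extruded MBB-like beam: simply supported, centre-top load."""
    import numpy as np

    from latticeimplant import fe_solver, fixtures

    base, _ = fixtures.make_cantilever(24, 8, 2, elem_size=1.0, total_load=500.0)
    mesh = fe_solver.MacroMesh(nodes=base.nodes.copy(), elements=base.elements.copy())
    nds = mesh.nodes
    for n in np.flatnonzero((np.abs(nds[:, 0]) < 1e-9) & (np.abs(nds[:, 1]) < 1e-9)):
        mesh.fixed_dofs += [(int(n), 0), (int(n), 1), (int(n), 2)]
    for n in np.flatnonzero(
        (np.abs(nds[:, 0] - 24) < 1e-9) & (np.abs(nds[:, 1]) < 1e-9)
    ):
        mesh.fixed_dofs += [(int(n), 1), (int(n), 2)]
    top_center = np.flatnonzero(
        (np.abs(nds[:, 0] - 12) < 1e-9) & (np.abs(nds[:, 1] - 8) < 1e-9)
    )
    mesh.loads = [(int(n), 1, -500.0 / len(top_center)) for n in top_center]
    return mesh
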