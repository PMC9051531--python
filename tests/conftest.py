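import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brushdpd.sim_core import BondSpec, DPDParams, State, WallSpec
from brushdpd.units import calibrate_unit_map

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def umap():
    """Unit map anchored at the softest wall: 150 reduced <-> 0.96 nN, 300 K."""
    return calibrate_unit_map(150.0, 0.96, 300.0)


@pytest.fixture
def free_pair_state():
    """Two solvent beads mid-slab, no bonds, gentle walls far away."""

    def _make(r=0.5, box=8.0, h=10.0):
        pos = np.array([[4.0, 4.0, 5.0], [4.0 + r, 4.0, 5.0]])
        return State(
            positions=pos,
            velocities=np.zeros((2, 3)),
            species=np.zeros(2, dtype=np.int32),
            bonds=np.zeros((0, 2), dtype=np.int64),
            bond_spec=BondSpec(),
            Lx=box,
            Ly=box,
            h=h,
            wall_bottom=WallSpec(a_w=150.0),
            wall_top=WallSpec(a_w=150.0, position=h, orientation=-1),
        )

    return _make


@pytest.fixture
def params_1species():
    return DPDParams(a_matrix=np.array([[25.0]]), gamma=4.5, sigma=3.0)
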