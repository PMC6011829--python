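import numpy as np
import pytest

from hostguest.synth import (SyntheticTrajectoryParams, build_toy_host,
                             simulate_binding_trajectory)

WATER_PDB = """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def water_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_PDB)
    return path


@pytest.fixture(scope="session")
def toy_host():
    return build_toy_host()


@pytest.fixture(scope="session")
def small_bundle():
    """500-frame synthetic trajectory with moderately fast kinetics, shared
    across read-only tests."""
    params = SyntheticTrajectoryParams(
        n_frames=500, frame_interval=100.0, p_hbond=0.05,
        k_on=0.5, k_off=1.0, seed=42)
    return simulate_binding_trajectory(params=params), params


def random_rigid_transform(rng):
    """A uniform random proper rotation plus a translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.uniform(-20.0, 20.0, size=3)
    return rot, shift
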