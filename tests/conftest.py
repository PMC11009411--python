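import numpy as np
import pytest

from memsort.membrane_builder import MembraneRecipe
from memsort.synthetic_data import GroundTruth, generate_membrane_trajectory
from memsort.traj_model import Box, Frame, Trajectory


@pytest.fixture(scope="session")
def dopc_recipe():
    return MembraneRecipe.from_fractions(["DOPC"], [1.0], 216)


@pytest.fixture(scope="session")
def ternary_recipe():
    return MembraneRecipe.from_counts(["DYPC", "DPPC", "CHOL"], [138, 92, 99])


@pytest.fixture(scope="session")
def box120():
    return Box(120.0, 120.0, 100.0)


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruth(h_far=29.0, h_contact=20.0, lambda_decay=20.0, R_protein=10.0,
                       sigma_z=0.0, sigma_xy=1.0, D_lat=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_traj(dopc_recipe, noiseless_truth, box120):
    return generate_membrane_trajectory(dopc_recipe, noiseless_truth, 20, box120)


def make_flat_frame(z_half=14.5, n_side=6, L=120.0, with_protein=True):
    """Planar bilayer fixture: heads at exactly +/- z_half on a lateral grid."""
    xs = (np.arange(n_side) + 0.5) * L / n_side
    gx, gy = np.meshgrid(xs, xs)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n = xy.shape[0]
    bead_id, bead_name, resid, resname, xyz = [], [], [], [], []
    if with_protein:
        bead_id.append(1)
        bead_name.append("BB")
        resid.append(1)
        resname.append("PROT")
        xyz.append([L / 2.0, L / 2.0, 0.0])
    next_id = len(bead_id) + 1
    next_res = 2 if with_protein else 1
    for sign in (1.0, -1.0):
        for k in range(n):
            bead_id.append(next_id)
            bead_name.append("PO4")
            resid.append(next_res)
            resname.append("DOPC")
            xyz.append([xy[k, 0], xy[k, 1], sign * z_half])
            next_id += 1
            next_res += 1
    return Frame(0.0, Box(L, L, 100.0), bead_id, bead_name, resid, resname, np.array(xyz))


@pytest.fixture
def flat_frame():
    return make_flat_frame()


@pytest.fixture
def flat_traj(flat_frame):
    return Trajectory(frames=[flat_frame], protein_resids=(1,), lipid_head_beads=("PO4",))
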