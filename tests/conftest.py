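import numpy as np
import pytest

from dockmap.cluster import ClusterParams
from dockmap.dock import DockParams, dock_rigid
from dockmap.fixtures import make_toy_complex, make_toy_pocket
from dockmap.ftmap import MapParams, map_structure, probe_library
from dockmap.pipeline import run_docking_pipeline


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(1)


@pytest.fixture(scope="session")
def toy_small():
    """Cheaper planted-pose system for contract (non-recovery) tests."""
    return make_toy_complex(5, n_rec=140, n_lig=30)


@pytest.fixture(scope="session")
def pocket():
    return make_toy_pocket(1)


@pytest.fixture(scope="session")
def probes():
    return probe_library()


@pytest.fixture(scope="session")
def small_map_params():
    return MapParams(seed=1, probe_rotations=24, poses_retained_per_probe=800,
                     minimize_iter=25)


@pytest.fixture(scope="session")
def pocket_map(pocket, small_map_params):
    """One full (reduced-rotation) mapping run shared across tests."""
    return map_structure(pocket.receptor, small_map_params)


@pytest.fixture(scope="session")
def docked(toy):
    """One 500-rotation docking run on the seed-1 toy complex."""
    return dock_rigid(toy.receptor, toy.ligand,
                      DockParams(n_rotations=500, seed=17))


@pytest.fixture(scope="session")
def dock_pipeline_result(toy):
    return run_docking_pipeline(toy.receptor, toy.ligand,
                                DockParams(n_rotations=500, seed=17),
                                ClusterParams())
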