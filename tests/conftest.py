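import numpy as np
import pytest

from oxypath import synthetic
from oxypath.tracking import TrackingParams, analyze_run


@pytest.fixture(scope="session")
def toy_protein():
    """One shared toy system (geometry is seed-independent)."""
    return synthetic.build_toy_system(seed=11)


@pytest.fixture(scope="session")
def scripted_run(toy_protein):
    """A deterministic scripted run with ground truth, shared read-only."""
    script = synthetic.random_script(toy_protein, seed=11, n_frames=400)
    traj, truth = synthetic.script_trajectory(toy_protein, script)
    return toy_protein, traj, truth


@pytest.fixture(scope="session")
def analyzed_run(scripted_run):
    protein, traj, truth = scripted_run
    result = analyze_run(traj, protein.atoms, protein.helices, protein.cavities,
                         TrackingParams(), label="toy")
    return protein, traj, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
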