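import numpy as np
import pytest

import prolifmap as pm


@pytest.fixture(scope="session")
def phantom_volume():
    return pm.build_phantom()


@pytest.fixture(scope="session")
def truth_2m(phantom_volume):
    """Nucleus cloud of a young-adult (2-month) phantom, fixed seed."""
    lam = pm.table1_intensities(phantom_volume, age_months=2, mouse="A")
    return pm.sample_nuclei(phantom_volume, lam, seed=0)


@pytest.fixture(scope="session")
def cloud_2m(phantom_volume, truth_2m):
    """The same cloud with densities attached and compartments assigned.

    The generator's label is kept as ``true_label`` so recovery can be
    checked against it.
    """
    pts = truth_2m.points.rename(columns={"label": "true_label"})
    pts = pm.with_density(pts)
    return pm.assign_compartments(pts, phantom_volume)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
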