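import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tfdyn as td

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return td.default_parameters()


@pytest.fixture(scope="session")
def net_b42_4():
    return td.build_canonical_network("B42", 4)


@pytest.fixture(scope="session")
def mcfg(params):
    return td.MeasurementConfig.from_params(params)


@pytest.fixture(scope="session")
def traj_b42_2000(params):
    """One shared induction trajectory (B42, 4 boxes, SDC, 2000 nM)."""
    tgrid = np.array([0.0, 60.0, 120.0, 180.0, 300.0, 600.0, 1200.0, 1440.0, 1680.0])
    return td.simulate(td.Condition("B42", 4, "SDC", 2000.0), params, tgrid)


@pytest.fixture(scope="session")
def tiny_dataset(params):
    """Small noise-free dataset: one fluorescence time course."""
    design = td.DesignSpec(
        variants=("B42",),
        box_counts=(4,),
        media=("SDC",),
        doses_nM=(0.0, 2000.0),
        growth_doses_nM=(0.0, 2000.0),
        fluor_times_min=(60.0, 300.0, 600.0, 1200.0),
        mrna_times_min=(15.0, 45.0, 120.0),
        seed=7,
        noise=False,
    )
    return td.generate(design, params)
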