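import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voxnorm import SimConfig, predict_all_conditions, simulate_dataset
from voxnorm.conditions import BODY_PREFERENCE_MAP

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def raw_from_canonical(canonical: dict, preference: str = "body") -> dict:
    """Invert the canonical relabelling to build a raw B/H response map."""
    if preference == "body":
        return {raw: canonical[c] for raw, c in BODY_PREFERENCE_MAP.items()}
    from voxnorm.conditions import HOUSE_PREFERENCE_MAP

    return {raw: canonical[c] for raw, c in HOUSE_PREFERENCE_MAP.items()}


@pytest.fixture(scope="session")
def norm_profile():
    """Noiseless normalization-generated profile (LP=4, LN=2, sigma=1, beta=2)."""
    return predict_all_conditions("normalization", np.array([4.0, 2.0, 1.0, 2.0]))


@pytest.fixture(scope="session")
def tiny_sim_config():
    return SimConfig(
        n_neurons=400,
        neurons_per_voxel=50,
        n_voxels_per_roi=3,
        roi_body_ratio={"LO": 0.5, "EBA": 0.9},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim_config):
    return simulate_dataset("normalizing", tiny_sim_config, seed=11)
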