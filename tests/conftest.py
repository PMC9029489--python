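import numpy as np
import pytest

import mocapcompare as mc
from mocapcompare.synthetic import MarkerlessDistortion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def joints():
    return mc.default_joint_definitions()


@pytest.fixture
def placements():
    return mc.default_placements()


def random_unit_quats(rng, n):
    """Uniformly random unit quaternions, scalar-first."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture
def null_trial():
    """One synthetic trial with every distortion switched off."""
    cfg = mc.SyntheticConfig.null(tasks=("bottle",), seed=7)
    return mc.generate_trial(cfg, subject=0, task="bottle", trial=0)


@pytest.fixture
def lagged_cfg():
    def make(lag_s, **kwargs):
        return mc.SyntheticConfig.null(
            markerless=MarkerlessDistortion(bias_deg=0.0, noise_sd_deg=0.0, lag_s=lag_s),
            **kwargs,
        )

    return make


def constant_series(value=0.0, n=100, rate=100.0, joint="shoulder",
                    dof="flexion_extension", system="reference"):
    return mc.JointAngleSeries(
        joint=joint, dof=dof, system=system, rate=rate,
        values=np.full(n, float(value)),
    )
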