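import numpy as np
import pytest

from dcmstereo.camsim import scale_distortion_spec
from dcmstereo.cli_io import RunConfig, run_stereo_experiment


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def experiment(default_cfg):
    """The five-distance stereo protocol at the reference lens magnitude."""
    return run_stereo_experiment(default_cfg)


def _scaled_cfg(factor: float) -> RunConfig:
    spec = RunConfig().distortion_spec()
    mild = scale_distortion_spec(spec, factor)
    return RunConfig(
        lambda1_left=mild.lambda1_left,
        lambda2_left=mild.lambda2_left,
        lambda1_right=mild.lambda1_right,
        lambda2_right=mild.lambda2_right,
    )


@pytest.fixture(scope="session")
def mild_cfg():
    """Fine-distortion conditions (one tenth of the reference lens)."""
    return _scaled_cfg(0.1)


@pytest.fixture(scope="session")
def mild_experiment(mild_cfg):
    return run_stereo_experiment(mild_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
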