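import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def case_study():
    from simsens import case_study_parameters

    return case_study_parameters()


@pytest.fixture
def config_yaml(tmp_path):
    """A small, fast experiment configuration file for CLI round trips."""
    text = """\
parameters:
  - {name: chemoThreshold, lower: 0.0, upper: 1.0, calibrated: 0.3, increment: 0.1}
  - {name: chemoLowerLinearAdjust, lower: 0.015, upper: 0.08, calibrated: 0.045, increment: 0.005}
  - {name: chemoUpperLinearAdjust, lower: 0.1, upper: 0.5, calibrated: 0.3, increment: 0.05}
  - {name: thresholdBindProbability, lower: 0.0, upper: 1.0, calibrated: 0.5, increment: 0.1}
  - {name: vcamSlope, lower: 0.25, upper: 2.0, calibrated: 1.0, increment: 0.25}
  - {name: maxVCAMeffectProbabilityCutoff, lower: 0.0, upper: 1.0, calibrated: 0.5, increment: 0.1}
responses: [Velocity, Displacement]
seed: 7
consistency:
  sample_sizes: [1, 5]
  subset_count: 3
lhs:
  n_sets: 10
  candidates: 5
efast:
  ns: 17
  nr: 2
  m: 4
  dummy_name: dummy
"""
    path = tmp_path / "config.yaml"
    path.write_text(text)
    return path
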