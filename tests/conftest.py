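import numpy as np
import pytest

from salinerf import make_config, run


@pytest.fixture(scope="session")
def ex_vivo_result():
    """Full 20 s bench-condition run (47 V, +1 %/degC, flow on, 24 degC)."""
    return run(make_config("ex_vivo", snapshot_interval=0.0))


@pytest.fixture(scope="session")
def in_vivo_perfused_result():
    return run(make_config("in_vivo_perfused", snapshot_interval=0.0))


@pytest.fixture(scope="session")
def in_vivo_clamped_result():
    return run(make_config("in_vivo_clamped", snapshot_interval=0.0))


@pytest.fixture(scope="session")
def zero_flow_result():
    return run(make_config("zero_flow", snapshot_interval=0.0))


@pytest.fixture(scope="session")
def ex_vivo_mesh(ex_vivo_result):
    return ex_vivo_result.mesh
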