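import numpy as np
import pytest

from csdwave import RunConfig


@pytest.fixture(scope="session")
def ref_cfg() -> RunConfig:
    return RunConfig.reference()


@pytest.fixture()
def tiny_cfg(ref_cfg) -> RunConfig:
    """Small, fast configuration for structural tests (not calibrated)."""
    return ref_cfg.with_overrides(
        **{
            "grid.n_nodes": 21,
            "grid.half_length": 4.0,
            "integration.dt": 0.01,
            "integration.t_final": 0.5,
            "integration.record_every": 5,
        }
    )


@pytest.fixture(scope="session")
def measurements():
    """Session-wide cache of expensive reference-scale measurements."""
    return {}


@pytest.fixture(scope="session")
def control_measurement(ref_cfg, measurements):
    from csdwave import measure_speed

    if "control" not in measurements:
        measurements["control"] = measure_speed(ref_cfg)
    return measurements["control"]


@pytest.fixture(scope="session")
def control_trajectory(ref_cfg):
    from csdwave import run_simulation

    return run_simulation(ref_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
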