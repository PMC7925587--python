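import time

import pytest

from gastamp import RunConfig, build_eye_model, run_grid


@pytest.fixture(scope="session")
def model24():
    return build_eye_model(24)


@pytest.fixture(scope="session")
def default_grid():
    """Full default grid (meniscus mode) with its wall-clock time."""
    t0 = time.perf_counter()
    table = run_grid(RunConfig())
    return table, time.perf_counter() - t0


@pytest.fixture(scope="session")
def flat_grid():
    return run_grid(RunConfig(mode="flat"))
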