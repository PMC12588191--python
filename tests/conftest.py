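import numpy as np
import pytest

from preictal.segment import segment_window
from preictal.synthetic import default_spec, generate_window


@pytest.fixture(scope="session")
def sim_window():
    """One default synthetic window plus its ground truth (seed 1)."""
    spec = default_spec(1)
    rng = np.random.default_rng(1)
    return generate_window(spec, rng)


@pytest.fixture(scope="session")
def sim_segments(sim_window):
    window, _ = sim_window
    return segment_window(window)


@pytest.fixture(scope="session")
def recovery_windows():
    """200 default windows with truths, shared by artifact-recovery checks."""
    spec = default_spec(7)
    rng = np.random.default_rng(7)
    out = [generate_window(spec, rng) for _ in range(200)]
    return [w for w, _ in out], [t for _, t in out]
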